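import pytest

from ampedit import (
    AlleleClass,
    example_locus,
    example_templates,
    make_allele_set,
)


@pytest.fixture(scope="session")
def locus():
    return example_locus(seed=0)


@pytest.fixture(scope="session")
def template_edits(locus):
    return example_templates(locus)


@pytest.fixture(scope="session")
def allele_set(locus, template_edits):
    return make_allele_set(locus, template_edits)


@pytest.fixture(scope="session")
def templates(allele_set):
    return [a for a in allele_set if a.allele_class is AlleleClass.INTENDED_EDIT]


@pytest.fixture(scope="session")
def alleles_by_label(allele_set):
    return {a.label: a for a in allele_set}
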