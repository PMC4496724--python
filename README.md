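# ampedit

Amplicon deep-sequencing analysis of genome-editing outcomes in single
embryos. The package quantifies wild-type alleles, template-specified
("intended") edits and random indels/point mutations from 2×250 bp paired-end
amplicon reads, and ships a synthetic read generator so the whole pipeline is
testable without external data.

## What it does

- **`ampedit.simulate`** — builds reference loci (amplicon + key-mutation
  window + A/B polymorphic sites), allele sets (templated edits, NHEJ-style
  indels, point mutations) and seeded paired-end FASTQ reads with a per-base
  Phred substitution error model and a ground-truth table.
- **`ampedit.readqc`** — quality trimming to the longest contiguous segment
  with per-base error probability < 0.01, exact-identity pair joining
  (overlap ≥ 14 bp, overlap quality = per-base maximum) and a ≥ 250 bp joined
  length filter.
- **`ampedit.mapping`** — semi-global affine-gap alignment of joined reads to
  the amplicon (match +2, mismatch −3, gap open −12, gap extend −1), key
  window extraction with gap removal, and unique-sequence enumeration with a
  strict > 1% reporting rule (wild-type rows always reported).
- **`ampedit.classify`** — allele classification (intended edit / WT-A / WT-B
  / indel / point / complex) with background assignment from surviving
  polymorphic sites, per-embryo profiles with mosaicism calls
  (non-mosaic-biallelic > 96% intended; unedited < 1% edited), in-silico
  restriction digest (XbaI/SfoI/RsaI) and IUPAC-degenerate probe matching.
- **`ampedit.stats`** — integer rate percentages (half away from zero),
  two-sided Fisher's exact test by hypergeometric enumeration, and a binomial
  logit-link GLM of (edited, not-edited) read counts on
  nucleic-acid × enzyme (reference levels DNA / TALEN; 8 h records excluded).
- **`ampedit.pipeline` / `ampedit.cli`** — the end-to-end pipeline with
  stage-count conservation logging and JSON/TSV reports.

## CLI

```bash
# simulate embryos (reference FASTA, locus YAML, paired FASTQ, truth table)
ampedit simulate --config sim.yaml --out-dir out/sim --seed 1

# stage by stage
ampedit qc --r1 out/sim/E1_R1.fastq --r2 out/sim/E1_R2.fastq --out-prefix out/E1
ampedit map --reads out/E1.joined.fastq --locus out/sim/locus.yaml --out out/alleles.tsv
ampedit classify --alleles out/alleles.tsv --locus out/sim/locus.yaml --out out/profile.json

# or everything at once
ampedit run --config run.yaml --out-dir out/report

# group statistics
ampedit stats --groups groups.tsv --model readcounts.tsv --out-dir out/stats
```

Example `sim.yaml`:

```yaml
locus: {kind: example, seed: 0}
reads: {read_length: 250, mean_quality: 30}
embryos:
  - id: E1
    n_read_pairs: 20000
    alleles: {"9 bp DEL-B": 0.93, "WT-B": 0.07}
```

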