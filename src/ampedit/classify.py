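"""Allele classification, embryo profiles and in-silico diagnostics.

Window sequences are classified against intended-edit templates and the two
wild-type backgrounds; remaining differences are read off a pairwise alignment
and summarised as deletion/insertion/transversion/transition calls. Profiles
aggregate class percentages per embryo and call mosaicism. Restriction digest
and degenerate-probe matching reproduce the gain-of-XbaI / loss-of-SfoI style
diagnostics in silico.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import Align
from Bio.Data.IUPACData import ambiguous_dna_values

from .core import is_transversion, revcomp
from .mapping import AlleleCount
from .simulate import AlleleClass, AlleleSpec, ReferenceLocus


class MosaicismCall(str, Enum):
    NON_MOSAIC_BIALLELIC = "NON_MOSAIC_BIALLELIC"
    MOSAIC_EDITED = "MOSAIC_EDITED"
    UNEDITED = "UNEDITED"


@dataclass(frozen=True)
class EditCall:
    """One difference from the wild-type window (positions 1-based in reports)."""

    kind: str  # DEL | INS | TV | TS
    position: int  # 0-based window coordinate of the event start
    length: int
    bases: str = ""  # inserted bases / substituted base
    ref_bases: str = ""  # deleted bases / reference base


@dataclass(frozen=True)
class AlleleCall:
    seq: str
    allele_class: AlleleClass
    background: str  # 'A', 'B' or 'ambiguous'
    label: str
    edits: Tuple[EditCall, ...] = ()


@dataclass(frozen=True)
class EmbryoProfile:
    embryo_id: str
    calls: Tuple[Tuple[AlleleCall, int, float], ...]
    pct_intended: float
    pct_wt: float
    pct_other: float
    mosaicism_call: MosaicismCall

    def __post_init__(self) -> None:
        if self.pct_intended + self.pct_wt + self.pct_other > 100.0 + 1e-6:
            raise ValueError("class percentages exceed 100")


@dataclass(frozen=True)
class RestrictionSite:
    enzyme: str
    recognition_seq: str

    def __post_init__(self) -> None:
        if not re.fullmatch("[ACGT]+", self.recognition_seq):
            raise ValueError("recognition sequence must be plain A/C/G/T")


#: built-in diagnostic enzymes
DEFAULT_ENZYMES = (
    RestrictionSite("XbaI", "TCTAGA"),
    RestrictionSite("SfoI", "GGCGCC"),
    RestrictionSite("RsaI", "GTAC"),
)


@dataclass(frozen=True)
class DigestResult:
    enzyme: str
    positions: Tuple[int, ...]  # motif start offsets, 0-based
    fragment_lengths: Tuple[int, ...]


# ---------------------------------------------------------------------------
# classification


@lru_cache(maxsize=1)
def _window_aligner() -> Align.PairwiseAligner:
    # global alignment with penalized end gaps: the window sequences are
    # complete, so edits at window edges must surface as gap columns
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


def _align_to_window(wt_window: str, seq: str):
    aln = _window_aligner().align(wt_window, seq)[0]
    return str(aln[0]), str(aln[1]), aln.score


def _extract_edits(ref_row: str, read_row: str) -> List[EditCall]:
    """Group alignment columns into DEL/INS runs and substitution calls."""
    edits: List[EditCall] = []
    rpos = 0
    run_kind = None
    run_start = 0
    run_read: List[str] = []
    run_ref: List[str] = []

    def flush() -> None:
        nonlocal run_kind, run_read, run_ref
        if run_kind == "DEL":
            edits.append(EditCall("DEL", run_start, len(run_ref), ref_bases="".join(run_ref)))
        elif run_kind == "INS":
            edits.append(EditCall("INS", run_start, len(run_read), bases="".join(run_read)))
        run_kind = None
        run_read = []
        run_ref = []

    for rc, qc in zip(ref_row, read_row):
        if rc == "-":  # insertion in read
            if run_kind != "INS":
                flush()
                run_kind, run_start = "INS", rpos
            run_read.append(qc)
        elif qc == "-":  # deletion from reference
            if run_kind != "DEL":
                flush()
                run_kind, run_start = "DEL", rpos
            run_ref.append(rc)
            rpos += 1
        else:
            flush()
            if rc != qc:
                kind = "TV" if is_transversion(rc, qc) else "TS"
                edits.append(EditCall(kind, rpos, 1, bases=qc, ref_bases=rc))
            rpos += 1
    flush()
    return edits


def _edit_part(e: EditCall) -> str:
    if e.kind in ("DEL", "INS"):
        return f"{e.length} bp {e.kind}"
    return f"{e.ref_bases}-{e.bases} {e.kind}"


def call_label(edits: Sequence[EditCall], background: str) -> str:
    if not edits:
        return f"WT-{background}"
    return ", ".join(_edit_part(e) for e in edits) + f"-{background}"


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def classify_allele(
    seq: str,
    locus: ReferenceLocus,
    templates: Sequence[AlleleSpec] = (),
    include_template_plus_subs: bool = False,
    max_template_subs: int = 3,
) -> AlleleCall:
    """Classify a gap-free window sequence.

    Precedence: exact intended-edit template match, then exact wild-type
    match, then alignment to both wild-type backgrounds. The background is
    read from surviving polymorphic-site bases when they are unanimous,
    otherwise from the higher alignment score, otherwise 'ambiguous'.

    With ``include_template_plus_subs``, a sequence equal to a template up to
    ``max_template_subs`` substitutions (and closer to that template than to
    either wild type) is still called INTENDED_EDIT.
    """
    if not seq:
        raise ValueError("cannot classify an empty sequence")
    intended = [t for t in templates if t.allele_class is AlleleClass.INTENDED_EDIT]
    for t in intended:
        if seq == t.window_seq:
            return AlleleCall(seq, AlleleClass.INTENDED_EDIT, t.background, t.label)
    windows = {"A": locus.window_seq("A"), "B": locus.window_seq("B")}
    if seq == windows["B"]:
        return AlleleCall(seq, AlleleClass.WT_B, "B", "WT-B")
    if seq == windows["A"]:
        return AlleleCall(seq, AlleleClass.WT_A, "A", "WT-A")

    if include_template_plus_subs:
        wt_dist = min(
            (_hamming(seq, w) for w in windows.values() if len(w) == len(seq)),
            default=None,
        )
        best_t, best_d = None, None
        for t in intended:
            if len(t.window_seq) != len(seq):
                continue
            d = _hamming(seq, t.window_seq)
            if d <= max_template_subs and (best_d is None or d < best_d):
                best_t, best_d = t, d
        if best_t is not None and (wt_dist is None or best_d < wt_dist):
            subs = _extract_edits(best_t.window_seq, seq)  # equal length: subs only
            return AlleleCall(
                seq, AlleleClass.INTENDED_EDIT, best_t.background, best_t.label, tuple(subs)
            )

    alignments = {bg: _align_to_window(w, seq) for bg, w in windows.items()}

    # vote on background from surviving polymorphic-site bases
    ws = locus.key_region[0]
    ref_row, read_row, _ = alignments["B"]
    site_bases: Dict[int, str] = {}
    rpos = 0
    for rc, qc in zip(ref_row, read_row):
        if rc != "-":
            if qc != "-":
                site_bases[rpos] = qc
            rpos += 1
    votes = set()
    for pos, a, b in locus.poly_sites:
        base = site_bases.get(pos - ws)
        if base == a:
            votes.add("A")
        elif base == b:
            votes.add("B")
    score_a, score_b = alignments["A"][2], alignments["B"][2]
    if len(votes) == 1:
        background = votes.pop()
    elif score_a != score_b:
        background = "A" if score_a > score_b else "B"
    else:
        background = "ambiguous"

    aln_bg = background if background in ("A", "B") else "B"
    edits = _extract_edits(alignments[aln_bg][0], alignments[aln_bg][1])
    if not edits:  # defensive: exact matches were handled above
        cls = AlleleClass.WT_A if aln_bg == "A" else AlleleClass.WT_B
        return AlleleCall(seq, cls, aln_bg, f"WT-{aln_bg}")
    n_indel = sum(1 for e in edits if e.kind in ("DEL", "INS"))
    n_sub = len(edits) - n_indel
    if n_indel == 1 and n_sub == 0:
        cls = AlleleClass.INDEL
    elif n_indel == 0:
        cls = AlleleClass.POINT
    else:
        cls = AlleleClass.COMPLEX
    return AlleleCall(seq, cls, background, call_label(edits, background), tuple(edits))


# ---------------------------------------------------------------------------
# embryo profiles


def build_profile(
    counts: Sequence[AlleleCount],
    calls: Sequence[AlleleCall],
    embryo_id: str = "",
    biallelic_threshold: float = 96.0,
) -> EmbryoProfile:
    """Aggregate per-allele fractions into class percentages and a mosaicism call.

    NON_MOSAIC_BIALLELIC when the intended-edit percentage exceeds the
    threshold; UNEDITED when intended plus indel/point/complex percentages
    stay below 1%; MOSAIC_EDITED otherwise.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    if len(counts) != len(calls):
        raise ValueError("counts and calls differ in length")
    pct = {cls: 0.0 for cls in AlleleClass}
    rows = []
    for count, call in zip(counts, calls):
        if count.seq != call.seq:
            raise ValueError("counts and calls are not aligned (sequence mismatch)")
        pct[call.allele_class] += count.fraction * 100.0
        rows.append((call, count.count, count.fraction))
    pct_intended = pct[AlleleClass.INTENDED_EDIT]
    pct_wt = pct[AlleleClass.WT_A] + pct[AlleleClass.WT_B]
    pct_other = pct[AlleleClass.INDEL] + pct[AlleleClass.POINT] + pct[AlleleClass.COMPLEX]
    if pct_intended > biallelic_threshold:
        call = MosaicismCall.NON_MOSAIC_BIALLELIC
    elif pct_intended + pct_other < 1.0:
        call = MosaicismCall.UNEDITED
    else:
        call = MosaicismCall.MOSAIC_EDITED
    return EmbryoProfile(embryo_id, tuple(rows), pct_intended, pct_wt, pct_other, call)


# ---------------------------------------------------------------------------
# in-silico diagnostics


def digest(
    seq: str, sites: Sequence[RestrictionSite] = DEFAULT_ENZYMES
) -> Dict[str, DigestResult]:
    """All exact motif occurrences per enzyme, with cut positions at motif
    starts; fragment lengths partition the sequence length."""
    results = {}
    for site in sites:
        positions = []
        i = seq.find(site.recognition_seq)
        while i != -1:
            positions.append(i)
            i = seq.find(site.recognition_seq, i + 1)
        bounds = [0] + positions + [len(seq)]
        fragments = tuple(
            b - a for a, b in zip(bounds, bounds[1:]) if b - a > 0
        )
        results[site.enzyme] = DigestResult(site.enzyme, tuple(positions), fragments)
    return results


_IUPAC = {k.upper(): set(v.upper()) for k, v in ambiguous_dna_values.items()}


def probe_match(seq: str, probe: str) -> bool:
    """True iff the IUPAC probe matches a substring of seq or its reverse
    complement with zero mismatches."""
    if not probe:
        raise ValueError("probe must be non-empty")
    parts = []
    for ch in probe.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in probe")
        parts.append("[" + "".join(sorted(_IUPAC[ch])) + "]")
    pattern = re.compile("".join(parts))
    if not seq:
        return False
    return bool(pattern.search(seq) or pattern.search(revcomp(seq)))
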