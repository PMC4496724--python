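"""Alignment of joined reads to the reference amplicon and allele enumeration.

Reads are aligned semi-globally (affine gap penalties, reference overhangs
free) to the amplicon; the key-mutation window is extracted in reference
coordinates, gap characters are removed, and distinct window sequences are
counted. Wild-type A and B rows are always reported; every other sequence is
reported when its fraction of reads exceeds the reporting threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, List, Tuple, Union

from Bio import Align

from .core import PARTIAL_SPAN, UNMAPPED, Rejection, revcomp
from .readqc import JoinedRead
from .simulate import ReferenceLocus


@dataclass(frozen=True)
class AlignConfig:
    """Scores are signed (penalties negative); a gap of length L scores
    ``gap_open + (L-1) * gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -12.0
    gap_extend: float = -1.0
    min_identity_to_map: float = 0.7
    require_full_window_span: bool = True
    try_both_orientations: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0.0):
            raise ValueError("expected gap_open <= gap_extend <= 0 (signed scores)")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")
        if not (0.0 <= self.min_identity_to_map <= 1.0):
            raise ValueError("min_identity_to_map must lie in [0, 1]")


@dataclass(frozen=True)
class ReadAlignment:
    """Gapped read/reference rows restricted to the read's aligned extent."""

    pair_id: str
    aligned_ref: str
    aligned_read: str
    ref_start: int  # 0-based reference coordinate of the first aligned column
    ref_end: int  # half-open
    score: float
    identity: float
    reverse: bool


@dataclass(frozen=True)
class AlleleCount:
    seq: str
    count: int
    fraction: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")


@lru_cache(maxsize=8)
def _aligner(cfg: AlignConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = cfg.match
    aligner.mismatch_score = cfg.mismatch
    aligner.open_gap_score = cfg.gap_open
    aligner.extend_gap_score = cfg.gap_extend
    # free end gaps on both sequences => semi-global / overlap alignment
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _score_and_trim(aln) -> Tuple[str, str, int, int, float]:
    """Trim terminal overhang columns; return rows, ref span and identity."""
    ref_row, read_row = str(aln[0]), str(aln[1])
    n = len(read_row)
    i0 = 0
    while i0 < n and read_row[i0] == "-":
        i0 += 1
    i1 = n
    while i1 > i0 and read_row[i1 - 1] == "-":
        i1 -= 1
    ref_start = sum(1 for c in ref_row[:i0] if c != "-")
    ref_len = sum(1 for c in ref_row[i0:i1] if c != "-")
    cols = i1 - i0
    matches = sum(1 for a, b in zip(ref_row[i0:i1], read_row[i0:i1]) if a == b and a != "-")
    identity = matches / cols if cols else 0.0
    return ref_row[i0:i1], read_row[i0:i1], ref_start, ref_start + ref_len, identity


def align_read(
    read: JoinedRead, locus: ReferenceLocus, cfg: AlignConfig = AlignConfig()
) -> Union[ReadAlignment, Rejection]:
    """Optimal semi-global alignment of the read to the amplicon.

    Both orientations are tried and the higher-scoring one wins (the reverse
    orientation is skipped when the forward identity is already >= 0.9, which
    cannot be beaten by the reverse strand of a real amplicon read). Returns
    an UNMAPPED rejection when identity over the aligned extent falls below
    ``min_identity_to_map``.
    """
    if not read.seq:
        raise ValueError("cannot align an empty read")
    aligner = _aligner(cfg)
    best = None
    for reverse in (False, True):
        if reverse and not cfg.try_both_orientations:
            break
        seq = revcomp(read.seq) if reverse else read.seq
        aln = aligner.align(locus.amplicon_seq, seq)[0]
        ref_row, read_row, ref_start, ref_end, identity = _score_and_trim(aln)
        cand = ReadAlignment(
            read.pair_id, ref_row, read_row, ref_start, ref_end, aln.score, identity, reverse
        )
        if best is None or cand.score > best.score:
            best = cand
        if not reverse and identity >= 0.9:
            break
    if best.identity < cfg.min_identity_to_map:
        return Rejection(UNMAPPED, detail=read.pair_id)
    return best


def extract_window(
    alignment: ReadAlignment, locus: ReferenceLocus, require_full_span: bool = True
) -> Union[str, Rejection]:
    """Gap-free read sequence over the key window, in reference coordinates.

    Insertions strictly inside the window are kept; insertions at either
    boundary are not. Returns a PARTIAL_SPAN rejection when the read does not
    cover the whole window and ``require_full_span`` is set.
    """
    ws, we = locus.key_region
    if require_full_span and (alignment.ref_start > ws or alignment.ref_end < we):
        return Rejection(PARTIAL_SPAN, detail=alignment.pair_id)
    out = []
    rpos = alignment.ref_start
    for rc, qc in zip(alignment.aligned_ref, alignment.aligned_read):
        if rc == "-":
            if ws < rpos < we and qc != "-":
                out.append(qc)
        else:
            if ws <= rpos < we and qc != "-":
                out.append(qc)
            rpos += 1
    return "".join(out)


def enumerate_alleles(
    window_seqs: Iterable[str],
    total_joined: int,
    locus: ReferenceLocus,
    report_threshold: float = 0.01,
) -> List[AlleleCount]:
    """Count distinct window sequences and apply the reporting rule.

    WT-A and WT-B window sequences are always included (count 0 allowed);
    any other sequence is included only when its fraction of ``total_joined``
    strictly exceeds ``report_threshold``. Sorted by count descending, ties
    broken lexicographically by sequence.
    """
    counts = Counter(window_seqs)
    n_seqs = sum(counts.values())
    if total_joined < n_seqs:
        raise ValueError(f"total_joined {total_joined} < number of window sequences {n_seqs}")
    if total_joined <= 0:
        raise ValueError("total_joined must be positive")
    wt = {locus.window_seq("A"), locus.window_seq("B")}
    rows = []
    for seq, count in counts.items():
        fraction = count / total_joined
        if seq in wt or fraction > report_threshold:
            rows.append(AlleleCount(seq, count, fraction))
    for w in sorted(wt):
        if w not in counts:
            rows.append(AlleleCount(w, 0, 0.0))
    rows.sort(key=lambda r: (-r.count, r.seq))
    return rows
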