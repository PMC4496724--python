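"""Read pre-processing: quality trimming, exact-overlap joining, length filter.

Trimming keeps the longest contiguous run of bases whose per-base error
probability (10**(-Q/10)) is strictly below a cutoff. Pairs are joined on the
longest suffix/prefix overlap of at least ``min_overlap`` bases at 100%
identity; joined reads shorter than ``min_joined_length`` are removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

from .core import NO_OVERLAP, FastqRecord, Rejection, revcomp


@dataclass(frozen=True)
class TrimConfig:
    max_error_prob: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.max_error_prob < 1.0):
            raise ValueError("max_error_prob must lie strictly in (0, 1)")


@dataclass(frozen=True)
class JoinConfig:
    min_overlap: int = 14
    required_identity: float = 1.0
    min_joined_length: int = 250

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.required_identity != 1.0:
            raise ValueError("only exact-identity joining is supported")
        if self.min_joined_length < 0:
            raise ValueError("min_joined_length must be >= 0")


@dataclass(frozen=True)
class JoinedRead:
    pair_id: str
    seq: str
    quals: Tuple[int, ...]
    overlap_len: int

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


def _passes(q: int, max_error_prob: float) -> bool:
    return 10.0 ** (-q / 10.0) < max_error_prob


def trim_longest_segment(
    seq: str, quals: Sequence[int], cfg: TrimConfig = TrimConfig()
) -> Tuple[str, Tuple[int, ...]]:
    """Longest contiguous run of bases with error probability < cutoff.

    Ties go to the leftmost run. The result may be empty.
    """
    if len(seq) != len(quals):
        raise ValueError(f"sequence length {len(seq)} != quality length {len(quals)}")
    best_start = best_len = 0
    run_start = None
    for i, q in enumerate(quals):
        if _passes(q, cfg.max_error_prob):
            if run_start is None:
                run_start = i
            if i - run_start + 1 > best_len:
                best_len = i - run_start + 1
                best_start = run_start
        else:
            run_start = None
    return seq[best_start : best_start + best_len], tuple(quals[best_start : best_start + best_len])


def trim_record(rec: FastqRecord, cfg: TrimConfig = TrimConfig()) -> FastqRecord:
    seq, quals = trim_longest_segment(rec.seq, rec.quals, cfg)
    return FastqRecord(rec.id, seq, quals)


def join_pair(
    r1: FastqRecord, r2: FastqRecord, cfg: JoinConfig = JoinConfig()
) -> Union[JoinedRead, Rejection]:
    """Join a pair on the longest exact suffix/prefix overlap.

    ``r2`` is given in raw orientation and reverse-complemented internally.
    Overlap bases must be identical; overlap qualities take the per-base
    maximum of the two reads. Returns a NO_OVERLAP rejection when no overlap
    of at least ``min_overlap`` bases matches exactly.
    """
    r2_seq = revcomp(r2.seq)
    r2_quals = tuple(reversed(r2.quals))
    for k in range(min(len(r1), len(r2_seq)), cfg.min_overlap - 1, -1):
        if r1.seq[len(r1) - k :] == r2_seq[:k]:
            seq = r1.seq + r2_seq[k:]
            quals = (
                r1.quals[: len(r1) - k]
                + tuple(max(a, b) for a, b in zip(r1.quals[len(r1) - k :], r2_quals[:k]))
                + r2_quals[k:]
            )
            return JoinedRead(r1.id, seq, quals, overlap_len=k)
    return Rejection(NO_OVERLAP, detail=r1.id)


def length_filter(
    reads: Iterable[JoinedRead], cfg: JoinConfig = JoinConfig()
) -> Tuple[List[JoinedRead], int]:
    """Keep joined reads of at least ``min_joined_length`` bases.

    Returns (kept reads, number removed).
    """
    kept, removed = [], 0
    for read in reads:
        if len(read) >= cfg.min_joined_length:
            kept.append(read)
        else:
            removed += 1
    return kept, removed
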