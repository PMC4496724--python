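"""Shared primitives: sequences, records, typed stage rejections."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

DNA_ALPHABET = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return all(b in DNA_ALPHABET for b in seq)


def is_transversion(ref: str, alt: str) -> bool:
    """True for purine<->pyrimidine changes, False for within-class changes."""
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}->{alt}")
    return (ref in PURINES) != (alt in PURINES)


@dataclass(frozen=True)
class FastqRecord:
    """A single read: identifier, bases and per-base Phred qualities."""

    id: str
    seq: str
    quals: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


# Typed rejection reasons used across pipeline stages.
NO_OVERLAP = "NO_OVERLAP"
UNMAPPED = "UNMAPPED"
PARTIAL_SPAN = "PARTIAL_SPAN"


@dataclass(frozen=True)
class Rejection:
    """Returned (not raised) when a read fails a stage, so callers can count."""

    reason: str
    detail: str = ""

    def __bool__(self) -> bool:  # rejections are falsy; results are truthy
        return False
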