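"""Synthetic amplicon data with known ground truth.

Generates reference loci (two wild-type backgrounds differing at a small
number of polymorphic sites inside a key-mutation window), allele sets
carrying templated edits / NHEJ-style indels / point mutations, and paired-end
FASTQ reads drawn from per-embryo allele mixtures under a seeded substitution
error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import DNA_ALPHABET, FastqRecord, is_dna, is_transversion, revcomp


class AlleleClass(str, Enum):
    WT_A = "WT_A"
    WT_B = "WT_B"
    INTENDED_EDIT = "INTENDED_EDIT"
    INDEL = "INDEL"
    POINT = "POINT"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class ReferenceLocus:
    """An amplicon with a key-mutation window and A/B polymorphic sites.

    ``amplicon_seq`` is the wild-type B sequence (the mapping reference);
    wild-type A differs from it exactly at ``poly_sites``. ``key_region`` is a
    half-open interval in 0-based amplicon coordinates. ``cut_site`` marks the
    nuclease cleavage position used to place edits.
    """

    name: str
    amplicon_seq: str
    key_region: Tuple[int, int]
    poly_sites: Tuple[Tuple[int, str, str], ...]  # (position, base_in_A, base_in_B)
    cut_site: int = -1

    def __post_init__(self) -> None:
        ws, we = self.key_region
        n = len(self.amplicon_seq)
        if not is_dna(self.amplicon_seq):
            raise ValueError("amplicon_seq must contain only A/C/G/T")
        if not (0 <= ws < we <= n):
            raise ValueError(f"key_region {self.key_region} outside amplicon of length {n}")
        for pos, a, b in self.poly_sites:
            if not (ws <= pos < we):
                raise ValueError(f"polymorphic site {pos} outside key_region {self.key_region}")
            if a == b:
                raise ValueError(f"polymorphic site {pos}: A and B bases are identical")
            if self.amplicon_seq[pos] != b:
                raise ValueError(f"polymorphic site {pos}: amplicon base does not match base_in_B")
        if self.cut_site == -1:
            object.__setattr__(self, "cut_site", (ws + we) // 2)
        if not (0 <= self.cut_site <= n):
            raise ValueError("cut_site outside amplicon")

    @property
    def window_length(self) -> int:
        ws, we = self.key_region
        return we - ws

    def wt_seq(self, background: str) -> str:
        """Full amplicon sequence of wild-type background 'A' or 'B'."""
        if background == "B":
            return self.amplicon_seq
        if background == "A":
            s = list(self.amplicon_seq)
            for pos, a, _b in self.poly_sites:
                s[pos] = a
            return "".join(s)
        raise ValueError(f"unknown background {background!r}")

    def window_seq(self, background: str) -> str:
        ws, we = self.key_region
        return self.wt_seq(background)[ws:we]


@dataclass(frozen=True)
class EditSpec:
    """One edit in amplicon coordinates (0-based).

    kind 'DEL': remove ``length`` bases starting at ``position``.
    kind 'INS': insert ``bases`` before ``position``.
    kind 'SUB': replace the base at ``position`` with ``bases`` (length 1).
    ``intended`` marks template-specified edits (vs random indels/SNVs).
    """

    kind: str
    position: int
    length: int = 0
    bases: str = ""
    background: str = "B"
    intended: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("DEL", "INS", "SUB"):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if self.kind == "INS":
            if not self.bases or not is_dna(self.bases):
                raise ValueError("INS requires inserted bases (A/C/G/T)")
            if self.length and self.length != len(self.bases):
                raise ValueError("INS length does not match inserted bases")
            object.__setattr__(self, "length", len(self.bases))
        elif self.kind == "SUB":
            if len(self.bases) != 1 or not is_dna(self.bases):
                raise ValueError("SUB requires a single replacement base")
            object.__setattr__(self, "length", 1)
        elif self.kind == "DEL" and self.length < 1:
            raise ValueError("DEL requires a positive length")
        if self.background not in ("A", "B"):
            raise ValueError(f"background must be 'A' or 'B', got {self.background!r}")


@dataclass(frozen=True)
class AlleleSpec:
    """A named full-length allele plus its key-window sequence."""

    label: str
    seq: str
    allele_class: AlleleClass
    background: str  # 'A', 'B' or 'ambiguous'
    edit: Optional[EditSpec] = None
    window_seq: str = ""


@dataclass(frozen=True)
class EmbryoMix:
    """Ground-truth allele composition of one simulated embryo."""

    embryo_id: str
    allele_freqs: Tuple[Tuple[AlleleSpec, float], ...]
    n_read_pairs: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_read_pairs < 1:
            raise ValueError("n_read_pairs must be >= 1")
        total = sum(f for _, f in self.allele_freqs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, expected 1")
        if any(f < 0 for _, f in self.allele_freqs):
            raise ValueError("allele frequencies must be non-negative")


@dataclass(frozen=True)
class ReadSimConfig:
    """Read geometry and error model for paired-end simulation.

    Per-base substitution probability is 10**(-q/10) for that base's assigned
    quality unless ``error_rate`` overrides it with a constant.
    ``tail_degradation`` = (n_tail_bases, phred_drop_per_base) makes 3' tails
    decline linearly in quality. The sequenced fragment is the centered
    ``fragment_length`` slice of the allele, capped so the two reads always
    overlap by at least ``min_overlap_generated``.
    """

    read_length: int = 250
    mean_quality: int = 30
    error_rate: Optional[float] = None
    tail_degradation: Optional[Tuple[int, int]] = None
    min_overlap_generated: int = 30
    fragment_length: int = 400

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not (0 <= self.mean_quality <= 93):
            raise ValueError("mean_quality outside Phred range 0..93")
        if self.error_rate is not None and not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must lie in [0, 1]")
        if self.min_overlap_generated < 1 or self.fragment_length < 1:
            raise ValueError("fragment geometry must be positive")


# ---------------------------------------------------------------------------
# Locus construction


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA_ALPHABET), size=n))


def make_reference_locus(
    length: int = 550,
    key_region_length: int = 71,
    n_poly_sites: int = 3,
    seed: int = 0,
    name: str = "locus",
) -> ReferenceLocus:
    """Random locus with a centered key window and A/B polymorphic sites.

    Deterministic for a fixed seed. Polymorphic positions are distinct and
    each site carries different bases on the A and B backgrounds.
    """
    if length < 1 or key_region_length < 1:
        raise ValueError("lengths must be positive")
    if key_region_length > length:
        raise ValueError("key_region_length exceeds amplicon length")
    if n_poly_sites > key_region_length:
        raise ValueError("more polymorphic sites than window positions")
    if n_poly_sites < 0:
        raise ValueError("n_poly_sites must be >= 0")
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, length)
    ws = (length - key_region_length) // 2
    we = ws + key_region_length
    positions = sorted(rng.choice(np.arange(ws, we), size=n_poly_sites, replace=False))
    sites = []
    for pos in positions:
        b = seq[pos]
        a = rng.choice([x for x in DNA_ALPHABET if x != b])
        sites.append((int(pos), str(a), b))
    return ReferenceLocus(
        name=name,
        amplicon_seq=seq,
        key_region=(ws, we),
        poly_sites=tuple(sites),
        cut_site=ws + key_region_length // 2,
    )


#: diagnostic motifs planted by :func:`example_locus`
_SFOI = "GGCGCC"
_XBAI = "TCTAGA"
#: bases inserted by the 5 bp insertion template; preceded by a planted T
#: they create one new XbaI site
_INS5_BASES = "CTAGA"
_DEL9_OFFSET = -4  # deletion start relative to cut site
_INS5_OFFSET = -11  # insertion point relative to cut site


def example_locus(
    seed: int = 0,
    length: int = 550,
    key_region_length: int = 71,
    n_poly_sites: int = 3,
) -> ReferenceLocus:
    """A locus wired for the two built-in edit templates.

    One SfoI site (GGCGCC) spans the cut site and is destroyed by the 9 bp
    deletion template; the 5 bp insertion template creates exactly one new
    XbaI site (TCTAGA). The construction is rejection-sampled so neither
    wild-type background nor any template allele carries spurious copies of
    either motif.
    """
    rng = np.random.default_rng(seed)
    ws = (length - key_region_length) // 2
    we = ws + key_region_length
    cut = ws + key_region_length // 2
    del_start = cut + _DEL9_OFFSET
    ins_pos = cut + _INS5_OFFSET
    planted = set(range(ins_pos - 1, cut + 5))  # keep poly sites off planted bases
    for _attempt in range(500):
        seq = list(_random_seq(rng, length))
        seq[cut - 3 : cut + 3] = list(_SFOI)
        seq[ins_pos - 1] = "T"
        seq = "".join(seq)
        candidates = [p for p in range(ws, we) if p not in planted]
        positions = sorted(rng.choice(candidates, size=n_poly_sites, replace=False))
        sites = []
        for pos in positions:
            b = seq[pos]
            a = rng.choice([x for x in DNA_ALPHABET if x != b])
            sites.append((int(pos), str(a), b))
        locus = ReferenceLocus(
            name=f"example_locus_seed{seed}",
            amplicon_seq=seq,
            key_region=(ws, we),
            poly_sites=tuple(sites),
            cut_site=cut,
        )
        if _example_locus_ok(locus):
            return locus
    raise RuntimeError("failed to construct example locus; try another seed")


def _example_locus_ok(locus: ReferenceLocus) -> bool:
    cut = locus.cut_site
    for bg in ("A", "B"):
        wt = locus.wt_seq(bg)
        del9 = wt[: cut + _DEL9_OFFSET] + wt[cut + _DEL9_OFFSET + 9 :]
        ins5 = wt[: cut + _INS5_OFFSET] + _INS5_BASES + wt[cut + _INS5_OFFSET :]
        if wt.count(_SFOI) != 1 or wt.count(_XBAI) != 0:
            return False
        if del9.count(_SFOI) != 0 or del9.count(_XBAI) != 0:
            return False
        if ins5.count(_SFOI) != 1 or ins5.count(_XBAI) != 1:
            return False
    return True


def example_templates(locus: ReferenceLocus) -> List[EditSpec]:
    """The two built-in intended edits, instantiated on both backgrounds."""
    specs = []
    for bg in ("A", "B"):
        specs.append(
            EditSpec("DEL", locus.cut_site + _DEL9_OFFSET, length=9, background=bg, intended=True)
        )
        specs.append(
            EditSpec("INS", locus.cut_site + _INS5_OFFSET, bases=_INS5_BASES, background=bg, intended=True)
        )
    return specs


# ---------------------------------------------------------------------------
# Allele construction


def _apply_edit(seq: str, edit: EditSpec) -> str:
    n = len(seq)
    p = edit.position
    if edit.kind == "DEL":
        if p < 0 or p + edit.length > n:
            raise ValueError(f"deletion {edit} outside sequence of length {n}")
        return seq[:p] + seq[p + edit.length :]
    if edit.kind == "INS":
        if p < 0 or p > n:
            raise ValueError(f"insertion point {p} outside sequence of length {n}")
        return seq[:p] + edit.bases + seq[p:]
    if p < 0 or p >= n:
        raise ValueError(f"substitution position {p} outside sequence of length {n}")
    if seq[p] == edit.bases:
        raise ValueError(f"substitution at {p} does not change the base {edit.bases}")
    return seq[:p] + edit.bases + seq[p + 1 :]


def _edited_window(wt: str, locus: ReferenceLocus, edit: EditSpec) -> str:
    """Key-window sequence of the edited allele.

    Edits must lie fully inside or fully outside the window; straddling edits
    would make the extracted window ill-defined.
    """
    ws, we = locus.key_region
    p, L = edit.position, edit.length
    if edit.kind == "DEL":
        if ws <= p and p + L <= we:
            return wt[ws:p] + wt[p + L : we]
        if p + L <= ws:
            allele = _apply_edit(wt, edit)
            return allele[ws - L : we - L]
        if p >= we:
            return wt[ws:we]
        raise ValueError(f"deletion {edit} straddles the key window {locus.key_region}")
    if edit.kind == "INS":
        if ws < p < we:
            return wt[ws:p] + edit.bases + wt[p:we]
        if p <= ws:
            allele = _apply_edit(wt, edit)
            return allele[ws + L : we + L]
        return wt[ws:we]
    # SUB
    if ws <= p < we:
        w = list(wt[ws:we])
        w[p - ws] = edit.bases
        return "".join(w)
    return wt[ws:we]


def edit_label(wt: str, edit: EditSpec) -> str:
    """Human-readable allele label, e.g. '9 bp DEL-B' or 'A-T TV-A'."""
    if edit.kind == "DEL":
        core = f"{edit.length} bp DEL"
    elif edit.kind == "INS":
        core = f"{edit.length} bp INS"
    else:
        ref = wt[edit.position]
        kind = "TV" if is_transversion(ref, edit.bases) else "TS"
        core = f"{ref}-{edit.bases} {kind}"
    return f"{core}-{edit.background}"


def make_allele_set(locus: ReferenceLocus, edits: Sequence[EditSpec] = ()) -> List[AlleleSpec]:
    """WT-A and WT-B plus one allele per edit description.

    Intended edits become INTENDED_EDIT alleles; other DEL/INS edits become
    INDEL and SUB edits become POINT alleles. Labels follow the
    '<n> bp DEL-<bg>' / '<ref>-<alt> <TV|TS>-<bg>' convention.
    """
    ws, we = locus.key_region
    alleles = [
        AlleleSpec("WT-A", locus.wt_seq("A"), AlleleClass.WT_A, "A", None, locus.window_seq("A")),
        AlleleSpec("WT-B", locus.wt_seq("B"), AlleleClass.WT_B, "B", None, locus.window_seq("B")),
    ]
    for edit in edits:
        wt = locus.wt_seq(edit.background)
        seq = _apply_edit(wt, edit)
        window = _edited_window(wt, locus, edit)
        if edit.intended:
            cls = AlleleClass.INTENDED_EDIT
        elif edit.kind == "SUB":
            cls = AlleleClass.POINT
        else:
            cls = AlleleClass.INDEL
        alleles.append(
            AlleleSpec(edit_label(wt, edit), seq, cls, edit.background, edit, window)
        )
    return alleles


def intended_templates(locus: ReferenceLocus, edits: Sequence[EditSpec]) -> List[AlleleSpec]:
    """AlleleSpecs for the intended-edit templates only."""
    return [a for a in make_allele_set(locus, edits) if a.allele_class is AlleleClass.INTENDED_EDIT]


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class SimulatedReads:
    """Paired reads plus the per-pair ground-truth allele table."""

    r1: Tuple[FastqRecord, ...]
    r2: Tuple[FastqRecord, ...]
    truth: Tuple[Tuple[str, str], ...]  # (pair_id, allele label)

    def truth_counts(self) -> "dict[str, int]":
        counts: dict = {}
        for _pid, label in self.truth:
            counts[label] = counts.get(label, 0) + 1
        return counts


def _quality_profile(cfg: ReadSimConfig) -> np.ndarray:
    q = np.full(cfg.read_length, cfg.mean_quality, dtype=int)
    if cfg.tail_degradation is not None:
        n_tail, drop = cfg.tail_degradation
        n_tail = min(n_tail, cfg.read_length)
        for i in range(n_tail):
            q[cfg.read_length - n_tail + i] = max(2, cfg.mean_quality - drop * (i + 1))
    return q


_BASE_IDX = {b: i for i, b in enumerate(DNA_ALPHABET)}


def _mutate(seq: str, p_err: np.ndarray, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(seq)) < p_err[: len(seq)])
    if hits.size == 0:
        return seq
    s = list(seq)
    for i in hits:
        alt = [b for b in DNA_ALPHABET if b != s[i]]
        s[i] = alt[rng.integers(3)]
    return "".join(s)


def simulate_embryo_reads(
    mix: EmbryoMix, cfg: ReadSimConfig, locus: ReferenceLocus
) -> SimulatedReads:
    """Draw read pairs from the embryo's allele mixture.

    Read 1 covers the 5' end of the sequenced fragment; read 2 is the reverse
    complement of its 3' end. Substitution errors are injected per base with
    the probability given by the error model. Deterministic under mix.seed.
    """
    rng = np.random.default_rng(mix.seed)
    alleles = [a for a, _ in mix.allele_freqs]
    freqs = np.array([f for _, f in mix.allele_freqs], dtype=float)
    freqs = freqs / freqs.sum()

    frag_cap = 2 * cfg.read_length - cfg.min_overlap_generated
    min_survivable = cfg.read_length  # shorter fragments join below typical length cutoffs
    fragments = []
    for allele in alleles:
        flen = min(len(allele.seq), cfg.fragment_length, frag_cap)
        if flen < min_survivable:
            warnings.warn(
                f"allele {allele.label!r} yields fragments of {flen} bases; joined "
                f"reads may fail downstream length filters",
                stacklevel=2,
            )
        start = (len(allele.seq) - flen) // 2
        fragments.append(allele.seq[start : start + flen])

    qprof = _quality_profile(cfg)
    if cfg.error_rate is not None:
        p_err = np.full(cfg.read_length, cfg.error_rate)
    else:
        p_err = 10.0 ** (-qprof / 10.0)

    picks = rng.choice(len(alleles), size=mix.n_read_pairs, p=freqs)
    r1s, r2s, truth = [], [], []
    for i, k in enumerate(picks):
        frag = fragments[k]
        pair_id = f"{mix.embryo_id}:{i}"
        fwd = frag[: cfg.read_length]
        rev = revcomp(frag)[: cfg.read_length]
        fwd = _mutate(fwd, p_err, rng)
        rev = _mutate(rev, p_err, rng)
        r1s.append(FastqRecord(pair_id, fwd, tuple(int(q) for q in qprof[: len(fwd)])))
        r2s.append(FastqRecord(pair_id, rev, tuple(int(q) for q in qprof[: len(rev)])))
        truth.append((pair_id, alleles[k].label))
    return SimulatedReads(tuple(r1s), tuple(r2s), tuple(truth))
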