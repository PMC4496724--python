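"""End-to-end pipeline: trim, join, length-filter, map, enumerate, classify.

Stage counts are conserved at every boundary:
pairs_in = trimmed_empty + join_rejected + joined;
joined = length_removed + length_kept;
length_kept = unmapped + partial_span + windows.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from . import io as aio
from .classify import AlleleCall, EmbryoProfile, build_profile, classify_allele
from .core import FastqRecord, Rejection
from .mapping import AlignConfig, AlleleCount, align_read, enumerate_alleles, extract_window
from .readqc import JoinConfig, JoinedRead, TrimConfig, join_pair, length_filter, trim_record
from .simulate import AlleleSpec, ReferenceLocus


@dataclass(frozen=True)
class PipelineConfig:
    trim: TrimConfig = TrimConfig()
    join: JoinConfig = JoinConfig()
    align: AlignConfig = AlignConfig()
    report_threshold: float = 0.01
    biallelic_threshold: float = 96.0
    include_template_plus_subs: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.report_threshold < 1.0):
            raise ValueError("report_threshold must lie in [0, 1)")
        if not (0.0 < self.biallelic_threshold <= 100.0):
            raise ValueError("biallelic_threshold must lie in (0, 100]")


@dataclass
class RunResult:
    embryo_id: str
    profile: EmbryoProfile
    stage_log: Dict[str, int]
    reported_alleles: List[dict]  # one row per reported AlleleCount, with its call


def process_pairs(
    r1: Sequence[FastqRecord],
    r2: Sequence[FastqRecord],
    locus: ReferenceLocus,
    templates: Sequence[AlleleSpec] = (),
    cfg: PipelineConfig = PipelineConfig(),
    embryo_id: str = "embryo",
) -> RunResult:
    """Run all stages on in-memory read pairs and build the embryo profile.

    Every distinct window sequence is classified and enters the profile; the
    ``report_threshold`` governs only which rows appear in the reported
    allele table (wild-type rows are always reported).
    """
    if len(r1) != len(r2):
        raise ValueError(f"R1 has {len(r1)} reads but R2 has {len(r2)}")
    log: Dict[str, int] = {"pairs_in": len(r1)}

    joined: List[JoinedRead] = []
    trimmed_empty = 0
    join_rejected = 0
    for a, b in zip(r1, r2):
        ta, tb = trim_record(a, cfg.trim), trim_record(b, cfg.trim)
        if len(ta) == 0 or len(tb) == 0:
            trimmed_empty += 1
            continue
        res = join_pair(ta, tb, cfg.join)
        if isinstance(res, Rejection):
            join_rejected += 1
        else:
            joined.append(res)
    log["trimmed_empty"] = trimmed_empty
    log["join_rejected"] = join_rejected
    log["joined"] = len(joined)

    kept, removed = length_filter(joined, cfg.join)
    log["length_removed"] = removed
    log["length_kept"] = len(kept)

    # deduplicate before aligning: identical joined sequences map identically
    seq_counts = Counter(read.seq for read in kept)
    window_of: Dict[str, object] = {}
    for seq in seq_counts:
        aln = align_read(JoinedRead("u", seq, tuple([30] * len(seq)), overlap_len=len(seq)), locus, cfg.align)
        if isinstance(aln, Rejection):
            window_of[seq] = aln
        else:
            window_of[seq] = extract_window(aln, locus, cfg.align.require_full_window_span)

    unmapped = partial = 0
    window_counts: Counter = Counter()
    for seq, n in seq_counts.items():
        res = window_of[seq]
        if isinstance(res, Rejection):
            if res.reason == "UNMAPPED":
                unmapped += n
            else:
                partial += n
        else:
            window_counts[res] += n
    log["unmapped"] = unmapped
    log["partial_span"] = partial
    n_windows = sum(window_counts.values())
    log["windows"] = n_windows

    if n_windows == 0:
        raise ValueError(f"embryo {embryo_id!r}: no reads survived to window extraction")

    # classify every distinct window sequence; profile aggregates all reads
    def _classify(seq: str) -> AlleleCall:
        if not seq:  # whole window deleted
            from .classify import EditCall
            from .simulate import AlleleClass

            n = locus.window_length
            return AlleleCall(
                seq,
                AlleleClass.INDEL,
                "ambiguous",
                f"{n} bp DEL-ambiguous",
                (EditCall("DEL", 0, n),),
            )
        return classify_allele(
            seq, locus, templates, include_template_plus_subs=cfg.include_template_plus_subs
        )

    calls: Dict[str, AlleleCall] = {seq: _classify(seq) for seq in window_counts}
    all_counts = [
        AlleleCount(seq, n, n / n_windows)
        for seq, n in sorted(window_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    profile = build_profile(
        all_counts,
        [calls[c.seq] for c in all_counts],
        embryo_id=embryo_id,
        biallelic_threshold=cfg.biallelic_threshold,
    )

    reported = enumerate_alleles(
        window_counts.elements(), n_windows, locus, cfg.report_threshold
    )
    reported_rows = []
    for row in reported:
        call = calls.get(row.seq)
        if call is None:  # wild-type row reported at count 0
            call = classify_allele(row.seq, locus, templates)
        reported_rows.append(
            {
                "seq": row.seq,
                "count": row.count,
                "fraction": round(row.fraction, 6),
                "label": call.label,
                "allele_class": call.allele_class.value,
            }
        )
    return RunResult(embryo_id, profile, log, reported_rows)


def run_pipeline(
    r1_path,
    r2_path,
    locus_path,
    cfg: PipelineConfig = PipelineConfig(),
    embryo_id: Optional[str] = None,
) -> RunResult:
    """File-based entry point: FASTQ pair + locus YAML (with edit templates)."""
    from .simulate import intended_templates

    locus, edits = aio.read_locus_yaml(locus_path)
    templates = intended_templates(locus, edits)
    r1 = aio.read_fastq(r1_path)
    r2 = aio.read_fastq(r2_path)
    if embryo_id is None:
        embryo_id = Path(str(r1_path)).name.split(".")[0]
    return process_pairs(r1, r2, locus, templates, cfg, embryo_id=embryo_id)


# ---------------------------------------------------------------------------
# reports


def profile_to_dict(profile: EmbryoProfile) -> dict:
    return {
        "embryo_id": profile.embryo_id,
        "pct_intended": round(profile.pct_intended, 6),
        "pct_wt": round(profile.pct_wt, 6),
        "pct_other": round(profile.pct_other, 6),
        "mosaicism_call": profile.mosaicism_call.value,
        "n_alleles": len(profile.calls),
    }


def result_to_dict(result: RunResult) -> dict:
    return {
        "embryo_id": result.embryo_id,
        "profile": profile_to_dict(result.profile),
        "stage_log": dict(result.stage_log),
        "reported_alleles": result.reported_alleles,
    }


ALLELE_COLUMNS = ("seq", "count", "fraction", "label", "allele_class")


def write_report(results: Sequence[RunResult], out_dir, stats: Optional[dict] = None) -> dict:
    """Write report.json, alleles.tsv and summary.txt; returns the JSON payload.

    The JSON payload round-trips: loading it and re-writing produces
    byte-identical output.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "results": [result_to_dict(r) for r in results],
        "stats": stats or {},
    }
    aio.write_json(payload, out_dir / "report.json")

    rows = []
    for r in results:
        for row in r.reported_alleles:
            rows.append({"embryo_id": r.embryo_id, **row})
    aio.write_tsv(rows, out_dir / "alleles.tsv", ("embryo_id",) + ALLELE_COLUMNS)

    with open(out_dir / "summary.txt", "w") as fh:
        for r in results:
            p = r.profile
            fh.write(
                f"{r.embryo_id}: intended {p.pct_intended:.2f}% | wild-type {p.pct_wt:.2f}% | "
                f"other {p.pct_other:.2f}% -> {p.mosaicism_call.value}\n"
            )
    return payload
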