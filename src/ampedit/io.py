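"""File I/O: FASTQ/FASTA via Biopython, locus/template YAML, TSV tables."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import IO, Dict, Iterable, List, Sequence, Tuple, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import FastqRecord
from .simulate import EditSpec, ReferenceLocus

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: PathLike) -> List[FastqRecord]:
    """Parse a (optionally gzipped) FASTQ file.

    Malformed input raises a ValueError naming the offending record.
    """
    records = []
    with _open_text(path, "r") as handle:
        parser = SeqIO.parse(handle, "fastq")
        i = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"FASTQ parse error in {path} at record {i + 1} "
                    f"(near line {4 * i + 1}): {exc}"
                ) from exc
            records.append(
                FastqRecord(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
            )
            i += 1
    return records


def write_fastq(records: Iterable[FastqRecord], path: PathLike) -> None:
    seq_records = []
    for r in records:
        sr = SeqRecord(Seq(r.seq), id=r.id, description="")
        sr.letter_annotations["phred_quality"] = list(r.quals)
        seq_records.append(sr)
    with _open_text(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fastq")


def write_fasta(name: str, seq: str, path: PathLike) -> None:
    with _open_text(path, "w") as handle:
        SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], handle, "fasta")


def read_fasta(path: PathLike) -> Tuple[str, str]:
    """Read the first record of a FASTA file as (name, sequence)."""
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            return rec.id, str(rec.seq).upper()
    raise ValueError(f"no FASTA records in {path}")


# ---------------------------------------------------------------------------
# locus / template YAML


def locus_to_dict(locus: ReferenceLocus) -> dict:
    return {
        "name": locus.name,
        "amplicon_seq": locus.amplicon_seq,
        "key_region": list(locus.key_region),
        "poly_sites": [[p, a, b] for p, a, b in locus.poly_sites],
        "cut_site": locus.cut_site,
    }


def locus_from_dict(d: dict) -> ReferenceLocus:
    return ReferenceLocus(
        name=d["name"],
        amplicon_seq=d["amplicon_seq"],
        key_region=tuple(d["key_region"]),
        poly_sites=tuple((int(p), a, b) for p, a, b in d["poly_sites"]),
        cut_site=int(d.get("cut_site", -1)),
    )


def edit_to_dict(edit: EditSpec) -> dict:
    return {
        "kind": edit.kind,
        "position": edit.position,
        "length": edit.length,
        "bases": edit.bases,
        "background": edit.background,
        "intended": edit.intended,
    }


def edit_from_dict(d: dict) -> EditSpec:
    return EditSpec(
        kind=d["kind"],
        position=int(d["position"]),
        length=int(d.get("length", 0)),
        bases=d.get("bases", ""),
        background=d.get("background", "B"),
        intended=bool(d.get("intended", False)),
    )


def write_locus_yaml(locus: ReferenceLocus, path: PathLike, edits: Sequence[EditSpec] = ()) -> None:
    doc = {"locus": locus_to_dict(locus)}
    if edits:
        doc["edits"] = [edit_to_dict(e) for e in edits]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_locus_yaml(path: PathLike) -> Tuple[ReferenceLocus, List[EditSpec]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    locus = locus_from_dict(doc["locus"])
    edits = [edit_from_dict(d) for d in doc.get("edits", [])]
    return locus, edits


# ---------------------------------------------------------------------------
# simple tables


def write_tsv(rows: Sequence[dict], path: PathLike, columns: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_tsv(path: PathLike) -> List[Dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: PathLike):
    with open(path) as fh:
        return json.load(fh)
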