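"""Readers and writers for the standard formats the tool touches.

FASTA/FASTQ (optionally gzipped) via Biopython, SAM/BAM via pysam, result
objects as JSON or TSV.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pysam
from Bio import SeqIO

__all__ = ["ReadRecord", "read_sequences", "read_alignments", "write_results",
           "write_fastq", "write_truth_table"]

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read, optionally with its alignment."""

    id: str
    sequence: str
    qualities: str | None = None
    chrom: str | None = None
    pos: int | None = None  # 0-based leftmost aligned reference position
    cigar: tuple[tuple[int, int], ...] | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - _VALID
        if bad:
            raise ValueError(f"read {self.id}: invalid symbol(s) {sorted(bad)}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    name = path.name.removesuffix(".gz").lower()
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    with _open_text(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise ValueError(f"{path}: cannot determine sequence format")


def read_sequences(path: str | Path) -> Iterator[ReadRecord]:
    """Lazily yield reads from a FASTA/FASTQ file (gz-aware, autodetected)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path)
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = None
            if fmt == "fastq":
                quals = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            yield ReadRecord(id=rec.id, sequence=str(rec.seq).upper(), qualities=quals)


def read_alignments(
    path: str | Path, region: tuple[str, int, int] | None = None
) -> Iterator[ReadRecord]:
    """Yield aligned reads overlapping ``region`` from an indexed SAM/BAM.

    ``region`` is (chrom, start, end) 0-based half-open; None iterates all
    mapped reads.  Sequences are returned as stored (the aligned, i.e.
    forward-reference, orientation) with the original strand reported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mode = "r" if path.suffix == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        if region is not None:
            chrom, start, end = region
            it = bam.fetch(chrom, start, end)
        else:
            it = (a for a in bam if not a.is_unmapped)
        for aln in it:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            yield ReadRecord(
                id=aln.query_name,
                sequence=aln.query_sequence.upper(),
                qualities=None,
                chrom=aln.reference_name,
                pos=aln.reference_start,
                cigar=tuple(aln.cigartuples or ()),
                strand="-" if aln.is_reverse else "+",
            )


def _to_jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _to_jsonable(obj.to_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_results(result, path: str | Path, fmt: str = "json") -> None:
    """Write a result object as JSON (round-trippable) or flat TSV."""
    path = Path(path)
    payload = _to_jsonable(result)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return
    if fmt == "tsv":
        flat = _flatten(payload)
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in flat.items():
                fh.write(f"{k}\t{v}\n")
        return
    raise ValueError(f"unknown format {fmt!r} (expected 'json' or 'tsv')")


def _flatten(obj, prefix: str = "") -> dict[str, object]:
    out: dict[str, object] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}." if prefix else f"{k}."))
    elif isinstance(obj, list):
        for idx, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}{idx}."))
    else:
        out[prefix.rstrip(".")] = obj
    return out


def write_fastq(reads, path: str | Path) -> None:
    """Write simulated reads as FASTQ with a uniform placeholder quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def write_truth_table(participants, path: str | Path) -> None:
    """Truth TSV: read_id, allele, tract bounds, true count, participant."""
    with open(path, "w") as fh:
        fh.write("read_id\tparticipant\tallele\ttract_start\ttract_end\ttrue_count\n")
        for part in participants:
            for read in part.reads:
                fh.write(
                    f"{read.read_id}\t{part.participant_id}\t{read.allele}\t"
                    f"{read.tract_start}\t{read.tract_end}\t{read.true_count}\n"
                )
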