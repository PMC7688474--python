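"""Reference-sequence I/O, 16S extraction from annotated genomes, QC filters."""

from __future__ import annotations

import math
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import has_ambiguous, reverse_complement
from .taxonomy import Lineage, SourceAnnotation

TARGET_PRODUCT = "16S ribosomal RNA"


@dataclass
class ReferenceRecord:
    """A 16S sequence with its source lineage and refreshed 7-rank lineage."""

    id: str
    sequence: str
    source_db: str = ""
    source_annotation: Optional[SourceAnnotation] = None
    lineage: Optional[Lineage] = None
    strand: str = "+"
    status: str = "ok"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LengthFilterPolicy:
    """k-sd length window: 3 for full-length databases, 2 for region fragments."""

    k_sd: float = 3.0
    mode: str = "two_sided"

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be positive")
        if self.mode not in {"two_sided", "upper_only"}:
            raise ValueError(f"unknown filter mode {self.mode!r}")


def read_fasta(path: str | Path, source_db: str = "") -> list[ReferenceRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ReferenceRecord(id=rec.id, sequence=str(rec.seq).upper(),
                            source_db=source_db)
        )
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def extract_16s_from_genome(
    gff_path: str | Path, genome_fasta_path: str | Path
) -> list[ReferenceRecord]:
    """Extract features typed rRNA with product "16S ribosomal RNA".

    GFF3 coordinates are 1-based inclusive; minus-strand features are
    reverse-complemented. The product comparison is exact and case-sensitive.
    """
    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(genome_fasta_path), "fasta")}
    out: list[ReferenceRecord] = []
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gff_path}: line {lineno}: expected 9 columns, "
                    f"got {len(fields)}"
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != "rRNA":
                continue
            attrs = _parse_gff_attributes(attrs_s)
            if attrs.get("product") != TARGET_PRODUCT:
                continue
            if seqid not in genome:
                raise ValueError(
                    f"{gff_path}: line {lineno}: feature references unknown "
                    f"sequence {seqid!r}"
                )
            start, end = int(start_s), int(end_s)
            if start < 1 or end > len(genome[seqid]) or start > end:
                raise ValueError(
                    f"{gff_path}: line {lineno}: coordinates {start}..{end} out "
                    f"of bounds for {seqid!r} (length {len(genome[seqid])})"
                )
            subseq = genome[seqid][start - 1:end]
            if strand == "-":
                subseq = reverse_complement(subseq)
            feature_id = attrs.get("ID", f"{seqid}_{start}_{end}")
            out.append(
                ReferenceRecord(
                    id=f"{feature_id}|{seqid}:{start}-{end}({strand})",
                    sequence=subseq,
                    source_db="genome",
                    strand=strand if strand in "+-" else "+",
                )
            )
    return out


def length_stats(records: Sequence) -> tuple[float, float]:
    """Mean and population standard deviation of sequence lengths."""
    if len(records) < 2:
        raise ValueError("length statistics require at least 2 records")
    lengths = [len(r.sequence) for r in records]
    mean = sum(lengths) / len(lengths)
    var = sum((x - mean) ** 2 for x in lengths) / len(lengths)
    return mean, math.sqrt(var)


def qc_filter(
    records: Sequence,
    policy: LengthFilterPolicy = LengthFilterPolicy(),
    stats: Optional[tuple[float, float]] = None,
) -> tuple[list, list]:
    """Split records into (kept, dropped).

    Any record containing an ambiguous nucleotide is dropped regardless of
    length. The length window is closed: len == mean +/- k*sd is kept.
    """
    if stats is None:
        stats = length_stats(records)
    mean, sd = stats
    low = mean - policy.k_sd * sd
    high = mean + policy.k_sd * sd
    kept, dropped = [], []
    for record in records:
        n = len(record.sequence)
        bad_length = n > high or (policy.mode == "two_sided" and n < low)
        if bad_length or has_ambiguous(record.sequence):
            dropped.append(record)
        else:
            kept.append(record)
    return kept, dropped
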