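"""Paired-end merging by overlap, and merged-read QC.

Overlap merging follows the FLASH contract: candidate overlaps between the
forward read and the reverse-complemented reverse read are scored by mismatch
ratio; the best (lowest ratio, ties -> longest overlap) is accepted when the
ratio is within the policy. At overlap mismatches the base with the higher
Phred score wins (ties -> forward base).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from ._dna import reverse_complement
from .reference_io import LengthFilterPolicy, qc_filter


@dataclass(frozen=True)
class ReadPair:
    id: str
    forward_seq: str
    forward_qual: Sequence[int]
    reverse_seq: str
    reverse_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.forward_seq) != len(self.forward_qual):
            raise ValueError(f"{self.id}: forward seq/qual length mismatch")
        if len(self.reverse_seq) != len(self.reverse_qual):
            raise ValueError(f"{self.id}: reverse seq/qual length mismatch")


@dataclass(frozen=True)
class MergePolicy:
    min_overlap: int = 20
    max_overlap: int = 300
    max_mismatch_ratio: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= self.max_overlap:
            raise ValueError("require 0 < min_overlap <= max_overlap")


@dataclass(frozen=True)
class MergedRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]
    overlap: int
    mismatches: int


def merge_pair(pair: ReadPair, policy: MergePolicy = MergePolicy()) -> Optional[MergedRead]:
    """Merge a read pair; returns None on failure."""
    if not pair.forward_seq or not pair.reverse_seq:
        raise ValueError("reads must be nonempty")
    fwd = pair.forward_seq.upper()
    rev = reverse_complement(pair.reverse_seq.upper())
    rev_qual = tuple(reversed(pair.reverse_qual))
    max_ov = min(policy.max_overlap, len(fwd), len(rev))
    fa = np.frombuffer(fwd.encode("ascii"), dtype=np.uint8)
    ra = np.frombuffer(rev.encode("ascii"), dtype=np.uint8)
    best: Optional[tuple[float, int, int]] = None  # (ratio, -overlap, mismatches)
    for ov in range(policy.min_overlap, max_ov + 1):
        mm = int((fa[len(fwd) - ov:] != ra[:ov]).sum())
        key = (mm / ov, -ov, mm)
        if best is None or key < best:
            best = key
    if best is None or best[0] > policy.max_mismatch_ratio:
        return None
    _ratio, neg_ov, mm = best
    ov = -neg_ov
    split = len(fwd) - ov
    seq_chars = list(fwd[:split])
    quals = list(pair.forward_qual[:split])
    for k in range(ov):
        fb, fq = fwd[split + k], pair.forward_qual[split + k]
        rb, rq = rev[k], rev_qual[k]
        if fb == rb:
            seq_chars.append(fb)
            quals.append(max(fq, rq))
        elif rq > fq:
            seq_chars.append(rb)
            quals.append(rq)
        else:
            seq_chars.append(fb)
            quals.append(fq)
    seq_chars.extend(rev[ov:])
    quals.extend(rev_qual[ov:])
    return MergedRead(
        id=pair.id,
        sequence="".join(seq_chars),
        qualities=tuple(quals),
        overlap=ov,
        mismatches=mm,
    )


def merged_qc(reads: Sequence, region_stats: tuple[float, float]) -> list:
    """Drop merged reads containing ambiguous bases or longer than mean + 2*sd.

    Only the upper length bound is enforced (upper_only), exactly as printed
    for merged fragments; the default V3-V4 stats are (421, 11).
    """
    kept, _dropped = qc_filter(
        reads, LengthFilterPolicy(k_sd=2.0, mode="upper_only"), stats=region_stats
    )
    return kept


def read_paired_fastq(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Read two synchronized FASTQ files into ReadPairs (ids from R1)."""
    fwd = list(SeqIO.parse(str(r1_path), "fastq"))
    rev = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(fwd) != len(rev):
        raise ValueError(
            f"paired FASTQ files differ in length: {len(fwd)} vs {len(rev)}"
        )
    pairs = []
    for f, r in zip(fwd, rev):
        pairs.append(
            ReadPair(
                id=f.id,
                forward_seq=str(f.seq).upper(),
                forward_qual=tuple(f.letter_annotations["phred_quality"]),
                reverse_seq=str(r.seq).upper(),
                reverse_qual=tuple(r.letter_annotations["phred_quality"]),
            )
        )
    return pairs


def write_merged_fasta(reads: Sequence[MergedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f">{read.id}\n{read.sequence}\n")
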