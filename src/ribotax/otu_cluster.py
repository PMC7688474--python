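"""Greedy identity-threshold OTU clustering and taxonomic separability.

Sequences are processed longest-first (ties keep input order); each joins the
existing cluster whose representative is most similar among those at or above
the threshold, else founds a new cluster. Identity is identical aligned
positions over the length of the shorter sequence (cd-hit convention), with
the shared scorer (free end gaps).

A q-gram prefilter is applied before alignment: by the q-gram lemma an
alignment with at most e non-matching columns destroys at most q*e of the
shorter sequence's q-grams, so pairs sharing too few 8-mers are provably below
the threshold and can be skipped without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import math

import pandas as pd

from ._align import align as align_fn

_Q = 8


@dataclass
class OTU:
    otu_id: str
    representative: str
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def pair_identity(a: str, b: str, band: Optional[int] = None) -> float:
    """Fraction in [0,1]: aligned identical positions / shorter length.

    With a band the value is exact whenever it is >= 1 - (band - 8)/min(len)
    (see _align.align); more-divergent pairs may be underestimated, which is
    safe for thresholded decisions at or above that identity.
    """
    result = align_fn(a, b, band=band)
    return result.n_matches / min(len(a), len(b))


def _auto_band(threshold: float, short_len: int) -> int:
    return int(math.ceil((1.0 - threshold) * short_len)) + 8


def _qgrams(seq: str, q: int = _Q) -> set[str]:
    return {seq[i:i + q] for i in range(len(seq) - q + 1)}


def _prefilter_ok(
    q_set: set[str], r_set: set[str], short_len: int, len_diff: int, threshold: float
) -> bool:
    """True if the pair may still reach the identity threshold.

    Identity >= t over the shorter length allows at most
    e = floor((1 - t) * short) + len_diff non-matching columns against the
    shorter sequence; each destroys at most q of its q-grams.
    """
    if short_len < 2 * _Q:
        return True  # too short for the bound to be meaningful
    e_allow = math.floor((1.0 - threshold) * short_len) + len_diff + 1
    min_shared = (short_len - _Q + 1) - _Q * e_allow
    if min_shared <= 0:
        return True
    return len(q_set & r_set) >= min_shared


def greedy_cluster(
    seqs: Sequence[tuple[str, str]],
    threshold: float = 0.99,
    assign: str = "most_similar",
    prefilter: bool = True,
) -> list[OTU]:
    """Cluster (id, sequence) pairs into OTUs at the identity threshold."""
    if not seqs:
        raise ValueError("greedy_cluster requires at least one sequence")
    if assign != "most_similar":
        raise ValueError(f"unknown assignment mode {assign!r}")
    order = sorted(range(len(seqs)), key=lambda i: -len(seqs[i][1]))
    clusters: list[OTU] = []
    rep_grams: list[set[str]] = []
    gram_cache: dict[str, set[str]] = {}
    identity_cache: dict[tuple[str, int], float] = {}
    for i in order:
        read_id, seq = seqs[i]
        if prefilter:
            grams = gram_cache.get(seq)
            if grams is None:
                grams = _qgrams(seq)
                gram_cache[seq] = grams
        else:
            grams = set()
        best_cluster: Optional[int] = None
        best_identity = -1.0
        for ci, otu in enumerate(clusters):
            rep = otu.representative
            if seq == rep:
                identity = 1.0
            else:
                identity = identity_cache.get((seq, ci))
                if identity is None:
                    short = min(len(seq), len(rep))
                    diff = abs(len(seq) - len(rep))
                    if prefilter and not _prefilter_ok(
                        grams, rep_grams[ci], short, diff, threshold
                    ):
                        identity = -1.0  # provably below threshold
                    else:
                        identity = pair_identity(
                            seq, rep, band=_auto_band(threshold, short)
                        )
                    identity_cache[(seq, ci)] = identity
            # earliest-founded cluster wins ties (strict > keeps the first)
            if identity >= threshold and identity > best_identity:
                best_identity = identity
                best_cluster = ci
        if best_cluster is None:
            clusters.append(
                OTU(otu_id=f"OTU{len(clusters) + 1:05d}", representative=seq,
                    member_ids=[read_id])
            )
            rep_grams.append(grams)
        else:
            clusters[best_cluster].member_ids.append(read_id)
    return clusters


@dataclass
class OTUTable:
    """OTU x sample count matrix plus representative sequences."""

    counts: pd.DataFrame  # index: otu_id, columns: sample
    representatives: dict[str, str]

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_otu_table(
    clusters: Sequence[OTU], read_to_sample: Mapping[str, Hashable]
) -> OTUTable:
    """Count cluster members per sample; every read must map to a sample."""
    samples = sorted(set(read_to_sample.values()))
    rows = {}
    for otu in clusters:
        counts = {s: 0 for s in samples}
        for read_id in otu.member_ids:
            if read_id not in read_to_sample:
                raise ValueError(f"read {read_id!r} has no sample mapping")
            counts[read_to_sample[read_id]] += 1
        rows[otu.otu_id] = counts
    counts_df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    counts_df = counts_df.reindex(columns=samples)
    counts_df.index.name = "otu_id"
    return OTUTable(
        counts=counts_df,
        representatives={o.otu_id: o.representative for o in clusters},
    )


def separability(
    labeled_seqs: Sequence,
    rank: str = "species",
    threshold: float = 0.99,
) -> float:
    """Fraction of OTUs containing >= 2 distinct labels at the given rank.

    Items are either (id, sequence, label) tuples or objects with id,
    sequence and a taxonomy.Lineage in .lineage (label taken at `rank`).
    """
    ids_seqs: list[tuple[str, str]] = []
    label_of: dict[str, Optional[str]] = {}
    for item in labeled_seqs:
        if isinstance(item, tuple):
            item_id, seq, label = item
        else:
            item_id, seq = item.id, item.sequence
            if item.lineage is None:
                raise ValueError(f"record {item_id!r} lacks a lineage")
            label = item.lineage.get(rank)
        if label is None:
            raise ValueError(f"record {item_id!r} is unlabeled at rank {rank!r}")
        ids_seqs.append((item_id, seq))
        label_of[item_id] = label
    clusters = greedy_cluster(ids_seqs, threshold=threshold)
    n_multi = sum(
        1 for otu in clusters
        if len({label_of[m] for m in otu.member_ids}) >= 2
    )
    return n_multi / len(clusters)
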