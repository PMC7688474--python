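"""End-to-end profiling: merge -> filter -> cluster -> classify -> assign -> profile."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consensus_groups import HomologousSpeciesGroup, SpeciesConsensus
from .nb_classifier import (
    ClassifierModel,
    RankAssignment,
    apply_confidence_threshold,
    classify,
)
from .otu_cluster import OTUTable, build_otu_table, greedy_cluster
from .read_preprocess import MergePolicy, ReadPair, merge_pair, merged_qc
from .species_assign import UNCLASSIFIED, SpeciesCall, assign_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionProfile:
    """Taxon (or group) label -> relative abundance, plus an unclassified bin."""

    rank: str
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        total = sum(self.abundances.values())
        if self.abundances and not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"abundances must sum to 1 (got {total})")


@dataclass(frozen=True)
class PipelineConfig:
    merge_policy: MergePolicy = field(default_factory=MergePolicy)
    region_stats: tuple[float, float] = (421.0, 11.0)  # V3-V4 printed stats
    otu_threshold: float = 0.99
    species_min_identity: float = 97.0
    species_max_evalue: float = 1e-10
    use_evalue: bool = True
    confidence_threshold: float = 0.8
    n_bootstrap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.otu_threshold <= 1:
            raise ValueError("otu_threshold must be in (0, 1]")
        if not 0 <= self.species_min_identity <= 100:
            raise ValueError("species_min_identity must be in [0, 100]")
        if not 0 <= self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in [0, 1]")


@dataclass
class ReferenceBundle:
    classifier: ClassifierModel
    consensus_db: Sequence[SpeciesConsensus]
    groups: Sequence[HomologousSpeciesGroup]

    def validate(self) -> None:
        if self.classifier is None:
            raise ValueError("reference bundle is missing the classifier model")
        if not self.consensus_db:
            raise ValueError("reference bundle has an empty consensus database")
        if self.groups is None:
            raise ValueError("reference bundle is missing the species groups")


@dataclass
class ProfileResult:
    otu_table: OTUTable
    genus_assignments: dict[str, RankAssignment]
    species_calls: dict[str, SpeciesCall]
    profiles: dict[str, dict[str, CompositionProfile]]  # rank -> sample -> profile
    stage_counts: dict[str, int]


def relative_abundance(
    otu_table: OTUTable,
    calls: Mapping[str, str],
    rank: str,
) -> dict[str, CompositionProfile]:
    """Per-sample composition: sum of OTU sizes per label over total reads.

    `calls` maps otu_id -> label; missing or falsy labels pool into the
    unclassified bin. Samples with zero reads get a 100% unclassified bin.
    """
    missing = set(otu_table.counts.index) - set(calls)
    if missing:
        raise ValueError(f"calls missing for OTUs: {sorted(missing)[:5]}")
    profiles: dict[str, CompositionProfile] = {}
    for sample in otu_table.counts.columns:
        column = otu_table.counts[sample]
        total = int(column.sum())
        sums: dict[str, float] = {}
        for otu_id, count in column.items():
            if count == 0:
                continue
            label = calls[otu_id] or UNCLASSIFIED
            sums[label] = sums.get(label, 0) + int(count)
        if total == 0:
            abundances = {UNCLASSIFIED: 1.0}
        else:
            abundances = {t: c / total for t, c in sums.items()}
            drift = 1.0 - sum(abundances.values())
            first = next(iter(abundances))
            abundances[first] += drift
        profiles[sample] = CompositionProfile(rank=rank, abundances=abundances)
    return profiles


def run_profile(
    samples: Mapping[str, Sequence[ReadPair]],
    bundle: ReferenceBundle,
    config: PipelineConfig = PipelineConfig(),
) -> ProfileResult:
    """Profile paired-end samples against a reference bundle.

    Every read is accounted for: input = merge-failed + qc-dropped + clustered.
    """
    bundle.validate()
    merged_all: list = []
    read_to_sample: dict[str, str] = {}
    n_input = n_merge_failed = n_qc_dropped = 0
    for sample, pairs in samples.items():
        merged = []
        for pair in pairs:
            n_input += 1
            result = merge_pair(pair, config.merge_policy)
            if result is None:
                n_merge_failed += 1
            else:
                merged.append(result)
        kept = merged_qc(merged, config.region_stats)
        n_qc_dropped += len(merged) - len(kept)
        for read in kept:
            qualified = f"{sample}/{read.id}"
            read_to_sample[qualified] = sample
            merged_all.append((qualified, read.sequence))
    logger.info(
        "preprocess: %d pairs in, %d merge failures, %d QC-dropped, %d kept",
        n_input, n_merge_failed, n_qc_dropped, len(merged_all),
    )
    if not merged_all:
        empty = OTUTable(
            counts=pd.DataFrame(columns=sorted(samples), index=[], dtype=int),
            representatives={},
        )
        return ProfileResult(
            otu_table=empty,
            genus_assignments={},
            species_calls={},
            profiles={
                "genus": {
                    s: CompositionProfile(rank="genus", abundances={UNCLASSIFIED: 1.0})
                    for s in samples
                },
                "species": {
                    s: CompositionProfile(rank="species", abundances={UNCLASSIFIED: 1.0})
                    for s in samples
                },
            },
            stage_counts={
                "input": n_input,
                "merge_failed": n_merge_failed,
                "qc_dropped": n_qc_dropped,
                "clustered": 0,
            },
        )
    clusters = greedy_cluster(merged_all, threshold=config.otu_threshold)
    n_clustered = sum(o.size for o in clusters)
    assert n_input == n_merge_failed + n_qc_dropped + n_clustered
    otu_table = build_otu_table(clusters, read_to_sample)

    genus_assignments: dict[str, RankAssignment] = {}
    for otu in clusters:
        assignment = classify(
            bundle.classifier,
            otu.representative,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
        )
        genus_assignments[otu.otu_id] = apply_confidence_threshold(
            assignment, config.confidence_threshold
        )
    species_calls = {
        call.otu_id: call
        for call in assign_all(
            [(o.otu_id, o.representative) for o in clusters],
            bundle.consensus_db,
            bundle.groups,
            min_identity=config.species_min_identity,
            max_evalue=config.species_max_evalue,
            use_evalue=config.use_evalue,
        )
    }
    genus_labels = {
        otu_id: (a.genus or UNCLASSIFIED) for otu_id, a in genus_assignments.items()
    }
    species_labels = {otu_id: c.label for otu_id, c in species_calls.items()}
    profiles = {
        "genus": relative_abundance(otu_table, genus_labels, "genus"),
        "species": relative_abundance(otu_table, species_labels, "species"),
    }
    return ProfileResult(
        otu_table=otu_table,
        genus_assignments=genus_assignments,
        species_calls=species_calls,
        profiles=profiles,
        stage_counts={
            "input": n_input,
            "merge_failed": n_merge_failed,
            "qc_dropped": n_qc_dropped,
            "clustered": n_clustered,
        },
    )
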