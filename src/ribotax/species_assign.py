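"""k-nearest-neighbor species assignment against the consensus database.

Every OTU representative is aligned exhaustively against every species
consensus (the databases are small, so no seeding heuristics); hits must pass
a strict >97% identity gate and an e-value gate computed from a Karlin-Altschul
surrogate. The best hit's species is reported; species belonging to a
multi-member homologous species group are reported under the group label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._align import align as _align
from .consensus_groups import (
    HomologousSpeciesGroup,
    SpeciesConsensus,
    group_label_map,
)

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

#: Karlin-Altschul parameters for the +1/-2 nucleotide scheme
DEFAULT_LAMBDA = 0.625
DEFAULT_K = 0.41


@dataclass(frozen=True)
class SpeciesCall:
    otu_id: str
    label: str
    best_identity: float
    n_tied_best: int
    evalue: float = math.inf


def evalue_surrogate(
    score: float,
    query_len: int,
    db_len: int,
    lam: float = DEFAULT_LAMBDA,
    k: float = DEFAULT_K,
) -> float:
    """E = K * m * n * exp(-lambda * S').

    `score` is the alignment score already rescaled to the +1/-2 scheme
    (matches - 2*mismatches - 2*internal gap columns); monotone decreasing
    in score, linear in both lengths.
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    return k * query_len * db_len * math.exp(-lam * score)


def rescaled_score(result) -> float:
    """Rescale an AlignmentResult to the +1/-2 scheme for the e-value gate."""
    internal_gaps = result.n_gap_columns - result.n_end_gap_columns
    return result.n_matches - 2.0 * result.n_mismatches - 2.0 * internal_gaps


def knn_species(
    otu_id: str,
    query: str,
    consensus_db: Sequence[SpeciesConsensus],
    groups: Iterable[HomologousSpeciesGroup],
    k: int = 1,
    min_identity: float = 97.0,
    max_evalue: float = 1e-10,
    use_evalue: bool = True,
) -> SpeciesCall:
    """Nearest-neighbor species call for one query sequence.

    Ties among equal-best species in one group resolve to the group label;
    ties spanning groups take the lexicographically smallest group label and
    record the tie count.
    """
    if not consensus_db:
        raise ValueError("consensus database is empty")
    if k != 1:
        raise ValueError("only k=1 is supported")
    labels = group_label_map(groups)
    db_len = sum(len(c.consensus_seq) for c in consensus_db)
    best_species: list[str] = []
    best_identity = -1.0
    best_evalue = math.inf
    top_identity = 0.0
    for cons in consensus_db:
        # band wide enough that any hit at or above the identity gate is
        # scored exactly; weaker hits may be underestimated, which only
        # affects the reported best_identity of unclassified calls
        short = min(len(query), len(cons.consensus_seq))
        band = int(math.ceil((1.0 - min_identity / 100.0) * short)) + 8
        result = _align(query, cons.consensus_seq, band=band)
        identity = result.identity_pct
        top_identity = max(top_identity, identity)
        if identity <= min_identity:  # strict: exactly 97.0 fails
            continue
        evalue = evalue_surrogate(rescaled_score(result), len(query), db_len)
        if use_evalue and not evalue < max_evalue:
            continue
        if identity > best_identity:
            best_identity = identity
            best_evalue = evalue
            best_species = [cons.species]
        elif identity == best_identity:
            best_species.append(cons.species)
            best_evalue = min(best_evalue, evalue)
    if not best_species:
        return SpeciesCall(
            otu_id=otu_id, label=UNCLASSIFIED, best_identity=top_identity,
            n_tied_best=0,
        )
    assert best_identity > min_identity  # classified implies above the gate
    tied_labels = sorted(labels.get(s, s) for s in best_species)
    return SpeciesCall(
        otu_id=otu_id,
        label=tied_labels[0],
        best_identity=best_identity,
        n_tied_best=len(best_species),
        evalue=best_evalue,
    )


def assign_all(
    otu_reps: Sequence[tuple[str, str]],
    consensus_db: Sequence[SpeciesConsensus],
    groups: Iterable[HomologousSpeciesGroup],
    min_identity: float = 97.0,
    max_evalue: float = 1e-10,
    use_evalue: bool = True,
) -> list[SpeciesCall]:
    """Map knn_species over (otu_id, representative) pairs."""
    groups = list(groups)
    calls = [
        knn_species(
            otu_id, rep, consensus_db, groups,
            min_identity=min_identity, max_evalue=max_evalue,
            use_evalue=use_evalue,
        )
        for otu_id, rep in otu_reps
    ]
    group_names = {g.name for g in groups if not g.is_singleton}
    n_group = sum(1 for c in calls if c.label in group_names)
    n_unclassified = sum(1 for c in calls if c.label == UNCLASSIFIED)
    logger.info(
        "species assignment: %d OTUs -> %d specific, %d group-labeled, "
        "%d unclassified",
        len(calls), len(calls) - n_group - n_unclassified, n_group,
        n_unclassified,
    )
    return calls


def write_calls_tsv(calls: Sequence[SpeciesCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlabel\tbest_identity\tn_tied_best\tevalue\n")
        for call in calls:
            fh.write(
                f"{call.otu_id}\t{call.label}\t{call.best_identity:.4f}\t"
                f"{call.n_tied_best}\t{call.evalue:.3e}\n"
            )
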