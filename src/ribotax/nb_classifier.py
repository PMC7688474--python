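"""RDP-style naive Bayesian 8-mer genus classifier with bootstrap confidence.

Word-presence semantics: a training sequence either contains a word or it does
not. Priors and conditionals follow

    P(w)   = (n(w) + 0.5) / (N + 1)        n(w): sequences containing w
    P(w|G) = (m(w) + P(w)) / (M + 1)       m(w): genus-G sequences containing w

Scores accumulate in log space over the query's word set; bootstrap trials draw
floor(|words| / 8) words with replacement and the per-rank confidence is the
fraction of trials whose argmax genus agrees with the point assignment's
lineage at that rank.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .taxonomy import CANONICAL_RANKS

MODEL_FORMAT_VERSION = 1
_VALID = frozenset("ACGT")


def extract_words(seq: str, w: int = 8) -> set[str]:
    """All distinct overlapping w-mers containing only A/C/G/T."""
    seq = seq.upper()
    if len(seq) < w:
        raise ValueError(f"sequence shorter than word size {w}")
    return {
        seq[i:i + w]
        for i in range(len(seq) - w + 1)
        if not (set(seq[i:i + w]) - _VALID)
    }


@dataclass
class ClassifierModel:
    """Trained word model: vocab index plus per-genus log conditionals."""

    word_size: int
    genera: list[str]
    lineages: dict[str, dict[str, Optional[str]]]  # genus -> rank -> name
    vocab: dict[str, int]
    log_cond: np.ndarray          # (n_genera, n_vocab)
    log_cond_unseen: np.ndarray   # (n_genera,) for words never seen in training
    training_counts: dict[str, int]

    @property
    def n_genera(self) -> int:
        return len(self.genera)


@dataclass(frozen=True)
class RankAssignment:
    """Per-rank label and bootstrap confidence (fraction of trials)."""

    labels: Mapping[str, Optional[str]]
    confidences: Mapping[str, float]

    @property
    def genus(self) -> Optional[str]:
        return self.labels.get("genus")

    def deepest_label(self) -> Optional[str]:
        for rank in reversed(CANONICAL_RANKS):
            if self.labels.get(rank):
                return self.labels[rank]
        return None


UNCLASSIFIED = RankAssignment(
    labels={r: None for r in CANONICAL_RANKS},
    confidences={r: 0.0 for r in CANONICAL_RANKS},
)


def train(records: Iterable, word_size: int = 8) -> ClassifierModel:
    """Train from records carrying sequences and genus-bearing lineages."""
    by_genus: dict[str, list[set[str]]] = {}
    lineages: dict[str, dict[str, Optional[str]]] = {}
    for record in records:
        lin = record.lineage
        if lin is None or lin.genus is None:
            raise ValueError(f"record {record.id!r} lacks a genus lineage")
        genus = lin.genus
        by_genus.setdefault(genus, []).append(
            extract_words(record.sequence, word_size)
        )
        lineages.setdefault(genus, {r: lin.get(r) for r in CANONICAL_RANKS})
    if not by_genus:
        raise ValueError("no training records")
    genera = sorted(by_genus)
    n_total = sum(len(v) for v in by_genus.values())

    doc_freq: dict[str, int] = {}
    for word_sets in by_genus.values():
        for words in word_sets:
            for word in words:
                doc_freq[word] = doc_freq.get(word, 0) + 1
    vocab = {w: i for i, w in enumerate(sorted(doc_freq))}

    prior = np.empty(len(vocab))
    for word, idx in vocab.items():
        prior[idx] = (doc_freq[word] + 0.5) / (n_total + 1.0)
    prior_unseen = 0.5 / (n_total + 1.0)

    log_cond = np.empty((len(genera), len(vocab)))
    log_cond_unseen = np.empty(len(genera))
    counts: dict[str, int] = {}
    for gi, genus in enumerate(genera):
        word_sets = by_genus[genus]
        m_total = len(word_sets)
        counts[genus] = m_total
        m = np.zeros(len(vocab))
        for words in word_sets:
            for word in words:
                m[vocab[word]] += 1.0
        log_cond[gi] = np.log((m + prior) / (m_total + 1.0))
        log_cond_unseen[gi] = math.log(prior_unseen / (m_total + 1.0))
    return ClassifierModel(
        word_size=word_size,
        genera=genera,
        lineages=lineages,
        vocab=vocab,
        log_cond=log_cond,
        log_cond_unseen=log_cond_unseen,
        training_counts=counts,
    )


def _genus_scores(model: ClassifierModel, word_indices: np.ndarray, n_unseen: int) -> np.ndarray:
    scores = model.log_cond[:, word_indices].sum(axis=1) if word_indices.size else np.zeros(model.n_genera)
    if n_unseen:
        scores = scores + n_unseen * model.log_cond_unseen
    return scores


def _argmax_genus(
    model: ClassifierModel,
    scores: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Index of the best-scoring genus.

    The point assignment breaks ties lexicographically (genera are sorted, so
    index 0 wins); bootstrap trials pass an rng and break ties uniformly so
    that indistinguishable genera split the confidence between them.
    """
    best = np.flatnonzero(scores == scores.max())
    if rng is not None and best.size > 1:
        return int(rng.choice(best))
    return int(best[0])


def classify(
    model: ClassifierModel,
    seq: str,
    n_bootstrap: int = 100,
    subsample_fraction: float = 1.0 / 8.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> RankAssignment:
    """Point assignment from the full word set plus bootstrap confidences."""
    try:
        words = extract_words(seq, model.word_size)
    except ValueError:
        words = set()
    if not words:
        return UNCLASSIFIED
    known = np.array(
        sorted(model.vocab[w] for w in words if w in model.vocab), dtype=np.int64
    )
    n_unseen = len(words) - known.size
    scores = _genus_scores(model, known, n_unseen)
    point_genus = model.genera[_argmax_genus(model, scores)]
    point_lineage = model.lineages[point_genus]

    if rng is None:
        rng = np.random.default_rng(seed)
    # the bootstrap draws from the full word multiset (known + unseen words);
    # represent unseen words by index -1
    pool = np.concatenate([known, np.full(n_unseen, -1, dtype=np.int64)])
    draw_size = max(1, int(len(words) * subsample_fraction))
    agree = {r: 0 for r in CANONICAL_RANKS}
    for _ in range(n_bootstrap):
        sample = rng.choice(pool, size=draw_size, replace=True)
        unseen = int((sample < 0).sum())
        trial_scores = _genus_scores(model, sample[sample >= 0], unseen)
        trial_genus = model.genera[_argmax_genus(model, trial_scores, rng)]
        trial_lineage = model.lineages[trial_genus]
        for rank in CANONICAL_RANKS:
            if (
                point_lineage.get(rank) is not None
                and trial_lineage.get(rank) == point_lineage.get(rank)
            ):
                agree[rank] += 1
    labels = {r: point_lineage.get(r) for r in CANONICAL_RANKS}
    labels["species"] = None  # species is assigned by the k-NN stage, not here
    confidences = {
        r: (agree[r] / n_bootstrap if labels.get(r) else 0.0)
        for r in CANONICAL_RANKS
    }
    return RankAssignment(labels=labels, confidences=confidences)


def apply_confidence_threshold(
    assignment: RankAssignment, threshold: float = 0.8
) -> RankAssignment:
    """Clear every rank at and below the first rank whose confidence is below
    threshold (searching from superkingdom down)."""
    labels = dict(assignment.labels)
    confidences = dict(assignment.confidences)
    failed = False
    for rank in CANONICAL_RANKS:
        if failed or (labels.get(rank) and confidences.get(rank, 0.0) < threshold):
            failed = True
            labels[rank] = None
            confidences[rank] = 0.0
    return RankAssignment(labels=labels, confidences=confidences)


# ---------------------------------------------------------------------------
# serialization (versioned JSON; text-only for portability)

def save_model(model: ClassifierModel, path: str | Path) -> None:
    vocab_words = sorted(model.vocab, key=model.vocab.get)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "word_size": model.word_size,
        "genera": model.genera,
        "lineages": model.lineages,
        "vocab": vocab_words,
        "log_cond": [[float(x) for x in row] for row in model.log_cond],
        "log_cond_unseen": [float(x) for x in model.log_cond_unseen],
        "training_counts": model.training_counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> ClassifierModel:
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return ClassifierModel(
        word_size=payload["word_size"],
        genera=list(payload["genera"]),
        lineages={g: dict(l) for g, l in payload["lineages"].items()},
        vocab={w: i for i, w in enumerate(payload["vocab"])},
        log_cond=np.asarray(payload["log_cond"], dtype=float),
        log_cond_unseen=np.asarray(payload["log_cond_unseen"], dtype=float),
        training_counts=dict(payload["training_counts"]),
    )
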