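"""Canonical taxonomy loading and lineage re-annotation.

Reads the pipe-delimited taxdump dialect (nodes.dmp / names.dmp), resolves
heterogeneous source lineages by searching from species up to superkingdom for
the first label present in the name index, and rebuilds a consistent 7-rank
lineage from that node's root path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

UNANNOTATED = "unannotated"
MERGED_GENUS = "Escherichia.Shigella"
_MERGED_SOURCE_GENERA = frozenset({"escherichia", "shigella"})


class TaxdumpParseError(ValueError):
    """Raised on malformed taxdump rows (message names the line number)."""


class NotABinomialError(ValueError):
    """Raised when a species label carries no binomial species information."""


class UnknownTaxidError(KeyError):
    """Raised when a taxid is not present in the tree."""


@dataclass(frozen=True)
class TaxonomyNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str = ""


@dataclass
class TaxonomyTree:
    """Rank hierarchy with a lowercased scientific-name index."""

    nodes: dict[int, TaxonomyNode] = field(default_factory=dict)
    name_index: dict[str, set[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def lookup(self, name: str) -> set[int]:
        """Case-insensitive exact name lookup; returns all matching taxids."""
        return set(self.name_index.get(name.strip().lower(), ()))

    def add_node(self, node: TaxonomyNode) -> None:
        if node.taxid in self.nodes:
            raise TaxdumpParseError(f"duplicate taxid {node.taxid}")
        self.nodes[node.taxid] = node

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise TaxdumpParseError(
                    f"taxid {node.taxid} references unknown parent "
                    f"{node.parent_taxid}"
                )


def _split_dmp_line(line: str, path: str, lineno: int, min_fields: int) -> list[str]:
    stripped = line.rstrip("\n")
    if stripped.endswith("\t|"):
        stripped = stripped[: -len("\t|")]
    fields = stripped.split("\t|\t")
    if len(fields) < min_fields:
        raise TaxdumpParseError(
            f"{path}: malformed row at line {lineno}: expected at least "
            f"{min_fields} fields, got {len(fields)}"
        )
    return fields


def load_taxdump(nodes_path: str | Path, names_path: str | Path) -> TaxonomyTree:
    """Load a taxdump-dialect taxonomy.

    Only "scientific name" rows of names.dmp populate the name index. The name
    index maps lowercased names to sets of taxids (homonyms keep all hits).
    """
    tree = TaxonomyTree()
    nodes_path, names_path = Path(nodes_path), Path(names_path)
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line, str(nodes_path), lineno, 3)
            try:
                taxid = int(fields[0])
                parent = int(fields[1])
            except ValueError:
                raise TaxdumpParseError(
                    f"{nodes_path}: malformed row at line {lineno}: "
                    f"non-integer taxid/parent"
                ) from None
            tree.add_node(TaxonomyNode(taxid=taxid, parent_taxid=parent,
                                       rank=fields[2].strip()))
    names_seen = 0
    with open(names_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_dmp_line(line, str(names_path), lineno, 4)
            try:
                taxid = int(fields[0])
            except ValueError:
                raise TaxdumpParseError(
                    f"{names_path}: malformed row at line {lineno}: "
                    f"non-integer taxid"
                ) from None
            if fields[3].strip() != "scientific name":
                continue
            if taxid not in tree.nodes:
                raise TaxdumpParseError(
                    f"{names_path}: line {lineno}: name row for unknown "
                    f"taxid {taxid}"
                )
            name = fields[1].strip()
            tree.nodes[taxid] = replace(tree.nodes[taxid], scientific_name=name)
            tree.name_index.setdefault(name.lower(), set()).add(taxid)
            names_seen += 1
    if names_seen == 0:
        raise TaxdumpParseError(f"{names_path}: no scientific-name rows found")
    tree._validate()
    return tree


def normalize_species_label(raw: str) -> str:
    """Reduce a species label to its binomial (first two tokens).

    Strain and subspecies suffixes are dropped. Labels without a usable
    species epithet ("Clostridium sp.") raise NotABinomialError.
    """
    tokens = raw.split()
    if len(tokens) < 2:
        raise NotABinomialError(f"not a binomial species label: {raw!r}")
    if tokens[1].lower() in {"sp.", "sp"}:
        raise NotABinomialError(f"no species epithet in label: {raw!r}")
    return f"{tokens[0]} {tokens[1]}"


@dataclass(frozen=True)
class SourceAnnotation:
    """Per-rank raw labels as provided by a source database."""

    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        usable = {r: v for r, v in self.labels.items()
                  if v and v != UNANNOTATED}
        if not usable:
            raise ValueError("source annotation must label at least one rank")
        object.__setattr__(self, "labels", dict(self.labels))

    def get(self, rank: str) -> Optional[str]:
        value = self.labels.get(rank)
        if not value or value == UNANNOTATED:
            return None
        return value


@dataclass(frozen=True)
class Lineage:
    """Names at exactly the 7 canonical ranks; missing ranks are None."""

    names: Mapping[str, Optional[str]]

    def __post_init__(self) -> None:
        filled = {r: self.names.get(r) for r in CANONICAL_RANKS}
        extra = set(self.names) - set(CANONICAL_RANKS)
        if extra:
            raise ValueError(f"non-canonical ranks in lineage: {sorted(extra)}")
        object.__setattr__(self, "names", filled)

    def get(self, rank: str) -> Optional[str]:
        return self.names[rank]

    @property
    def genus(self) -> Optional[str]:
        return self.names["genus"]

    @property
    def species(self) -> Optional[str]:
        return self.names["species"]

    def as_annotation(self) -> SourceAnnotation:
        labels = {r: v for r, v in self.names.items() if v}
        return SourceAnnotation(labels=labels)


def resolve_lowest_rank(tree: TaxonomyTree, ann: SourceAnnotation) -> Optional[int]:
    """Search species -> superkingdom for the first resolvable label.

    Species labels are first normalized to binomials; non-binomials fall
    through to genus. Homonyms are resolved by preferring the taxid whose node
    rank equals the rank being searched; still-ambiguous ranks are skipped.
    """
    for rank in reversed(CANONICAL_RANKS):
        label = ann.get(rank)
        if label is None:
            continue
        if rank == "species":
            try:
                label = normalize_species_label(label)
            except NotABinomialError:
                continue
        if rank == "genus" and label == MERGED_GENUS:
            label = "Escherichia"  # merged label is ours, not the taxonomy's
        hits = tree.lookup(label)
        if not hits:
            continue
        if len(hits) == 1:
            return next(iter(hits))
        same_rank = [t for t in hits if tree.nodes[t].rank == rank]
        if len(same_rank) == 1:
            return same_rank[0]
        # ambiguous: skip this rank, mirroring skip-on-failure
    return None


def lineage_of(tree: TaxonomyTree, taxid: int) -> Lineage:
    """Walk ancestors to the root, filling the 7 canonical ranks."""
    if taxid not in tree.nodes:
        raise UnknownTaxidError(f"unknown taxid {taxid}")
    names: dict[str, Optional[str]] = {r: None for r in CANONICAL_RANKS}
    current = taxid
    seen: set[int] = set()
    while current not in seen:
        seen.add(current)
        node = tree.nodes[current]
        if node.rank in names and names[node.rank] is None:
            names[node.rank] = node.scientific_name or None
        if node.parent_taxid == current:  # root
            break
        current = node.parent_taxid
    if names["genus"] is None and names["species"] is not None:
        names["species"] = None  # species under an unannotated genus is disallowed
    return Lineage(names=names)


def merge_escherichia_shigella(lin: Lineage) -> Lineage:
    """Collapse genus Escherichia/Shigella into the merged label."""
    genus = lin.genus
    if genus is None or genus.lower() not in _MERGED_SOURCE_GENERA:
        return lin
    names = dict(lin.names)
    names["genus"] = MERGED_GENUS
    return Lineage(names=names)


@dataclass(frozen=True)
class ReannotationSummary:
    n_input: int
    n_reannotated: int
    n_dropped: int


def reannotate(tree: TaxonomyTree, records: Iterable) -> tuple[list, ReannotationSummary]:
    """Refresh each record's lineage via lowest-rank lookup.

    Records must expose ``source_annotation`` and mutable ``lineage`` /
    ``status`` attributes (see reference_io.ReferenceRecord). Unresolvable
    records are flagged status="unannotated" rather than raised. Re-running on
    the output is a no-op: an existing refreshed lineage is used as the
    annotation for the next pass.
    """
    out = list(records)
    n_ok = 0
    for record in out:
        if record.lineage is not None and record.status == "ok":
            ann = record.lineage.as_annotation()
        else:
            ann = record.source_annotation
        if ann is None:
            record.status = "unannotated"
            continue
        taxid = resolve_lowest_rank(tree, ann)
        if taxid is None:
            record.status = "unannotated"
            record.lineage = None
            continue
        lin = merge_escherichia_shigella(lineage_of(tree, taxid))
        record.lineage = lin
        record.status = "ok"
        n_ok += 1
    summary = ReannotationSummary(
        n_input=len(out), n_reannotated=n_ok, n_dropped=len(out) - n_ok
    )
    logger.info(
        "re-annotation: %d records in, %d re-annotated, %d dropped",
        summary.n_input, summary.n_reannotated, summary.n_dropped,
    )
    return out, summary


# ---------------------------------------------------------------------------
# TSV interfaces

_TSV_COLUMNS = ["id", *CANONICAL_RANKS, "raw_species_label"]


def read_source_annotations(path: str | Path) -> dict[str, SourceAnnotation]:
    """Read a lineage TSV (columns: id, superkingdom..species, raw_species_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNANNOTATED)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"lineage TSV missing columns: {sorted(missing)}")
    out: dict[str, SourceAnnotation] = {}
    for _, row in df.iterrows():
        labels = {r: row[r] for r in CANONICAL_RANKS}
        raw = row["raw_species_label"]
        if raw and raw != UNANNOTATED:
            labels["species"] = raw
        labels = {r: v for r, v in labels.items() if v and v != UNANNOTATED}
        if not labels:
            continue  # fully unannotated row carries no source information
        out[str(row["id"])] = SourceAnnotation(labels=labels)
    return out


def write_reannotated(records: Sequence, path: str | Path) -> None:
    """Write records back as a lineage TSV with an extra status column."""
    rows = []
    for record in records:
        lin = record.lineage
        row = {"id": record.id}
        for rank in CANONICAL_RANKS:
            value = lin.get(rank) if lin is not None else None
            row[rank] = value if value else UNANNOTATED
        raw = None
        if record.source_annotation is not None:
            raw = record.source_annotation.get("species")
        row["raw_species_label"] = raw if raw else UNANNOTATED
        row["status"] = record.status
        rows.append(row)
    pd.DataFrame(rows, columns=[*_TSV_COLUMNS, "status"]).to_csv(
        path, sep="\t", index=False
    )
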