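"""Per-species consensus models and homologous species groups.

A species' region model is the column-wise plurality consensus of a center-star
alignment of its non-redundant member sequences. Species whose consensus
sequences share >= 99% identity (needle-style: identical columns over the full
alignment length, end gaps free) are linked; the connected components of that
graph are the homologous species groups. Multi-member groups are named after
the member with the most strains, suffixed "+".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from ._align import AlignmentResult, align

__all__ = [
    "AlignmentResult",
    "SpeciesConsensus",
    "HomologousSpeciesGroup",
    "needleman_wunsch",
    "star_msa",
    "consensus",
    "build_species_consensus",
    "similarity_graph",
    "build_groups",
    "name_group",
    "build_named_groups",
    "group_label_map",
    "export_group_graph",
    "read_group_graph",
    "write_consensus_fasta",
    "read_consensus_fasta",
]


@dataclass(frozen=True)
class SpeciesConsensus:
    species: str
    genus: str
    region: str
    consensus_seq: str
    n_strains: int

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("a consensus needs at least one member strain")
        if not self.consensus_seq:
            raise ValueError("empty consensus sequence")


@dataclass(frozen=True)
class HomologousSpeciesGroup:
    members: frozenset[str]
    name: str
    region: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group needs at least one member")

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1


def needleman_wunsch(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
) -> AlignmentResult:
    """Global alignment with affine gaps; N scores -2 against anything."""
    return align(
        a, b, match=match, mismatch=mismatch, n_score=-2.0,
        gap_open=gap_open, gap_extend=gap_extend, end_gaps_free=end_gaps_free,
    )


def star_msa(seqs: Sequence[str], ids: Optional[Sequence[str]] = None) -> list[str]:
    """Center-star alignment: longest sequence (ties -> lexicographically
    smallest id) is the center; every other sequence is pairwise-aligned to it
    and the gaps merged into common coordinates. Row order follows the input.
    """
    if not seqs:
        raise ValueError("star_msa requires at least one sequence")
    if ids is None:
        ids = [f"seq{i:06d}" for i in range(len(seqs))]
    if len(ids) != len(seqs):
        raise ValueError("ids and seqs must have equal length")
    if len(seqs) == 1:
        return [seqs[0]]
    center_i = min(range(len(seqs)), key=lambda i: (-len(seqs[i]), ids[i]))
    center = seqs[center_i]
    # pairwise alignments of every other row against the center
    pair_aligned: dict[int, tuple[str, str]] = {}
    for i, seq in enumerate(seqs):
        if i == center_i:
            continue
        result = needleman_wunsch(center, seq)
        pair_aligned[i] = (result.aligned_a, result.aligned_b)
    # per center position p (0..len(center)), the number of inserted columns
    # required immediately before center base p (p == len -> trailing)
    inserts = [0] * (len(center) + 1)
    for ca, _sa in pair_aligned.values():
        pos = 0
        run = 0
        for ch in ca:
            if ch == "-":
                run += 1
            else:
                inserts[pos] = max(inserts[pos], run)
                run = 0
                pos += 1
        inserts[len(center)] = max(inserts[len(center)], run)

    def pad(ca: str, sa: str) -> str:
        out: list[str] = []
        pos = 0
        run: list[str] = []
        for cch, sch in zip(ca, sa):
            if cch == "-":
                run.append(sch)
            else:
                out.append("-" * (inserts[pos] - len(run)))
                out.extend(run)
                run = []
                out.append(sch)
                pos += 1
        out.append("-" * (inserts[len(center)] - len(run)))
        out.extend(run)
        return "".join(out)

    rows: list[str] = []
    center_row = pad(center, center)
    for i in range(len(seqs)):
        if i == center_i:
            rows.append(center_row)
        else:
            rows.append(pad(*pair_aligned[i]))
    assert len({len(r) for r in rows}) == 1
    return rows


def consensus(msa: Sequence[str], plurality_fraction: float = 0.5) -> str:
    """Column-wise plurality consensus.

    Per column the most frequent non-gap residue wins if its count reaches
    plurality_fraction * n_rows (ties -> lexicographically smallest residue),
    else N. All-gap columns are removed.
    """
    if not msa:
        raise ValueError("consensus requires at least one row")
    if len({len(r) for r in msa}) != 1:
        raise ValueError("consensus requires equal-length rows")
    n_rows = len(msa)
    need = plurality_fraction * n_rows
    out: list[str] = []
    for col in zip(*msa):
        counts = Counter(c for c in col if c != "-")
        if not counts:
            continue  # all-gap column
        top = max(counts.values())
        if top >= need:
            out.append(min(c for c, k in counts.items() if k == top))
        else:
            out.append("N")
    return "".join(out)


def build_species_consensus(
    seqs_by_species: Mapping[str, Sequence[str]],
    genus_of: Mapping[str, str],
    region: str,
) -> list[SpeciesConsensus]:
    """One consensus per species from its deduplicated member sequences."""
    out: list[SpeciesConsensus] = []
    for species in sorted(seqs_by_species):
        members = seqs_by_species[species]
        if not members:
            continue
        seqs = [s.upper() for s in members]
        msa = star_msa(seqs)
        out.append(
            SpeciesConsensus(
                species=species,
                genus=genus_of[species],
                region=region,
                consensus_seq=consensus(msa),
                # strains are deduplicated for counting only; the consensus
                # itself weights every member sequence
                n_strains=len(set(seqs)),
            )
        )
    return out


def similarity_graph(
    consensuses: Sequence[SpeciesConsensus],
    threshold: float = 99.0,
    scope: str = "within_genus",
) -> list[tuple[str, str, float]]:
    """Undirected edges (s1, s2, identity_pct) for pairs at or above threshold.

    scope "within_genus" restricts candidate pairs to species of the same
    genus; "all" compares every pair.
    """
    if not consensuses:
        raise ValueError("similarity_graph requires at least one consensus")
    if scope not in {"within_genus", "all"}:
        raise ValueError(f"unknown scope {scope!r}")
    edges: list[tuple[str, str, float]] = []
    ordered = sorted(consensuses, key=lambda c: c.species)
    for i, c1 in enumerate(ordered):
        for c2 in ordered[i + 1:]:
            if scope == "within_genus" and c1.genus != c2.genus:
                continue
            identity = needleman_wunsch(c1.consensus_seq, c2.consensus_seq).identity_pct
            if identity >= threshold:
                edges.append((c1.species, c2.species, identity))
    return edges


def build_groups(
    species: Iterable[str],
    edges: Iterable[tuple],
    region: str = "",
) -> list[HomologousSpeciesGroup]:
    """Connected components of the similarity graph, singletons included.

    Group names are provisional (smallest member); use name_group /
    build_named_groups to apply the strain-count naming rule.
    """
    graph = nx.Graph()
    species = list(species)
    graph.add_nodes_from(species)
    known = set(species)
    for edge in edges:
        s1, s2 = edge[0], edge[1]
        if s1 not in known or s2 not in known:
            raise ValueError(f"edge references unknown species: {(s1, s2)}")
        graph.add_edge(s1, s2)
    groups = []
    for component in nx.connected_components(graph):
        members = frozenset(component)
        groups.append(
            HomologousSpeciesGroup(
                members=members, name=min(members), region=region
            )
        )
    return sorted(groups, key=lambda g: g.name)


def name_group(group: HomologousSpeciesGroup, strain_counts: Mapping[str, int]) -> str:
    """Singleton -> member name; else top-strain member (ties -> smallest) + '+'."""
    members = sorted(group.members)
    missing = [m for m in members if m not in strain_counts]
    if missing:
        raise ValueError(f"strain counts missing for {missing}")
    if group.is_singleton:
        return members[0]
    top = min(members, key=lambda m: (-strain_counts[m], m))
    return f"{top}+"


def build_named_groups(
    consensuses: Sequence[SpeciesConsensus],
    threshold: float = 99.0,
    scope: str = "within_genus",
) -> tuple[list[HomologousSpeciesGroup], list[tuple[str, str, float]]]:
    """similarity_graph + build_groups + naming in one step."""
    edges = similarity_graph(consensuses, threshold=threshold, scope=scope)
    strain_counts = {c.species: c.n_strains for c in consensuses}
    region = consensuses[0].region if consensuses else ""
    groups = build_groups([c.species for c in consensuses], edges, region=region)
    named = [
        HomologousSpeciesGroup(
            members=g.members, name=name_group(g, strain_counts), region=g.region
        )
        for g in groups
    ]
    return sorted(named, key=lambda g: g.name), edges


def group_label_map(groups: Iterable[HomologousSpeciesGroup]) -> dict[str, str]:
    """species -> reported label (group name for multi-member groups)."""
    label: dict[str, str] = {}
    for group in groups:
        for member in group.members:
            label[member] = group.name
    return label


# ---------------------------------------------------------------------------
# file interfaces

def export_group_graph(
    groups: Sequence[HomologousSpeciesGroup],
    edges: Sequence[tuple[str, str, float]],
    path: str | Path,
) -> None:
    """TSV edge list (node1, node2, identity_pct); header always written."""
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tidentity_pct\n")
        for s1, s2, identity in edges:
            fh.write(f"{s1}\t{s2}\t{identity:.4f}\n")


def read_group_graph(path: str | Path) -> list[tuple[str, str, float]]:
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("node1\t"):
            raise ValueError(f"{path}: not a group-graph edge list")
        for line in fh:
            if not line.strip():
                continue
            s1, s2, identity = line.rstrip("\n").split("\t")
            edges.append((s1, s2, float(identity)))
    return edges


def write_consensus_fasta(consensuses: Sequence[SpeciesConsensus], path: str | Path) -> None:
    """FASTA with header species|genus|region|n_strains (pipes in names forbidden)."""
    with open(path, "w") as fh:
        for c in consensuses:
            if "|" in c.species or "|" in c.genus:
                raise ValueError("species/genus names must not contain '|'")
            fh.write(f">{c.species}|{c.genus}|{c.region}|{c.n_strains}\n")
            fh.write(f"{c.consensus_seq}\n")


def read_consensus_fasta(path: str | Path) -> list[SpeciesConsensus]:
    out = []
    header: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split("|")
        if len(fields) != 4:
            raise ValueError(f"{path}: bad consensus header {header!r}")
        species, genus, region, n_strains = fields
        out.append(
            SpeciesConsensus(
                species=species, genus=genus, region=region,
                consensus_seq="".join(chunks), n_strains=int(n_strains),
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                chunks = []
            elif line:
                chunks.append(line.strip())
    flush()
    return out


def write_groups_tsv(
    groups: Sequence[HomologousSpeciesGroup],
    strain_counts: Mapping[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("group_name\tmember\tn_strains\n")
        for group in groups:
            for member in sorted(group.members):
                fh.write(f"{group.name}\t{member}\t{strain_counts.get(member, 0)}\n")


def read_groups_tsv(path: str | Path, region: str = "") -> list[HomologousSpeciesGroup]:
    members_by_name: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("group_name\t"):
            raise ValueError(f"{path}: not a groups TSV")
        for line in fh:
            if not line.strip():
                continue
            name, member, _n = line.rstrip("\n").split("\t")
            members_by_name.setdefault(name, set()).add(member)
    return sorted(
        (
            HomologousSpeciesGroup(members=frozenset(m), name=n, region=region)
            for n, m in members_by_name.items()
        ),
        key=lambda g: g.name,
    )
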