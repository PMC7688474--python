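"""Synthetic inputs for the whole pipeline, with ground truth.

Generates a toy 7-rank taxonomy (taxdump dialect), full-length 16S-like
references with the printed V3-V4 primer sites flanking a variable core,
planted homologous species groups (within-group core divergence below the
grouping threshold, everything else far apart), rank-abundance communities,
and error-bearing (optionally paired) amplicon reads. Everything is
deterministic under the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._dna import reverse_complement
from .amplicon_regions import PrimerPair, extract_region
from .read_preprocess import ReadPair
from .reference_io import ReferenceRecord
from .taxonomy import CANONICAL_RANKS, SourceAnnotation, UNANNOTATED

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    n_genera: int = 10
    species_per_genus: int = 5
    strains_per_species: int = 3
    within_species_divergence: float = 0.002
    group_divergence: float = 0.004   # max pairwise core divergence inside a group
    min_separation: float = 0.02      # guaranteed divergence between non-grouped pairs
    region_core_length: int = 400
    pad_length: int = 60
    primer_pair: PrimerPair = field(default_factory=PrimerPair)
    #: groups as ((genus_idx, species_idx), ...) tuples; members must share a genus
    planted_groups: tuple[tuple[tuple[int, int], ...], ...] = (
        ((0, 0), (0, 1)),
        ((1, 0), (1, 1), (1, 2)),
    )
    include_escherichia_shigella: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for div in (self.within_species_divergence, self.group_divergence):
            if not 0.0 <= div < 1.0:
                raise ValueError("divergences must be in [0, 1)")
        if self.group_divergence >= self.min_separation:
            raise ValueError(
                "planted within-group divergence must be below the "
                "between-species separation"
            )
        seen: set[tuple[int, int]] = set()
        for group in self.planted_groups:
            genera = {g for g, _ in group}
            if len(genera) != 1:
                raise ValueError("planted group members must share a genus")
            for member in group:
                if member in seen:
                    raise ValueError("planted groups must be disjoint")
                seen.add(member)
            g, = genera
            if g >= self.n_genera or any(s >= self.species_per_genus for _, s in group):
                raise ValueError("planted group member out of range")

    def genus_name(self, g: int) -> str:
        if self.include_escherichia_shigella and g == 0:
            return "Escherichia"
        if self.include_escherichia_shigella and g == 1:
            return "Shigella"
        return f"Genus{g + 1:02d}"

    def species_name(self, g: int, s: int) -> str:
        return f"{self.genus_name(g)} species{s + 1:02d}"

    def species_names(self) -> list[str]:
        return [
            self.species_name(g, s)
            for g in range(self.n_genera)
            for s in range(self.species_per_genus)
        ]

    def planted_group_names(self) -> list[frozenset[str]]:
        return [
            frozenset(self.species_name(g, s) for g, s in group)
            for group in self.planted_groups
        ]


# ---------------------------------------------------------------------------
# taxonomy

def simulate_taxonomy(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write nodes.dmp / names.dmp for a full 7-rank tree, one path per species."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes: list[tuple[int, int, str, str]] = [(1, 1, "no rank", "root")]
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        nodes.append((next_id, parent, rank, name))
        next_id += 1
        return next_id - 1

    superkingdom = add(1, "superkingdom", "Bacteria")
    phylum_of: dict[int, int] = {}
    family_of: dict[int, int] = {}
    for g in range(spec.n_genera):
        p = g // 5
        if p not in phylum_of:
            phylum = add(superkingdom, "phylum", f"Phylum{p + 1:02d}")
            cls = add(phylum, "class", f"Class{p + 1:02d}")
            order = add(cls, "order", f"Order{p + 1:02d}")
            phylum_of[p] = order
        f = g // 2
        if f not in family_of:
            family_of[f] = add(phylum_of[p], "family", f"Family{f + 1:02d}")
        genus = add(family_of[f], "genus", spec.genus_name(g))
        for s in range(spec.species_per_genus):
            add(genus, "species", spec.species_name(g, s))

    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    with open(nodes_path, "w") as fh:
        for taxid, parent, rank, _name in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid, _parent, _rank, name in nodes:
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


# ---------------------------------------------------------------------------
# references

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))

def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Substitute round(divergence * len) distinct positions to different bases."""
    n_mut = int(round(divergence * len(seq)))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    chars = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)

def _instantiate(rng: np.random.Generator, primer: str) -> str:
    from ._dna import IUPAC_EXPANSION

    out = []
    for code in primer.upper():
        expansion = sorted(IUPAC_EXPANSION[code])
        out.append(expansion[rng.integers(len(expansion))])
    return "".join(out)


def simulate_references(spec: SyntheticSpec) -> list[ReferenceRecord]:
    """Full-length 16S-like references: pad + forward site + core + reverse
    site + pad. Planted-group members share a core to within the group
    divergence; all other same-genus pairs are forced apart by at least
    min_separation."""
    rng = np.random.default_rng(spec.seed)
    pad5 = _random_seq(rng, spec.pad_length)
    pad3 = _random_seq(rng, spec.pad_length)
    group_of = {member: gi for gi, group in enumerate(spec.planted_groups)
                for member in group}
    records: list[ReferenceRecord] = []
    core_len = spec.region_core_length
    min_sep_sites = int(math.ceil(spec.min_separation * core_len))
    for g in range(spec.n_genera):
        genus_cores: list[str] = []
        group_core_cache: dict[int, str] = {}
        for s in range(spec.species_per_genus):
            key = (g, s)
            if key in group_of:
                gi = group_of[key]
                if gi not in group_core_cache:
                    group_core_cache[gi] = _new_core(
                        rng, core_len, genus_cores, min_sep_sites
                    )
                    genus_cores.append(group_core_cache[gi])
                core = _mutate(rng, group_core_cache[gi], spec.group_divergence / 2.0)
            else:
                core = _new_core(rng, core_len, genus_cores, min_sep_sites)
                genus_cores.append(core)
            fwd_site = _instantiate(rng, spec.primer_pair.forward)
            rev_site = reverse_complement(_instantiate(rng, spec.primer_pair.reverse))
            species = spec.species_name(g, s)
            genus = spec.genus_name(g)
            for t in range(spec.strains_per_species):
                strain_core = _mutate(rng, core, spec.within_species_divergence)
                seq = pad5 + fwd_site + strain_core + rev_site + pad3
                rec_id = f"{species.replace(' ', '_')}_strain{t + 1:02d}"
                labels = {
                    "superkingdom": "Bacteria",
                    "genus": genus,
                    "species": species,
                }
                records.append(
                    ReferenceRecord(
                        id=rec_id,
                        sequence=seq,
                        source_db="synthetic",
                        source_annotation=SourceAnnotation(labels=labels),
                    )
                )
    return records


def _new_core(
    rng: np.random.Generator,
    length: int,
    existing: list[str],
    min_diff_sites: int,
    max_tries: int = 50,
) -> str:
    """A random core differing from every existing same-genus core at more
    than min_diff_sites positions (random 400-mers essentially always do)."""
    for _ in range(max_tries):
        core = _random_seq(rng, length)
        ok = all(
            sum(a != b for a, b in zip(core, other)) > min_diff_sites
            for other in existing
        )
        if ok:
            return core
    raise RuntimeError("could not draw a sufficiently separated species core")


def reference_lineage_rows(records: Sequence[ReferenceRecord]) -> list[dict]:
    """Rows for the lineage TSV matching the taxonomy module's schema."""
    rows = []
    for record in records:
        ann = record.source_annotation
        row = {"id": record.id}
        for rank in CANONICAL_RANKS:
            value = ann.get(rank) if ann is not None else None
            row[rank] = value if value else UNANNOTATED
        species = ann.get("species") if ann is not None else None
        row["raw_species_label"] = species if species else UNANNOTATED
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# communities

@dataclass(frozen=True)
class CommunityProfile:
    abundances: dict[str, float]
    abundance_model: str
    copy_number: dict[str, int]

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"abundances must sum to 1 (got {total})")


def simulate_community(
    species: Sequence[str],
    model: str = "uniform",
    p: float = 1.0,
    copy_number: Optional[dict[str, int]] = None,
    seed: int = 0,
) -> CommunityProfile:
    """Rank-abundance community: uniform, linear, or powerlaw(p).

    linear assigns a_i proportional to S-i+1 over a seeded random species
    order; powerlaw assigns a_i proportional to i^(-p) likewise.
    """
    if not species:
        raise ValueError("community requires at least one species")
    if model == "powerlaw" and p <= 0:
        raise ValueError("power-law exponent must be positive")
    species = list(species)
    n = len(species)
    rng = np.random.default_rng(seed)
    order = list(species)
    if model in {"linear", "powerlaw"}:
        rng.shuffle(order)
    if model == "uniform":
        weights = {s: 1.0 for s in species}
    elif model == "linear":
        weights = {s: float(n - i) for i, s in enumerate(order)}
    elif model == "powerlaw":
        weights = {s: float(i + 1) ** (-p) for i, s in enumerate(order)}
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    total = sum(weights.values())
    abundances = {s: weights[s] / total for s in species}
    # exact renormalization guard against float drift
    drift = 1.0 - sum(abundances.values())
    first = species[0]
    abundances[first] += drift
    return CommunityProfile(
        abundances=abundances,
        abundance_model=model if model != "powerlaw" else f"powerlaw({p})",
        copy_number=dict(copy_number or {s: 1 for s in species}),
    )


# ---------------------------------------------------------------------------
# amplicon reads

@dataclass(frozen=True)
class SimulatedRead:
    id: str
    species: str
    sequence: str


def simulate_amplicons(
    refs: Sequence[ReferenceRecord],
    community: CommunityProfile,
    error_rate: float = 0.005,
    coverage_fold: int = 1000,
    n_reads: Optional[int] = None,
    copy_number_bias: bool = True,
    paired: bool = False,
    min_overlap: int = 20,
    seed: int = 0,
) -> tuple[list, dict[str, str]]:
    """Simulate reads from extracted regions under the community profile.

    Read counts are multinomial with weights abundance x copy number (bias on).
    Errors are i.i.d. substitutions at error_rate. In paired mode each template
    becomes two overlapping reads (overlap >= min_overlap) as ReadPairs, with
    flat Phred-40 qualities; otherwise SimulatedReads. Returns (reads, truth)
    with truth mapping read id -> species. Species whose references yield no
    amplifiable region raise, naming the species.
    """
    rng = np.random.default_rng(seed)
    species_order = sorted(s for s, a in community.abundances.items() if a > 0)
    regions: dict[str, list[str]] = {}
    strain_of = {}
    for record in refs:
        ann = record.source_annotation
        species = ann.get("species") if ann is not None else None
        if record.lineage is not None and record.lineage.species:
            species = record.lineage.species
        if species is None:
            continue
        strain_of.setdefault(species, []).append(record)
    for species in species_order:
        extracted = []
        for record in strain_of.get(species, []):
            pair = PrimerPair()
            fragment = extract_region(record, pair)
            if fragment is not None and fragment.sequence:
                extracted.append(fragment.sequence)
        if not extracted:
            raise ValueError(
                f"no amplifiable region for community species {species!r}"
            )
        regions[species] = extracted
    if n_reads is None:
        n_reads = coverage_fold * len(species_order)
    weights = np.array(
        [
            community.abundances[s]
            * (community.copy_number.get(s, 1) if copy_number_bias else 1)
            for s in species_order
        ],
        dtype=float,
    )
    weights /= weights.sum()
    counts = rng.multinomial(n_reads, weights)
    reads: list = []
    truth: dict[str, str] = {}
    idx = 0
    for species, count in zip(species_order, counts):
        for _ in range(count):
            template = regions[species][rng.integers(len(regions[species]))]
            erroneous = _add_errors(rng, template, error_rate)
            read_id = f"r{idx:07d}"
            idx += 1
            truth[read_id] = species
            if paired:
                read_len = (len(erroneous) + min_overlap) // 2 + min_overlap // 2
                read_len = min(read_len, len(erroneous))
                reads.append(
                    ReadPair(
                        id=read_id,
                        forward_seq=erroneous[:read_len],
                        forward_qual=tuple([40] * read_len),
                        reverse_seq=reverse_complement(erroneous[-read_len:]),
                        reverse_qual=tuple([40] * read_len),
                    )
                )
            else:
                reads.append(
                    SimulatedRead(id=read_id, species=species, sequence=erroneous)
                )
    return reads, truth


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    flips = rng.random(len(seq)) < rate
    if not flips.any():
        return seq
    chars = list(seq)
    for pos in np.flatnonzero(flips):
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# file output

def write_paired_fastq(
    pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    def qual_str(quals: Sequence[int]) -> str:
        return "".join(chr(q + 33) for q in quals)

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for pair in pairs:
            f1.write(
                f"@{pair.id}\n{pair.forward_seq}\n+\n{qual_str(pair.forward_qual)}\n"
            )
            f2.write(
                f"@{pair.id}\n{pair.reverse_seq}\n+\n{qual_str(pair.reverse_qual)}\n"
            )


def write_truth_tsv(truth: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tspecies\n")
        for read_id in sorted(truth):
            fh.write(f"{read_id}\t{truth[read_id]}\n")
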