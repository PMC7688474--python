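from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import copy

from ribotax import taxonomy as tx
from ribotax.synthetic_data import (
    SyntheticSpec,
    simulate_references,
    simulate_taxonomy,
)


def _dmp_nodes(rows):
    return "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r in rows)


def _dmp_names(rows):
    return "".join(
        f"{t}\t|\t{n}\t|\t\t|\t{cls}\t|\n" for t, n, cls in rows
    )


@pytest.fixture
def toy_taxdump(tmp_path):
    """Small taxonomy with Escherichia/Shigella, a rank gap, and a homonym.

    Paths:
      Bacteria > Proteobacteria > Gammaproteobacteria > Enterobacterales >
        Enterobacteriaceae > {Escherichia > E. coli, Shigella > S. flexneri}
      Bacteria > Firmicutes > Bacilli > Bacillales > Bacillaceae >
        Bacillus > B. subtilis
      Bacteria > Firmicutes > Bacilli > Gapless (order) > Gapgenus (genus,
        directly under the order: no family on the path) > Gapgenus gapspecies
      "Duplex" is both a genus (30) and a class-rank homonym (31).
    """
    nodes = [
        (1, 1, "no rank"),
        (2, 1, "superkingdom"),
        (3, 2, "phylum"),
        (4, 3, "class"),
        (5, 4, "order"),
        (6, 5, "family"),
        (7, 6, "genus"),
        (8, 7, "species"),
        (9, 6, "genus"),
        (10, 9, "species"),
        (11, 2, "phylum"),
        (12, 11, "class"),
        (13, 12, "order"),
        (14, 13, "family"),
        (15, 14, "genus"),
        (16, 15, "species"),
        (17, 12, "order"),
        (18, 17, "genus"),
        (19, 18, "species"),
        (30, 14, "genus"),
        (31, 12, "class"),
        (32, 14, "species"),
    ]
    names = [
        (1, "root", "scientific name"),
        (2, "Bacteria", "scientific name"),
        (3, "Proteobacteria", "scientific name"),
        (4, "Gammaproteobacteria", "scientific name"),
        (5, "Enterobacterales", "scientific name"),
        (6, "Enterobacteriaceae", "scientific name"),
        (7, "Escherichia", "scientific name"),
        (8, "Escherichia coli", "scientific name"),
        (9, "Shigella", "scientific name"),
        (10, "Shigella flexneri", "scientific name"),
        (11, "Firmicutes", "scientific name"),
        (12, "Bacilli", "scientific name"),
        (13, "Bacillales", "scientific name"),
        (14, "Bacillaceae", "scientific name"),
        (15, "Bacillus", "scientific name"),
        (16, "Bacillus subtilis", "scientific name"),
        (16, "Vibrio subtilis", "synonym"),
        (17, "Gapless", "scientific name"),
        (18, "Gapgenus", "scientific name"),
        (19, "Gapgenus gapspecies", "scientific name"),
        (30, "Duplex", "scientific name"),
        (31, "Duplex", "scientific name"),
        (32, "Orphanus orphan", "scientific name"),
    ]
    nodes_path = tmp_path / "nodes.dmp"
    names_path = tmp_path / "names.dmp"
    nodes_path.write_text(_dmp_nodes(nodes))
    names_path.write_text(_dmp_names(names))
    return nodes_path, names_path


@pytest.fixture
def toy_tree(toy_taxdump):
    return tx.load_taxdump(*toy_taxdump)


@pytest.fixture(scope="session")
def default_spec():
    """The default synthetic reference layout used by the acceptance criteria."""
    return SyntheticSpec(seed=20)


@pytest.fixture(scope="session")
def default_refs(default_spec):
    return simulate_references(default_spec)


@pytest.fixture(scope="session")
def default_refs_annotated(default_spec, default_refs, tmp_path_factory):
    """Default references with lineages refreshed through the simulated
    taxonomy, as the real pipeline would see them."""
    out = tmp_path_factory.mktemp("default_taxdump")
    nodes, names = simulate_taxonomy(default_spec, out)
    tree = tx.load_taxdump(nodes, names)
    refs, summary = tx.reannotate(tree, copy.deepcopy(default_refs))
    assert summary.n_dropped == 0
    return refs


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_genera=3,
        species_per_genus=3,
        strains_per_species=2,
        region_core_length=200,
        planted_groups=(((0, 0), (0, 1)),),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_refs(small_spec):
    return simulate_references(small_spec)
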