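import random

import pytest

from ribotax import consensus_groups as cg

from _oracles import components_oracle


class TestStarMsa:
    def test_identical_sequences_no_gaps(self):
        rows = cg.star_msa(["ACGTAC", "ACGTAC", "ACGTAC"])
        assert rows == ["ACGTAC", "ACGTAC", "ACGTAC"]

    def test_single_sequence(self):
        assert cg.star_msa(["ACGT"]) == ["ACGT"]

    def test_two_sequences_center_is_longest(self):
        # under the free-end-gap scorer ACT aligns to ACGT as ACT- (terminal
        # gap free, one G/T mismatch beats an internal gap costing 10)
        rows = cg.star_msa(["ACGT", "ACT"])
        assert rows[0] == "ACGT"
        assert rows[1] == "ACT-"

    def test_internal_deletion_gets_gap(self):
        # a deletion in a longer context does produce an internal gap
        center = "AAAACGTTTTCCCCGGGG"
        other = "AAAACGTTTCCCCGGGG"  # one T deleted
        rows = cg.star_msa([center, other])
        assert rows[0] == center
        assert rows[1].replace("-", "") == other
        assert "-" in rows[1]

    def test_rows_have_equal_length(self):
        rng = random.Random(0)
        seqs = []
        base = "".join(rng.choice("ACGT") for _ in range(50))
        for _ in range(5):
            chars = [c for c in base if rng.random() > 0.05]
            seqs.append("".join(chars))
        rows = cg.star_msa(seqs)
        assert len({len(r) for r in rows}) == 1
        for row, seq in zip(rows, seqs):
            assert row.replace("-", "") == seq

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cg.star_msa([])


class TestConsensus:
    def test_majority_column(self):
        assert cg.consensus(["A", "A", "T"]) == "A"

    def test_tie_lexicographic(self):
        assert cg.consensus(["A", "T"]) == "A"
        assert cg.consensus(["T", "G"]) == "G"

    def test_subplurality_gives_n(self):
        assert cg.consensus(["A", "C", "G", "T"]) == "N"

    def test_all_gap_column_removed(self):
        assert cg.consensus(["A-C", "A-C"]) == "AC"

    def test_gaps_do_not_count_toward_plurality(self):
        # column {A, -, -}: count 1 of 3 rows < 1.5 -> N
        assert cg.consensus(["A", "-", "-"]) == "N"

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            cg.consensus(["AC", "A"])


class TestBuildSpeciesConsensus:
    def test_identical_strains_deduplicated(self):
        out = cg.build_species_consensus(
            {"Sp a": ["ACGTACGTAC"] * 3}, {"Sp a": "Sp"}, "V3V4"
        )
        assert len(out) == 1
        assert out[0].consensus_seq == "ACGTACGTAC"
        assert out[0].n_strains == 1

    def test_majority_base_wins(self):
        seqs = ["ACGTACGTAC", "ACGTACGTAC", "ACGAACGTAC"]  # col 4: T,T,A
        out = cg.build_species_consensus({"Sp a": seqs}, {"Sp a": "Sp"}, "V3V4")
        assert out[0].consensus_seq == "ACGTACGTAC"
        assert out[0].n_strains == 2  # two unique sequences

    def test_two_species_two_records(self):
        out = cg.build_species_consensus(
            {"Sp a": ["ACGTACGTAC"], "Sp b": ["TTTTACGTAC"]},
            {"Sp a": "Sp", "Sp b": "Sp"},
            "V3V4",
        )
        assert [c.species for c in out] == ["Sp a", "Sp b"]


def _cons(species, genus, seq, n_strains=1):
    return cg.SpeciesConsensus(
        species=species, genus=genus, region="V3V4",
        consensus_seq=seq, n_strains=n_strains,
    )


class TestSimilarityGraph:
    def test_identical_same_genus(self):
        seq = "ACGT" * 30
        edges = cg.similarity_graph([_cons("G a", "G", seq), _cons("G b", "G", seq)])
        assert [(e[0], e[1]) for e in edges] == [("G a", "G b")]
        assert edges[0][2] == 100.0

    def test_below_threshold_no_edge(self):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(1000))
        chars = list(seq)
        for pos in rng.sample(range(1000), 11):  # identity ~98.9
            chars[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[pos]]
        other = "".join(chars)
        edges = cg.similarity_graph(
            [_cons("G a", "G", seq), _cons("G b", "G", other)]
        )
        assert edges == []

    def test_scope_restricts_to_genus(self):
        seq = "ACGT" * 30
        consensuses = [_cons("G1 a", "G1", seq), _cons("G2 b", "G2", seq)]
        assert cg.similarity_graph(consensuses, scope="within_genus") == []
        edges = cg.similarity_graph(consensuses, scope="all")
        assert len(edges) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cg.similarity_graph([])


class TestBuildGroups:
    def test_chain_components(self):
        groups = cg.build_groups(
            ["A", "B", "C", "D"], [("A", "B"), ("B", "C")]
        )
        assert {frozenset(g.members) for g in groups} == {
            frozenset({"A", "B", "C"}), frozenset({"D"})
        }

    def test_no_edges_all_singletons(self):
        groups = cg.build_groups(["A", "B", "C"], [])
        assert all(g.is_singleton for g in groups)
        assert len(groups) == 3

    def test_unknown_species_in_edge(self):
        with pytest.raises(ValueError):
            cg.build_groups(["A"], [("A", "Z")])

    def test_random_graphs_match_transitive_closure_oracle(self):
        rng = random.Random(11)
        for _ in range(40):
            n = rng.randint(1, 12)
            nodes = [f"s{i}" for i in range(n)]
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1:]
                if rng.random() < 0.25
            ]
            groups = cg.build_groups(nodes, edges)
            got = {frozenset(g.members) for g in groups}
            assert got == components_oracle(nodes, edges)

    def test_partition(self):
        rng = random.Random(5)
        nodes = [f"s{i}" for i in range(10)]
        edges = [(a, b) for a in nodes for b in nodes
                 if a < b and rng.random() < 0.3]
        groups = cg.build_groups(nodes, edges)
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == sorted(nodes)


class TestNameGroup:
    def test_top_strain_member(self):
        group = cg.HomologousSpeciesGroup(
            members=frozenset({"X x", "Y y", "Z z"}), name="", region="V3V4"
        )
        assert cg.name_group(group, {"X x": 10, "Y y": 3, "Z z": 1}) == "X x+"

    def test_singleton_keeps_name(self):
        group = cg.HomologousSpeciesGroup(
            members=frozenset({"Q q"}), name="", region=""
        )
        assert cg.name_group(group, {"Q q": 5}) == "Q q"

    def test_tie_lexicographic(self):
        group = cg.HomologousSpeciesGroup(
            members=frozenset({"X x", "Y y"}), name="", region=""
        )
        assert cg.name_group(group, {"X x": 5, "Y y": 5}) == "X x+"

    def test_missing_counts_rejected(self):
        group = cg.HomologousSpeciesGroup(
            members=frozenset({"X x"}), name="", region=""
        )
        with pytest.raises(ValueError):
            cg.name_group(group, {})


class TestThresholdMonotonicity:
    def test_group_count_nondecreasing_in_threshold(self):
        rng = random.Random(21)
        base = "".join(rng.choice("ACGT") for _ in range(200))
        consensuses = []
        for i in range(8):
            chars = list(base)
            for pos in rng.sample(range(200), rng.randint(0, 6)):
                chars[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[chars[pos]]
            consensuses.append(_cons(f"G s{i}", "G", "".join(chars)))
        counts = []
        for threshold in (95.0, 97.0, 99.0, 99.5, 100.0):
            groups, _ = cg.build_named_groups(consensuses, threshold=threshold)
            counts.append(len(groups))
        assert counts == sorted(counts)


class TestPlantedGroupRecovery:
    def test_small_planted_groups(self, small_spec, small_refs):
        from ribotax.amplicon_regions import extract_region

        frags: dict[str, list[str]] = {}
        genus_of: dict[str, str] = {}
        for record in small_refs:
            fragment = extract_region(record, small_spec.primer_pair)
            assert fragment is not None
            species = record.source_annotation.get("species")
            genus_of[species] = record.source_annotation.get("genus")
            frags.setdefault(species, []).append(fragment.sequence)
        consensuses = cg.build_species_consensus(frags, genus_of, "V3V4")
        groups, _ = cg.build_named_groups(consensuses)
        multi = {frozenset(g.members) for g in groups if not g.is_singleton}
        assert multi == set(small_spec.planted_group_names())


class TestExportGroupGraph:
    def test_round_trip(self, tmp_path):
        edges = [("A a", "B b", 99.5), ("B b", "C c", 100.0)]
        groups = cg.build_groups(["A a", "B b", "C c"], [(e[0], e[1]) for e in edges])
        path = tmp_path / "edges.tsv"
        cg.export_group_graph(groups, edges, path)
        assert cg.read_group_graph(path) == edges

    def test_empty_graph_header_only(self, tmp_path):
        path = tmp_path / "edges.tsv"
        cg.export_group_graph([], [], path)
        assert path.read_text() == "node1\tnode2\tidentity_pct\n"
        assert cg.read_group_graph(path) == []


class TestConsensusFastaRoundTrip:
    def test_round_trip(self, tmp_path):
        consensuses = [
            _cons("G a", "G", "ACGTACGT", 3),
            _cons("G b", "G", "ACGTNCGT", 1),
        ]
        path = tmp_path / "cons.fasta"
        cg.write_consensus_fasta(consensuses, path)
        assert cg.read_consensus_fasta(path) == consensuses

    def test_groups_tsv_round_trip(self, tmp_path):
        groups = [
            cg.HomologousSpeciesGroup(
                members=frozenset({"G a", "G b"}), name="G a+", region="V3V4"
            ),
            cg.HomologousSpeciesGroup(
                members=frozenset({"G c"}), name="G c", region="V3V4"
            ),
        ]
        path = tmp_path / "groups.tsv"
        cg.write_groups_tsv(groups, {"G a": 2, "G b": 1, "G c": 1}, path)
        assert cg.read_groups_tsv(path, region="V3V4") == sorted(
            groups, key=lambda g: g.name
        )
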