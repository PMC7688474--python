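import pytest

from ribotax import synthetic_data as sd
from ribotax import taxonomy as tx
from ribotax.amplicon_regions import extract_region
from ribotax.reference_io import LengthFilterPolicy, qc_filter


class TestSpecValidation:
    def test_group_spanning_genera_rejected(self):
        with pytest.raises(ValueError, match="share a genus"):
            sd.SyntheticSpec(planted_groups=(((0, 0), (1, 0)),))

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            sd.SyntheticSpec(planted_groups=(((0, 0), (0, 1)), ((0, 1), (0, 2))))

    def test_incompatible_divergences_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            sd.SyntheticSpec(group_divergence=0.05, min_separation=0.02)

    def test_out_of_range_member_rejected(self):
        with pytest.raises(ValueError, match="range"):
            sd.SyntheticSpec(n_genera=2, planted_groups=(((5, 0), (5, 1)),))


class TestSimulateTaxonomy:
    def test_resolvable_species(self, tmp_path):
        spec = sd.SyntheticSpec(n_genera=2, species_per_genus=3, seed=1)
        nodes, names = sd.simulate_taxonomy(spec, tmp_path)
        tree = tx.load_taxdump(nodes, names)
        species = [n for n in tree.nodes.values() if n.rank == "species"]
        assert len(species) == 6
        for name in spec.species_names():
            taxid = tx.resolve_lowest_rank(
                tree, tx.SourceAnnotation(labels={"species": name})
            )
            assert taxid is not None
            lin = tx.lineage_of(tree, taxid)
            assert lin.species == name
            assert all(lin.get(r) for r in tx.CANONICAL_RANKS)

    def test_deterministic_bytes(self, tmp_path):
        spec = sd.SyntheticSpec(
            n_genera=2, species_per_genus=2, planted_groups=(), seed=5
        )
        n1, m1 = sd.simulate_taxonomy(spec, tmp_path / "a")
        n2, m2 = sd.simulate_taxonomy(spec, tmp_path / "b")
        assert n1.read_bytes() == n2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()

    def test_escherichia_shigella_on_demand(self, tmp_path):
        spec = sd.SyntheticSpec(
            n_genera=3, species_per_genus=2, include_escherichia_shigella=True,
            planted_groups=(), seed=2,
        )
        nodes, names = sd.simulate_taxonomy(spec, tmp_path)
        tree = tx.load_taxdump(nodes, names)
        assert tree.lookup("Escherichia")
        assert tree.lookup("Shigella")


class TestSimulateReferences:
    def test_structure_and_determinism(self, small_spec):
        refs1 = sd.simulate_references(small_spec)
        refs2 = sd.simulate_references(small_spec)
        assert [(r.id, r.sequence) for r in refs1] == [
            (r.id, r.sequence) for r in refs2
        ]
        expected = (
            small_spec.n_genera
            * small_spec.species_per_genus
            * small_spec.strains_per_species
        )
        assert len(refs1) == expected

    def test_regions_extractable_with_zero_edits(self, small_spec, small_refs):
        for record in small_refs[:6]:
            fragment = extract_region(record, small_spec.primer_pair)
            assert fragment is not None
            assert fragment.fwd_edits == 0 and fragment.rev_edits == 0
            assert len(fragment.sequence) == small_spec.region_core_length

    def test_references_pass_full_length_qc(self, small_refs):
        kept, dropped = qc_filter(small_refs, LengthFilterPolicy(k_sd=3.0))
        assert not dropped

    def test_zero_group_divergence_collapses_genus(self):
        spec = sd.SyntheticSpec(
            n_genera=2, species_per_genus=3, strains_per_species=1,
            within_species_divergence=0.0, group_divergence=0.0,
            region_core_length=150,
            planted_groups=(
                ((0, 0), (0, 1), (0, 2)),
                ((1, 0), (1, 1), (1, 2)),
            ),
            seed=3,
        )
        refs = sd.simulate_references(spec)
        by_genus = {}
        for record in refs:
            genus = record.source_annotation.get("genus")
            core = record.sequence[
                spec.pad_length + len(spec.primer_pair.forward):
                -(spec.pad_length + len(spec.primer_pair.reverse))
            ]
            by_genus.setdefault(genus, set()).add(core)
        # every species in a genus shares one identical core
        assert all(len(cores) == 1 for cores in by_genus.values())


class TestSimulateCommunity:
    def test_uniform(self):
        profile = sd.simulate_community(["a", "b", "c", "d"], "uniform")
        assert all(v == pytest.approx(0.25) for v in profile.abundances.values())

    def test_linear_multiset(self):
        profile = sd.simulate_community(["a", "b", "c", "d"], "linear", seed=1)
        assert sorted(profile.abundances.values()) == pytest.approx(
            [0.1, 0.2, 0.3, 0.4]
        )

    def test_powerlaw_p1(self):
        profile = sd.simulate_community(["a", "b"], "powerlaw", p=1.0, seed=2)
        assert sorted(profile.abundances.values()) == pytest.approx(
            [1 / 3, 2 / 3]
        )

    def test_powerlaw_p2(self):
        profile = sd.simulate_community(["a", "b"], "powerlaw", p=2.0, seed=2)
        assert sorted(profile.abundances.values()) == pytest.approx(
            [0.2, 0.8]
        )

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            sd.simulate_community(["a"], "powerlaw", p=0.0)

    def test_empty_species_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_community([], "uniform")

    def test_linear_rank_order_is_seeded(self):
        p1 = sd.simulate_community(list("abcd"), "linear", seed=1)
        p2 = sd.simulate_community(list("abcd"), "linear", seed=1)
        p3 = sd.simulate_community(list("abcd"), "linear", seed=2)
        assert p1.abundances == p2.abundances
        assert p1.abundances != p3.abundances  # different shuffle (w.h.p.)


class TestSimulateAmplicons:
    def test_error_free_reads_are_exact_regions(self, small_spec, small_refs):
        species = small_spec.species_names()[:2]
        community = sd.simulate_community(species, "uniform")
        reads, truth = sd.simulate_amplicons(
            small_refs, community, error_rate=0.0, n_reads=20, seed=1
        )
        regions = set()
        for record in small_refs:
            fragment = extract_region(record, small_spec.primer_pair)
            regions.add(fragment.sequence)
        assert all(read.sequence in regions for read in reads)
        assert len(truth) == 20

    def test_truth_complete_and_consistent(self, small_spec, small_refs):
        community = sd.simulate_community(
            small_spec.species_names(), "uniform"
        )
        reads, truth = sd.simulate_amplicons(
            small_refs, community, n_reads=50, seed=2
        )
        assert sorted(truth) == sorted(r.id for r in reads)
        for read in reads:
            assert truth[read.id] == read.species

    def test_copy_number_bias_ratio(self, small_spec, small_refs):
        species = small_spec.species_names()[:2]
        community = sd.simulate_community(
            species, "uniform", copy_number={species[0]: 4, species[1]: 1}
        )
        reads, truth = sd.simulate_amplicons(
            small_refs, community, n_reads=2000, seed=3
        )
        counts = {s: 0 for s in species}
        for sp in truth.values():
            counts[sp] += 1
        ratio = counts[species[0]] / counts[species[1]]
        assert 3.0 < ratio < 5.3  # binomial tolerance around 4.0

    def test_copy_number_bias_off(self, small_spec, small_refs):
        species = small_spec.species_names()[:2]
        community = sd.simulate_community(
            species, "uniform", copy_number={species[0]: 4, species[1]: 1}
        )
        reads, truth = sd.simulate_amplicons(
            small_refs, community, n_reads=2000, copy_number_bias=False, seed=4
        )
        counts = {s: 0 for s in species}
        for sp in truth.values():
            counts[sp] += 1
        assert 0.8 < counts[species[0]] / counts[species[1]] < 1.25

    def test_deterministic_under_seed(self, small_spec, small_refs):
        community = sd.simulate_community(small_spec.species_names(), "uniform")
        r1, t1 = sd.simulate_amplicons(small_refs, community, n_reads=30, seed=9)
        r2, t2 = sd.simulate_amplicons(small_refs, community, n_reads=30, seed=9)
        assert [x.sequence for x in r1] == [x.sequence for x in r2]
        assert t1 == t2

    def test_paired_mode_merges_back(self, small_spec, small_refs):
        from ribotax.read_preprocess import merge_pair

        community = sd.simulate_community(small_spec.species_names()[:1], "uniform")
        pairs, truth = sd.simulate_amplicons(
            small_refs, community, error_rate=0.0, n_reads=5, paired=True, seed=5
        )
        regions = {
            extract_region(r, small_spec.primer_pair).sequence
            for r in small_refs
        }
        for pair in pairs:
            merged = merge_pair(pair)
            assert merged is not None
            assert merged.sequence in regions

    def test_missing_region_names_species(self, small_spec, small_refs):
        community = sd.simulate_community(["Ghost species99"], "uniform")
        with pytest.raises(ValueError, match="Ghost species99"):
            sd.simulate_amplicons(small_refs, community, n_reads=5, seed=1)

    def test_paired_fastq_bytes_deterministic(self, small_spec, small_refs, tmp_path):
        community = sd.simulate_community(small_spec.species_names(), "uniform")
        for sub in ("a", "b"):
            out = tmp_path / sub
            out.mkdir()
            pairs, _ = sd.simulate_amplicons(
                small_refs, community, n_reads=10, paired=True, seed=6
            )
            sd.write_paired_fastq(pairs, out / "r1.fastq", out / "r2.fastq")
        assert (tmp_path / "a/r1.fastq").read_bytes() == (
            tmp_path / "b/r1.fastq"
        ).read_bytes()
        assert (tmp_path / "a/r2.fastq").read_bytes() == (
            tmp_path / "b/r2.fastq"
        ).read_bytes()
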