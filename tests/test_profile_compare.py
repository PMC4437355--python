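"""End-to-end profiles, strand-confirmed variants, gaps and attribution."""

import numpy as np
import pytest

import popseq as pq
from popseq.kmer_index import KmerMultiset
from conftest import brute_signature


@pytest.fixture(scope="module")
def clean_profile_setup():
    g = pq.generate_genome(20_000, seed=30, genome_id="G")
    decoys = [pq.generate_genome(20_000, seed=s, genome_id=f"d{s}") for s in (31, 32)]
    lineages = {"G": "r;x;G", "d31": "r;y;d31", "d32": "r;y;d32"}
    idx = pq.build_reference_index([g] + decoys, lineages, k=12)
    cfg = pq.ReadSimConfig(
        read_length=100, coverage=15.0, error_rate=0.0, proportions={"G": 1.0}, seed=33
    )
    reads = pq.simulate_reads([g], cfg)
    return g, idx, reads


class TestBuildProfile:
    def test_clean_single_genome_round_trip(self, clean_profile_setup):
        g, idx, reads = clean_profile_setup
        prof = pq.build_profile(reads, idx, pq.ProfileConfig(n_bootstrap=0), sample_id="s1")
        assert prof.matches[0].genome_id == "G"
        # genome-end windows see fewer reads, so a handful of signature k-mers
        # go unobserved even without errors; cosine is 1 minus that edge effect
        assert prof.matches[0].cosine == pytest.approx(1.0, abs=1e-3)
        assert prof.abundances.proportions["G"] == pytest.approx(1.0, abs=1e-6)
        assert prof.abundances.unassigned == 0.0
        assert not any(v.confirmed for v in prof.variants)
        assert prof.posteriors.top()[0] == "G"

    def test_same_seed_gives_byte_identical_json(self, clean_profile_setup):
        _, idx, reads = clean_profile_setup
        cfg = pq.ProfileConfig(n_bootstrap=10, seed=5)
        a = pq.build_profile(reads, idx, cfg, sample_id="s1").to_json()
        b = pq.build_profile(reads, idx, cfg, sample_id="s1").to_json()
        assert a == b

    def test_save_load_round_trip(self, clean_profile_setup, tmp_path):
        _, idx, reads = clean_profile_setup
        prof = pq.build_profile(reads, idx, pq.ProfileConfig(n_bootstrap=0), sample_id="s1")
        path = tmp_path / "s1.json"
        prof.save(path)
        loaded = pq.SampleProfile.load(path)
        assert np.array_equal(loaded.retained.codes, prof.retained.codes)
        assert loaded.calibrant == prof.calibrant
        assert loaded.to_json() == prof.to_json()

    def test_minor_component_detected_in_mixture(self):
        a = pq.generate_genome(30_000, seed=40, genome_id="a")
        b_mut, _ = pq.apply_mutations(a, 1500, seed=41)  # 5% diverged relative
        b = pq.GenomeRecord("b", b_mut.sequence)
        idx = pq.build_reference_index([a, b], {"a": "r;a", "b": "r;b"}, k=12)
        cfg = pq.ReadSimConfig(
            read_length=100, coverage=30.0, error_rate=0.001,
            proportions={"a": 0.95, "b": 0.05}, seed=42,
        )
        reads = pq.simulate_reads([a, b], cfg)
        prof = pq.build_profile(reads, idx, pq.ProfileConfig(n_bootstrap=0), "mix")
        gids = [m.genome_id for m in prof.matches]
        assert set(gids) == {"a", "b"}
        assert prof.abundances.proportions["b"] < prof.abundances.proportions["a"]

    def test_reference_free_profile_has_retained_set_only(self, clean_profile_setup):
        _, _, reads = clean_profile_setup
        prof = pq.build_profile(reads, None, pq.ProfileConfig(), "free")
        assert len(prof.retained) > 0
        assert prof.matches == [] and prof.abundances is None


class TestConfirmVariants:
    def test_singleton_below_threshold_unconfirmed(self):
        ms = KmerMultiset.from_counts({"ACGTACGTACGA": (1, 1)}, k=12)
        calls = pq.confirm_variants(ms, [], pq.CalibrantThreshold(t=3))
        assert len(calls) == 1 and not calls[0].confirmed
        assert calls[0].total == 1

    def test_single_orientation_rejected(self):
        ms = KmerMultiset.from_counts({"ACGTACGTACGA": (12, 12)}, k=12)  # fwd only
        calls = pq.confirm_variants(ms, [], pq.CalibrantThreshold(t=3))
        assert calls[0].as_forward == 12 and calls[0].as_reverse == 0
        assert not calls[0].confirmed

    def test_both_orientations_above_threshold_confirmed(self):
        ms = KmerMultiset.from_counts({"ACGTACGTACGA": (10, 6)}, k=12)
        calls = pq.confirm_variants(ms, [], pq.CalibrantThreshold(t=3))
        assert calls[0].confirmed

    def test_reference_kmers_are_not_candidates(self, small_genome):
        sig = pq.build_signature(small_genome, k=12)
        cfg = pq.ReadSimConfig(
            read_length=100, coverage=20.0, error_rate=0.0,
            proportions={"g1": 1.0}, seed=3,
        )
        ms = pq.count_read_kmers(pq.simulate_reads([small_genome], cfg), k=12)
        assert pq.confirm_variants(ms, [sig], pq.CalibrantThreshold(t=1)) == []

    def test_true_snp_confirmed_with_expected_window_span(self):
        """A real SNP at deep coverage yields exactly the novel windows it spans."""
        ref = pq.generate_genome(5_000, seed=50, genome_id="ref")
        mutant, events = pq.apply_mutations(ref, 1, seed=51)
        mutant = pq.GenomeRecord("mut", mutant.sequence)
        cfg = pq.ReadSimConfig(
            read_length=100, coverage=40.0, error_rate=0.0,
            proportions={"mut": 1.0}, seed=52,
        )
        ms = pq.count_read_kmers(pq.simulate_reads([mutant], cfg), k=12)
        sig = pq.build_signature(ref, k=12)
        cal = pq.fit_calibrant(pq.multiplicity_histogram(ms))
        calls = pq.confirm_variants(ms, [sig], cal)
        confirmed = {c.kmer for c in calls if c.confirmed}
        # oracle: distinct canonical mutant windows overlapping the SNP that
        # do not also occur elsewhere in the reference
        expected = brute_signature(mutant.sequence, 12) - brute_signature(ref.sequence, 12)
        assert confirmed == expected
        assert len(expected) >= 10  # ~k windows, minus rare coincidences


class TestGapAnalysis:
    def test_full_signature_has_no_gaps(self, small_genome):
        sig = pq.build_signature(small_genome, k=12)
        rep = pq.gap_analysis(sig, small_genome, k=12)
        assert rep.gaps == () and rep.n_covered == rep.n_windows
        assert rep.unmatched_sample_kmers == 0

    def test_empty_retained_is_one_full_gap(self, small_genome):
        empty = pq.KmerSet(k=12, codes=np.empty(0, dtype=np.int64))
        rep = pq.gap_analysis(empty, small_genome, k=12)
        assert rep.gaps == (len(small_genome) - 12 + 1,)
        assert rep.n_covered == 0

    def test_interior_deletion_window_arithmetic(self):
        """Deleting 100 bp leaves a single gap of 100 + k - 1 windows."""
        ref = pq.generate_genome(2000, seed=1, genome_id="ref")
        sample = pq.GenomeRecord("sample", ref.sequence[:800] + ref.sequence[900:])
        retained = pq.build_signature(sample, k=12)
        rep = pq.gap_analysis(retained, ref, k=12)
        assert rep.gaps == (111,)

    def test_gap_conservation(self):
        ref = pq.generate_genome(3000, seed=2, genome_id="ref")
        # keep only the first third of the genome's k-mers
        partial = pq.build_signature(
            pq.GenomeRecord("part", ref.sequence[:1000]), k=12
        )
        rep = pq.gap_analysis(partial, ref, k=12)
        assert rep.n_covered + sum(rep.gaps) == rep.n_windows == 3000 - 12 + 1

    def test_reference_shorter_than_k_raises(self):
        with pytest.raises(ValueError):
            pq.gap_analysis(
                pq.KmerSet(k=12, codes=np.empty(0, dtype=np.int64)),
                pq.GenomeRecord("tiny", "ACGTACGT"),
                k=12,
            )


class TestCompareProfiles:
    def _profile_from_genome(self, genome, seed, coverage=15.0, error_rate=0.0):
        cfg = pq.ReadSimConfig(
            read_length=100, coverage=coverage, error_rate=error_rate,
            proportions={genome.genome_id: 1.0}, seed=seed,
        )
        reads = pq.simulate_reads([genome], cfg)
        return pq.build_profile(reads, None, pq.ProfileConfig(), genome.genome_id)

    def test_self_comparison_reflexive(self, clean_profile_setup):
        _, _, reads = clean_profile_setup
        prof = pq.build_profile(reads, None, pq.ProfileConfig(), "s")
        d = pq.compare_profiles(prof, prof)
        assert d.distance == 0.0 and d.related

    def test_symmetry(self):
        a = self._profile_from_genome(pq.generate_genome(10_000, seed=60, genome_id="a"), 61)
        b = self._profile_from_genome(pq.generate_genome(10_000, seed=62, genome_id="b"), 63)
        assert pq.compare_profiles(a, b).cosine == pq.compare_profiles(b, a).cosine

    def test_unrelated_genomes_have_negligible_cosine(self):
        """Chance 12-mer collisions between unrelated 50 kb genomes stay tiny."""
        a = self._profile_from_genome(pq.generate_genome(50_000, seed=64, genome_id="a"), 65)
        b = self._profile_from_genome(pq.generate_genome(50_000, seed=66, genome_id="b"), 67)
        assert pq.compare_profiles(a, b).cosine < 0.01

    def test_mutation_count_orders_similarity(self):
        """cosine(founder, 1 mutation) > cosine(founder, 100 mutations)."""
        base = pq.generate_genome(20_000, seed=70, genome_id="base")
        one, _ = pq.apply_mutations(base, 1, seed=71)
        many, _ = pq.apply_mutations(base, 100, seed=72)
        pa = self._profile_from_genome(base, 73)
        pb = self._profile_from_genome(pq.GenomeRecord("one", one.sequence), 74)
        pc = self._profile_from_genome(pq.GenomeRecord("many", many.sequence), 75)
        assert pq.compare_profiles(pa, pb).cosine > pq.compare_profiles(pa, pc).cosine

    def test_mismatched_k_raises(self, clean_profile_setup):
        _, _, reads = clean_profile_setup
        p1 = pq.build_profile(reads, None, pq.ProfileConfig(k=12), "a")
        p2 = pq.build_profile(reads, None, pq.ProfileConfig(k=11), "b")
        with pytest.raises(ValueError):
            pq.compare_profiles(p1, p2)

    def test_distance_matrix_symmetric_unit_diagonal(self):
        genomes = [pq.generate_genome(10_000, seed=80 + s, genome_id=f"g{s}") for s in range(3)]
        profiles = [self._profile_from_genome(g, 90 + i) for i, g in enumerate(genomes)]
        mat = pq.profile_distance_matrix(profiles)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)
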