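"""Synthetic-data generator: reproducibility, truth consistency, and the
statistical structure each stage is supposed to emulate."""

import numpy as np
import pytest

import hexapop as hp
from hexapop.scoring import RankingCombination, filter_peaks


class TestConfig:
    def test_divergence_bounds(self):
        with pytest.raises(ValueError):
            hp.SimConfig(divergence_F=0.0)
        with pytest.raises(ValueError):
            hp.SimConfig(divergence_F=1.0)

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            hp.SimConfig(stutter_prob=1.5)


class TestFrequencies:
    def test_seed_reproducibility(self):
        cfg = hp.SimConfig(seed=3)
        f1 = hp.simulate_allele_frequencies(cfg)
        f2 = hp.simulate_allele_frequencies(cfg)
        for cluster in f1:
            for pop in f1[cluster]:
                for a, b in zip(f1[cluster][pop], f2[cluster][pop]):
                    assert np.array_equal(a, b)

    def test_low_divergence_limit_tracks_baseline(self):
        cfg = hp.SimConfig(seed=2, divergence_F=1e-4, n_populations=3)
        freqs = hp.simulate_allele_frequencies(cfg)
        for cluster in freqs:
            pops = list(freqs[cluster].values())
            for locus in range(cfg.n_loci):
                for p in pops[1:]:
                    assert np.max(np.abs(p[locus] - pops[0][locus])) < 0.05

    def test_between_cluster_differentiation_exceeds_within(self):
        """Multilocus G_ST between clusters exceeds G_ST within clusters on
        average (F = 0.3, 2 clusters x 3 populations, 20 replicates)."""
        diff_between, diff_within = [], []
        for seed in range(20):
            cfg = hp.SimConfig(
                seed=seed, divergence_F=0.3, n_populations=3, n_samples=12,
                clone_fraction=0.0,
            )
            freqs = hp.simulate_allele_frequencies(cfg)
            g, _ = hp.simulate_individuals(freqs, cfg)
            pops = g.populations
            north = [p for p in pops if p.startswith("N")]
            south = [p for p in pops if p.startswith("S")]
            r_b = hp.pairwise_differentiation(g, north[0], south[0], n_boot=0)
            r_w = hp.pairwise_differentiation(g, north[0], north[1], n_boot=0)
            diff_between.append(r_b.g_st)
            diff_within.append(r_w.g_st)
        assert np.mean(diff_between) > np.mean(diff_within)


class TestIndividuals:
    def test_zero_somatic_rate_gives_identical_ramets(self):
        cfg = hp.SimConfig(
            seed=4, n_populations=1, n_samples=20, clone_fraction=0.5,
            somatic_mutation_rate=0.0,
        )
        freqs = hp.simulate_allele_frequencies(cfg)
        g, truth = hp.simulate_individuals(freqs, cfg)
        clones = {}
        for s in g.samples:
            clones.setdefault(truth.clone_of[s], []).append(s)
        multi = {c: ss for c, ss in clones.items() if len(ss) >= 2}
        assert multi
        for ss in multi.values():
            ref = [g.alleles(ss[0], l) for l in g.loci]
            for s in ss[1:]:
                assert [g.alleles(s, l) for l in g.loci] == ref

    def test_phenotype_sizes_within_ploidy(self, small_dataset):
        g = small_dataset.genotypes
        for s in g.samples:
            for l in g.loci:
                assert 1 <= len(g.alleles(s, l)) <= 6

    def test_single_allele_locus(self):
        cfg = hp.SimConfig(seed=1, n_populations=1, n_samples=4, n_alleles=1)
        freqs = hp.simulate_allele_frequencies(cfg)
        g, _ = hp.simulate_individuals(freqs, cfg)
        for s in g.samples:
            assert len(g.alleles(s, g.loci[0])) == 1

    def test_mean_set_size_matches_closed_form(self):
        """With k equifrequent alleles and 6 draws, E|set| = k(1-(1-1/k)^6)."""
        cfg = hp.SimConfig(
            seed=8, n_populations=1, n_samples=300, n_alleles=10,
            clone_fraction=0.0,
        )
        k = cfg.n_alleles
        uniform = [np.full(k, 1.0 / k) for _ in range(cfg.n_loci)]
        freqs = {"NORTH": {"N1": uniform}, "SOUTH": {"S1": uniform}}
        g, _ = hp.simulate_individuals(freqs, cfg)
        sizes = [
            len(g.alleles(s, l)) for s in g.samples_of("N1") for l in g.loci
        ]
        expected = k * (1 - (1 - 1 / k) ** 6)
        assert np.mean(sizes) == pytest.approx(expected, rel=0.05)


class TestPeaks:
    def test_no_stutter_deterministic_rank(self):
        cfg = hp.SimConfig(
            seed=5, n_populations=1, n_samples=6, stutter_prob=0.0,
            rank_reliability=1.0, rank_thresholds=(10,) * 12,
        )
        ds = hp.simulate_dataset(cfg)
        # triangular over [10, 10] is deterministic rank 10
        assert all(p.rank == 10 for p in ds.peaks)
        n_true = sum(
            len(ds.truth.true_alleles[(s, l)])
            for s in ds.genotypes.samples for l in ds.genotypes.loci
        )
        assert len(ds.peaks) == n_true

    def test_full_stutter_adds_shadow_peaks(self):
        cfg = hp.SimConfig(
            seed=6, n_populations=1, n_samples=4, stutter_prob=1.0,
        )
        ds = hp.simulate_dataset(cfg)
        by_cell = {}
        for p in ds.peaks:
            by_cell.setdefault((p.sample_id, p.marker_id), []).append(p)
        for (s, m), cell_peaks in by_cell.items():
            sizes = sorted(p.size_bp for p in cell_peaks)
            true = ds.truth.true_alleles[(s, m)]
            assert len(cell_peaks) == 2 * len(true)
            for a in true:
                assert 100.0 + (a - 1) * cfg.motif_length in sizes

    def test_truth_consistency_after_stripping_stutter(self):
        """Filtering at each marker's generating threshold recovers the true
        allele sets for >= 95% of cells at the default configuration."""
        cfg = hp.SimConfig(seed=7, n_populations=2, n_samples=20)
        ds = hp.simulate_dataset(cfg)
        combo = RankingCombination.from_mapping(
            dict(zip(cfg.marker_ids, cfg.thresholds))
        )
        scored = filter_peaks(ds.peaks, combo, ds.markers, ds.truth.population_of)
        assert hp.recovery_rate(scored, ds.truth) >= 0.95

    def test_exact_truth_without_noise(self):
        cfg = hp.SimConfig(
            seed=9, n_populations=1, n_samples=10, stutter_prob=0.0,
            rank_reliability=1.0,
        )
        ds = hp.simulate_dataset(cfg)
        combo = RankingCombination.from_mapping(
            dict(zip(cfg.marker_ids, cfg.thresholds))
        )
        scored = filter_peaks(ds.peaks, combo, ds.markers, ds.truth.population_of)
        assert hp.recovery_rate(scored, ds.truth) == 1.0


class TestChloroplast:
    def test_zero_steps_all_identical(self):
        cfg = hp.SimConfig(
            seed=1, n_populations=2, n_samples=5, cp_step_p=1.0,
            cp_inter_cluster_steps=0,
        )
        haps, _ = hp.simulate_cp_haplotypes(cfg)
        assert len({h.repeats for h in haps}) == 1

    def test_seed_reproducibility(self):
        cfg = hp.SimConfig(seed=13)
        h1, _ = hp.simulate_cp_haplotypes(cfg)
        h2, _ = hp.simulate_cp_haplotypes(cfg)
        assert [h.repeats for h in h1] == [h.repeats for h in h2]

    def test_high_separation_orders_distances(self):
        cfg = hp.SimConfig(
            seed=2, n_populations=2, n_samples=10,
            cp_inter_cluster_steps=15, cp_step_p=0.7,
        )
        haps, truth = hp.simulate_cp_haplotypes(cfg)
        import itertools

        intra, inter = [], []
        for a, b in itertools.combinations(haps, 2):
            d = hp.goldstein_distance(a, b)
            same = truth.cluster_of[a.sample_id] == truth.cluster_of[b.sample_id]
            (intra if same else inter).append(d)
        assert min(inter) > max(intra)

    def test_ramets_share_haplotype(self):
        cfg = hp.SimConfig(seed=3, n_populations=1, n_samples=20, clone_fraction=0.5)
        ds = hp.simulate_dataset(cfg)
        hap_of = {h.sample_id: h.repeats for h in ds.haplotypes}
        for s, c in ds.truth.clone_of.items():
            peers = [t for t, c2 in ds.truth.clone_of.items() if c2 == c]
            for t in peers:
                assert hap_of[s] == hap_of[t]


class TestQMatrixGenerator:
    def test_k1_degenerate(self):
        q = hp.simulate_q_matrix(5, 1, seed=0)
        assert np.array_equal(q.p, np.ones((5, 1)))

    def test_small_alpha_near_degenerate_rows(self):
        q = hp.simulate_q_matrix(200, 4, alpha=0.01, seed=1)
        frac = np.mean(q.p.max(axis=1) > 0.95)
        assert frac > 0.9

    def test_rows_sum_to_one_tightly(self):
        q = hp.simulate_q_matrix(100, 6, alpha=1.0, seed=2)
        assert np.max(np.abs(q.p.sum(axis=1) - 1.0)) <= 1e-12

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            hp.simulate_q_matrix(0, 2)
        with pytest.raises(ValueError):
            hp.simulate_q_matrix(5, 2, alpha=0.0)


class TestDatasetDeterminism:
    def test_bit_identical_under_fixed_seed(self):
        cfg = hp.SimConfig(seed=42, n_populations=2, n_samples=8)
        d1 = hp.simulate_dataset(cfg)
        d2 = hp.simulate_dataset(cfg)
        assert d1.peaks == d2.peaks
        assert [h.repeats for h in d1.haplotypes] == [h.repeats for h in d2.haplotypes]
        assert d1.truth.clone_of == d2.truth.clone_of
        for key in d1.truth.true_alleles:
            assert d1.truth.true_alleles[key] == d2.truth.true_alleles[key]

    def test_emitted_artifacts_pass_model_invariants(self, small_dataset):
        # peaks carry valid ranks/sizes; haplotype table aligns with loci
        for p in small_dataset.peaks[::97]:
            assert 1 <= p.rank <= 10 and p.size_bp > 0
        L = small_dataset.config.n_cp_loci
        assert all(len(h.repeats) == L for h in small_dataset.haplotypes)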