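"""Diversity/differentiation statistics, with independent single-pass
oracles for Jost's D / G_ST and an exhaustive permutation oracle for AMOVA."""

import itertools
import math

import numpy as np
import pytest

import hexapop as hp
from conftest import build_genotypes


class TestAlleleFrequencies:
    def test_fixed_population(self):
        g = build_genotypes({"x": {"L1": {3}}, "y": {"L1": {3}}})
        f = hp.estimate_allele_frequencies(g, "P")
        assert f["L1"] == {3: 1.0}

    def test_equal_dosage_weighting(self):
        # {a} contributes 1 to a; {a,b} contributes 1/2 each -> (1.5/2, 0.5/2)
        g = build_genotypes({"x": {"L1": {1}}, "y": {"L1": {1, 2}}})
        f = hp.estimate_allele_frequencies(g, "P")
        assert f["L1"][1] == pytest.approx(0.75)
        assert f["L1"][2] == pytest.approx(0.25)

    def test_frequencies_sum_to_one(self, small_dataset):
        g = small_dataset.genotypes
        for pop in g.populations:
            for locus, f in hp.estimate_allele_frequencies(g, pop).items():
                assert sum(f.values()) == pytest.approx(1.0, abs=1e-12)


class TestShannon:
    def test_all_unique_equals_ln_n(self):
        layout = {f"s{i}": {"L1": {i}} for i in range(13)}
        g = build_genotypes(layout)
        h = hp.shannon_genotype_diversity(g, "P")
        assert h == pytest.approx(math.log(13), abs=1e-12)
        assert round(h, 2) == 2.56

    def test_four_unique(self):
        g = build_genotypes({f"s{i}": {"L1": {i}} for i in range(4)})
        assert round(hp.shannon_genotype_diversity(g, "P"), 2) == 1.39

    def test_closed_form_mixed_frequencies(self):
        # genotype frequencies (0.5, 0.25, 0.25) -> H = 1.5 ln 2
        layout = {
            "a": {"L1": {1}}, "b": {"L1": {1}},
            "c": {"L1": {2}}, "d": {"L1": {3}},
        }
        g = build_genotypes(layout)
        assert hp.shannon_genotype_diversity(g, "P") == pytest.approx(
            1.5 * math.log(2), abs=1e-12
        )

    def test_bounded_by_ln_n(self, small_dataset):
        g = small_dataset.genotypes
        for pop in g.populations:
            n = len(g.samples_of(pop))
            assert hp.shannon_genotype_diversity(g, pop) <= math.log(n) + 1e-12


class TestAlleleCounts:
    def test_single_population_all_private(self):
        g = build_genotypes({"x": {"L1": {1, 2}}, "y": {"L1": {2, 3}}})
        (summary,) = hp.count_alleles_and_private(g)
        assert summary.total_alleles == 3
        assert summary.private_alleles == 3

    def test_disjoint_alleles_all_private(self):
        g = build_genotypes(
            {"x": {"L1": {1}}, "y": {"L1": {2}}},
            population_of={"x": "A", "y": "B"},
        )
        summaries = {s.population: s for s in hp.count_alleles_and_private(g)}
        assert summaries["A"].private_alleles == 1
        assert summaries["B"].private_alleles == 1

    def test_shared_alleles_not_private(self, two_pop_genotypes):
        summaries = hp.count_alleles_and_private(two_pop_genotypes)
        for s in summaries:
            assert s.private_alleles <= s.total_alleles


# ---------------------------------------------------------------------------
# independent oracle for Jost's D / G_ST: direct frequency arithmetic
# ---------------------------------------------------------------------------

def d_gst_oracle(freqs_a, freqs_b):
    """freqs_x: list over loci of dict allele -> frequency."""
    ds, gs = [], []
    for fa, fb in zip(freqs_a, freqs_b):
        alleles = sorted(set(fa) | set(fb))
        va = [fa.get(a, 0.0) for a in alleles]
        vb = [fb.get(a, 0.0) for a in alleles]
        ha = 1 - sum(v * v for v in va)
        hb = 1 - sum(v * v for v in vb)
        hs = (ha + hb) / 2
        ht = 1 - sum(((x + y) / 2) ** 2 for x, y in zip(va, vb))
        if ht <= 0:
            continue
        ds.append((ht - hs) / (1 - hs) * 2)
        gs.append((ht - hs) / ht)
    return sum(ds) / len(ds), sum(gs) / len(gs)


class TestDifferentiation:
    def test_identical_profiles_zero(self):
        g = build_genotypes(
            {
                "a1": {"L1": {1, 2}}, "a2": {"L1": {1}},
                "b1": {"L1": {1, 2}}, "b2": {"L1": {1}},
            },
            population_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        r = hp.pairwise_differentiation(g, "A", "B", n_boot=0)
        assert r.jost_d == pytest.approx(0.0, abs=1e-12)
        assert r.g_st == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_maximal(self):
        g = build_genotypes(
            {
                "a1": {"L1": {1}}, "a2": {"L1": {1}},
                "b1": {"L1": {2}}, "b2": {"L1": {2}},
            },
            population_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        r = hp.pairwise_differentiation(g, "A", "B", n_boot=0)
        assert r.jost_d == pytest.approx(1.0)
        assert r.g_st == pytest.approx(1.0)

    def test_matches_independent_oracle(self, small_dataset):
        g = small_dataset.genotypes
        pa, pb = g.populations[0], g.populations[-1]
        r = hp.pairwise_differentiation(g, pa, pb, n_boot=0)
        fa = hp.estimate_allele_frequencies(g, pa)
        fb = hp.estimate_allele_frequencies(g, pb)
        loci = [l for l in g.loci if l in fa and l in fb]
        d, gst = d_gst_oracle([fa[l] for l in loci], [fb[l] for l in loci])
        assert r.jost_d == pytest.approx(d, abs=1e-12)
        assert r.g_st == pytest.approx(gst, abs=1e-12)

    def test_invariant_to_allele_relabeling_and_duplication(self):
        layout = {
            "a1": {"L1": {1, 2}}, "a2": {"L1": {2}},
            "b1": {"L1": {2, 3}}, "b2": {"L1": {3}},
        }
        pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        g = build_genotypes(layout, pops)
        r = hp.pairwise_differentiation(g, "A", "B", n_boot=0)
        # relabel alleles by an arbitrary injective map
        remap = {1: 10, 2: 40, 3: 7}
        layout2 = {s: {"L1": {remap[a] for a in v["L1"]}} for s, v in layout.items()}
        r2 = hp.pairwise_differentiation(build_genotypes(layout2, pops), "A", "B", n_boot=0)
        assert r2.jost_d == pytest.approx(r.jost_d, abs=1e-12)
        assert r2.g_st == pytest.approx(r.g_st, abs=1e-12)
        # duplicate every sample in both populations
        layout3 = dict(layout)
        pops3 = dict(pops)
        for s, v in layout.items():
            layout3[s + "_dup"] = v
            pops3[s + "_dup"] = pops[s]
        r3 = hp.pairwise_differentiation(build_genotypes(layout3, pops3), "A", "B", n_boot=0)
        assert r3.jost_d == pytest.approx(r.jost_d, abs=1e-12)
        assert r3.g_st == pytest.approx(r.g_st, abs=1e-12)

    def test_bootstrap_p_reproducible_and_significant_when_fixed(self):
        g = build_genotypes(
            {
                "a1": {"L1": {1}}, "a2": {"L1": {1}}, "a3": {"L1": {1}},
                "b1": {"L1": {2}}, "b2": {"L1": {2}}, "b3": {"L1": {2}},
            },
            population_of={f"{c}{i}": c.upper() for c in "ab" for i in (1, 2, 3)},
        )
        r1 = hp.pairwise_differentiation(g, "A", "B", n_boot=200, seed=3)
        r2 = hp.pairwise_differentiation(g, "A", "B", n_boot=200, seed=3)
        assert r1.p_jost_d == r2.p_jost_d == 0.0
        assert r1.p_g_st == 0.0

    def test_small_population_rejected(self, two_pop_genotypes):
        g = two_pop_genotypes.subset(["a1", "b1", "b2"])
        with pytest.raises(ValueError):
            hp.pairwise_differentiation(g, "A", "B", n_boot=0)


class TestPresenceAbsence:
    def test_row_sums_and_column_count(self, two_pop_genotypes):
        binary, mask = hp.to_presence_absence(two_pop_genotypes)
        g = two_pop_genotypes
        n_cols = sum(
            len(set().union(*(g.alleles(s, l) for s in g.samples)))
            for l in g.loci
        )
        assert binary.shape[1] == n_cols
        for s in g.samples:
            k = sum(len(g.alleles(s, l)) for l in g.loci)
            assert binary.loc[s].sum() == k
        assert not mask.to_numpy().any()

    def test_identical_samples_identical_rows(self):
        g = build_genotypes({"x": {"L1": {1, 2}}, "y": {"L1": {1, 2}}})
        binary, _ = hp.to_presence_absence(g)
        assert (binary.loc["x"] == binary.loc["y"]).all()

    def test_missing_cell_masked_and_zero(self):
        g = build_genotypes({"x": {"L1": {1}, "L2": {2}}, "y": {"L1": {1}, "L2": set()}})
        binary, mask = hp.to_presence_absence(g)
        assert mask.loc["y", "L2"]
        assert binary.loc["y", "L2:2"] == 0


# ---------------------------------------------------------------------------
# AMOVA with exhaustive label-permutation oracle
# ---------------------------------------------------------------------------

def amova_phi_oracle(x, labels):
    """Direct Phi computation from explicit pair sums (independent path)."""
    x = np.asarray(x)
    labels = list(labels)
    n = len(labels)
    pops = sorted(set(labels))
    d = {}
    for i, j in itertools.combinations(range(n), 2):
        d[(i, j)] = int(np.sum(x[i] != x[j]))
    ss_total = sum(d.values()) / n
    ss_within = 0.0
    for p in pops:
        idx = [i for i, l in enumerate(labels) if l == p]
        ss_within += sum(
            d[(min(i, j), max(i, j))] for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(pops) - 1, n - len(pops)
    sw = ss_within / df_w
    counts = [labels.count(p) for p in pops]
    n0 = (n - sum(c * c for c in counts) / n) / df_a
    sa = (ss_among / df_a - sw) / n0
    return sa / (sa + sw) if (sa + sw) > 0 else 0.0


class TestAmova:
    def binary_fixture(self):
        x = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]]
        )
        return x, ["A", "A", "B", "B"]

    def test_maximally_distinct_populations(self):
        x, labels = self.binary_fixture()
        r = hp.amova_binary(x, labels, n_perm=999, seed=0)
        assert r.phi_pt == pytest.approx(1.0)
        assert r.pct_among == pytest.approx(100.0)
        assert r.pct_among + r.pct_within == pytest.approx(100.0)
        # smallest achievable p given the permutation structure
        assert r.p_value is not None and r.p_value < 0.4

    def test_p_value_matches_exhaustive_enumeration(self):
        x, labels = self.binary_fixture()
        phi_obs = amova_phi_oracle(x, labels)
        perms = [
            [labels[i] for i in perm]
            for perm in itertools.permutations(range(4))
        ]
        exhaustive = sum(
            amova_phi_oracle(x, p) >= phi_obs - 1e-12 for p in perms
        ) / len(perms)
        r = hp.amova_binary(x, labels, n_perm=4999, seed=1)
        assert r.p_value == pytest.approx(exhaustive, abs=0.05)

    def test_panmictic_phi_near_zero(self):
        rng = np.random.default_rng(0)
        phis = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, size=(16, 10))
            labels = ["A"] * 8 + ["B"] * 8
            r = hp.amova_binary(x, labels, n_perm=0)
            phis.append(r.phi_pt)
        assert abs(np.mean(phis)) < 0.05

    def test_phi_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 2, size=(9, 6))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        r = hp.amova_binary(x, labels, n_perm=0)
        assert r.phi_pt == pytest.approx(amova_phi_oracle(x, labels), abs=1e-12)

    def test_singleton_population_rejected(self):
        with pytest.raises(ValueError):
            hp.amova_binary(np.zeros((3, 2), dtype=int), ["A", "A", "B"], n_perm=0)

    def test_permutation_p_reproducible(self):
        x, labels = self.binary_fixture()
        p1 = hp.amova_binary(x, labels, n_perm=99, seed=5).p_value
        p2 = hp.amova_binary(x, labels, n_perm=99, seed=5).p_value
        assert p1 == p2
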