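"""APM sharing statistic, Monte Carlo nulls, multipoint scores, genome-wide
adjustment, and meta-analysis."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from apmscan.genedrop import AlleleFrequencyTable, GeneticMap, haldane_theta
from apmscan.linkage import (
    DegenerateNullError,
    MetaInput,
    PairScorer,
    SharingWeight,
    apm_observed,
    genomewide_adjust,
    grid_multipoint,
    grid_weights,
    meta_combine,
    multipoint_window,
    null_distribution,
    sharing_statistic,
    z_and_pvalues,
)
from apmscan.pedigree import RelativePair


Q = {1: 0.25, 2: 0.25, 3: 0.5}  # allele "A" = 1 etc.
W = SharingWeight("inverse_sqrt")


class TestSharingStatistic:
    def test_no_shared_alleles(self):
        assert sharing_statistic((1, 1), (2, 3), Q, W) == 0.0

    def test_homozygous_identical_pair(self):
        # (A,A) vs (A,A), q(A)=0.25, f=1/sqrt(q)=2 -> 1/4 * 4 matches * 2 = 2
        assert sharing_statistic((1, 1), (1, 1), Q, W) == pytest.approx(2.0)

    def test_homozygous_vs_het(self):
        # (A,A) vs (A,B): two matching (a,b) combinations -> 1/4 * 2 * 2 = 1
        assert sharing_statistic((1, 1), (1, 2), Q, W) == pytest.approx(1.0)

    def test_constant_weight_bounded(self):
        w = SharingWeight("constant")
        for gi, gj in itertools.product(itertools.product((1, 2, 3), repeat=2),
                                        repeat=2):
            assert 0.0 <= sharing_statistic(gi, gj, Q, w) <= 1.0

    def test_symmetry(self):
        for gi, gj in itertools.product(itertools.product((1, 2, 3), repeat=2),
                                        repeat=2):
            assert sharing_statistic(gi, gj, Q, W) == pytest.approx(
                sharing_statistic(gj, gi, Q, W)
            )

    def test_missing_frequency_raises(self):
        with pytest.raises(KeyError):
            sharing_statistic((1, 9), (1, 1), Q, W)


class TestApmObserved:
    pairs = [RelativePair("a", "b", 0.25), RelativePair("a", "c", 0.25)]

    def test_single_pair_score(self):
        geno = {"a": (1, 1), "b": (1, 2)}
        score, n = apm_observed(self.pairs[:1], geno, Q, W)
        assert score == pytest.approx(1.0)
        assert n == 1

    def test_missing_member_excluded(self):
        geno = {"a": (1, 1), "b": (1, 2), "c": (0, 0)}
        score, n = apm_observed(self.pairs, geno, Q, W)
        assert n == 1
        assert score == pytest.approx(1.0)

    def test_no_informative_pairs_raises(self):
        with pytest.raises(ValueError):
            apm_observed(self.pairs, {"a": (0, 0)}, Q, W)

    def test_matches_bruteforce_on_random_panel(self, four_generations, rng):
        """Vectorised PairScorer equals the naive double loop."""
        ids = four_generations.ids
        affected = [i for i in ids if not four_generations[i].is_founder]
        pairs = [
            RelativePair(a, b, four_generations.kinship(a, b))
            for a, b in itertools.combinations(affected, 2)
            if four_generations.kinship(a, b) > 0
        ]
        geno = {i: tuple(rng.choice([0, 1, 2, 3], 2)) for i in ids}
        freqs = AlleleFrequencyTable({"M": Q})
        # brute force
        expect = 0.0
        for p in pairs:
            gi, gj = geno[p.id_a], geno[p.id_b]
            if 0 in gi or 0 in gj:
                continue
            expect += sharing_statistic(gi, gj, Q, W)
        idx = {iid: k for k, iid in enumerate(ids)}
        obs = np.zeros((len(ids), 1, 2), dtype=np.int64)
        for iid, g in geno.items():
            obs[idx[iid], 0, :] = g if 0 not in g else (0, 0)
        scorer = PairScorer(
            obs,
            np.asarray([[idx[p.id_a], idx[p.id_b]] for p in pairs]),
            [freqs.weight_lookup("M", "inverse_sqrt")],
        )
        assert scorer.observed()[0] == pytest.approx(expect)


class TestNullDistribution:
    def _setup(self, trio):
        freqs = AlleleFrequencyTable({"M": {1: 0.5, 2: 0.5}})
        pairs = [RelativePair("f", "c", 0.25)]
        geno = {"f": (1, 2), "m": (1, 1), "c": (1, 2)}
        return freqs, pairs, geno

    def test_reproducible_under_seed(self, trio):
        freqs, pairs, geno = self._setup(trio)
        n1 = null_distribution(trio, pairs, freqs, None, "M", geno, 50, "unlinked",
                               rng_seed=4)
        n2 = null_distribution(trio, pairs, freqs, None, "M", geno, 50, "unlinked",
                               rng_seed=4)
        assert np.array_equal(n1, n2)

    def test_near_degenerate_marker_raises(self, trio):
        freqs = AlleleFrequencyTable({"M": {1: 1 - 1e-9, 2: 1e-9}})
        pairs = [RelativePair("f", "c", 0.25)]
        geno = {"f": (1, 1), "c": (1, 1)}
        with pytest.raises(DegenerateNullError):
            null_distribution(trio, pairs, freqs, None, "M", geno, 100, "unlinked",
                              rng_seed=0)

    def test_null_mean_matches_exhaustive_enumeration(self, trio):
        """For a parent-offspring pair at a biallelic marker with constant
        weight, E[S] under gene dropping is computed by exhaustive
        enumeration over founder genotype configurations."""
        q1 = 0.3
        freqs = AlleleFrequencyTable({"M": {1: q1, 2: 1 - q1}})
        pairs = [RelativePair("f", "c", 0.25)]
        geno = {"f": (1, 2), "m": (1, 2), "c": (1, 2)}
        # enumeration: founders f=(a1,a2), m=(b1,b2) each allele iid from q;
        # child picks one of father's and one of mother's uniformly
        qmap = {1: q1, 2: 1 - q1}
        w = SharingWeight("constant")
        expect = 0.0
        for fa in itertools.product((1, 2), repeat=2):
            for mo in itertools.product((1, 2), repeat=2):
                p_geno = (
                    qmap[fa[0]] * qmap[fa[1]] * qmap[mo[0]] * qmap[mo[1]]
                )
                for pick_f in (0, 1):
                    for pick_m in (0, 1):
                        child = (fa[pick_f], mo[pick_m])
                        expect += (
                            p_geno * 0.25 * sharing_statistic(fa, child, qmap, w)
                        )
        null = null_distribution(
            trio, pairs, freqs, None, "M", geno, 4000, "unlinked",
            weight=w, rng_seed=8,
        )
        se = null.std(ddof=1) / math.sqrt(null.size)
        assert null.mean() == pytest.approx(expect, abs=4 * se)


class TestZAndP:
    def test_z_arithmetic(self):
        null = np.array([2.0, 4.0, 6.0])  # mean 4, sd 2
        z, p_asym, p_emp = z_and_pvalues(10.0, null)
        assert z == pytest.approx(3.0)
        assert p_emp == 0.0

    def test_zero_z_gives_half(self):
        null = np.array([-1.0, 1.0])
        z, p_asym, _ = z_and_pvalues(0.0, null)
        assert z == 0.0
        assert p_asym == pytest.approx(0.5)

    def test_empirical_conventions(self):
        null = np.arange(500, dtype=float)
        _, _, plug = z_and_pvalues(1000.0, null)
        assert plug == 0.0
        _, _, add1 = z_and_pvalues(1000.0, null, empirical="add_one")
        assert add1 == pytest.approx(1 / 501)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateNullError):
            z_and_pvalues(1.0, np.ones(10))


class TestMultipoint:
    def test_window_of_one_reduces_to_singlepoint(self, rng):
        obs = rng.normal(10, 2, size=5)
        null = rng.normal(10, 2, size=(200, 5))
        res = multipoint_window(obs, null, [2])
        z, p_asym, p_emp = z_and_pvalues(obs[2], null[:, 2])
        assert res["Z"] == pytest.approx(z)
        assert res["p_empirical"] == pytest.approx(p_emp)

    def test_duplicated_marker_doubles_scores_z_unchanged(self, rng):
        """Two perfectly linked identical markers double observed and null
        scores but leave Z invariant."""
        obs1 = rng.normal(10, 2, size=1)
        null1 = rng.normal(10, 2, size=(300, 1))
        obs2 = np.repeat(obs1, 2)
        null2 = np.repeat(null1, 2, axis=1)
        single = multipoint_window(obs1, null1, [0])
        double = multipoint_window(obs2, null2, [0, 1])
        assert double["observed"] == pytest.approx(2 * single["observed"])
        assert double["null_mean"] == pytest.approx(2 * single["null_mean"])
        assert double["Z"] == pytest.approx(single["Z"])

    def test_matches_bruteforce_sum(self, rng):
        obs = rng.normal(5, 1, size=4)
        null = rng.normal(5, 1, size=(100, 4))
        res = multipoint_window(obs, null, [1, 2, 3])
        assert res["observed"] == pytest.approx(obs[1:].sum())
        brute_null = null[:, 1:].sum(axis=1)
        assert res["null_mean"] == pytest.approx(brute_null.mean())


class TestGrid:
    def test_weights_at_marker(self):
        assert grid_weights(0.0, 5.0) == (1.0, 0.0)
        assert grid_weights(5.0, 0.0) == (0.0, 1.0)

    def test_weights_midpoint(self):
        w_l, w_r = grid_weights(3.0, 3.0)
        assert w_l == pytest.approx(0.5)
        assert w_r == pytest.approx(0.5)

    def test_weights_asymmetric_hand_computation(self):
        """d_L=1 cM, d_R=4 cM: w_L = (1/theta_1)/((1/theta_1)+(1/theta_4))."""
        theta1 = 0.5 * (1 - math.exp(-0.02))
        theta4 = 0.5 * (1 - math.exp(-0.08))
        expect = (1 / theta1) / ((1 / theta1) + (1 / theta4))
        w_l, w_r = grid_weights(1.0, 4.0)
        assert w_l == pytest.approx(expect, abs=1e-9)
        assert w_l + w_r == pytest.approx(1.0, abs=1e-12)

    def test_grid_scores_at_markers_and_midpoints(self, rng):
        obs = np.array([10.0, 20.0])
        null = rng.normal(15, 3, size=(100, 2))
        df, grid, null_grid = grid_multipoint(obs, null, np.array([0.0, 10.0]),
                                              step_cm=5.0)
        assert df.iloc[0]["observed"] == pytest.approx(10.0)
        assert df.iloc[-1]["observed"] == pytest.approx(20.0)
        mid = df.iloc[1]
        assert mid["observed"] == pytest.approx(15.0)
        # null combination applied replicate-wise
        assert null_grid[:, 1] == pytest.approx(null.mean(axis=1))

    def test_single_marker_chromosome_degenerates(self, rng):
        obs = np.array([5.0])
        null = rng.normal(5, 1, size=(50, 1))
        df, grid, _ = grid_multipoint(obs, null, np.array([42.0]))
        assert len(df) == 1
        assert df.iloc[0]["position_cM"] == 42.0


class TestGenomewideAdjust:
    def test_boundaries_and_single_locus_reduction(self, rng):
        null = rng.normal(0, 1, size=(1, 200))
        # observed Z above every replicate's max -> 0; below every max -> 1
        assert genomewide_adjust(np.array([99.0]), null)[0] == 0.0
        assert genomewide_adjust(np.array([-99.0]), null)[0] == 1.0
        # single locus: adjusted p equals empirical p for any observed value
        scores = rng.normal(3, 2, size=(1, 500))
        obs_score = 4.7
        z = (obs_score - scores.mean()) / scores.std(ddof=1)
        p_emp = (scores[0] >= obs_score).mean()
        adj = genomewide_adjust(np.array([z]), scores)[0]
        assert adj == pytest.approx(p_emp)

    def test_adjusted_geq_empirical_all_loci(self, rng):
        scores = rng.normal(10, 2, size=(8, 300))
        obs = rng.normal(12, 2, size=8)
        z = (obs - scores.mean(axis=1)) / scores.std(axis=1, ddof=1)
        adj = genomewide_adjust(z, scores)
        for k in range(8):
            p_emp = (scores[k] >= obs[k]).mean()
            assert adj[k] >= p_emp - 1e-12

    def test_monotone_in_observed_z(self, rng):
        scores = rng.normal(0, 1, size=(5, 100))
        z_sorted = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        adj = genomewide_adjust(z_sorted, scores)
        assert (np.diff(adj) <= 1e-12).all()

    def test_warns_on_few_replicates(self, rng):
        with pytest.warns(RuntimeWarning):
            genomewide_adjust(np.zeros(2), rng.normal(size=(2, 10)))


class TestMetaCombine:
    def _study(self, label, z, weight=1.0):
        pos = np.arange(0.0, 101.0, 10.0)
        return MetaInput(label, pos, np.full(pos.size, z), weight)

    def test_equal_z_gives_sqrt2(self):
        out = meta_combine([self._study("a", 2.0), self._study("b", 2.0)])
        assert out["Z_meta"].to_numpy() == pytest.approx(
            math.sqrt(2) * 2.0, abs=1e-12
        )

    def test_closed_form_3_and_4(self):
        out = meta_combine([self._study("a", 3.0), self._study("b", 4.0)])
        assert out["Z_meta"].iloc[0] == pytest.approx(7 / math.sqrt(2))
        assert out["Z_meta"].iloc[0] == pytest.approx(4.9497, abs=1e-4)

    def test_vanishing_weight_recovers_other_study(self):
        out = meta_combine(
            [self._study("a", 3.0, weight=1.0), self._study("b", -5.0, weight=1e-9)]
        )
        assert out["Z_meta"].to_numpy() == pytest.approx(3.0, abs=1e-6)

    def test_self_combination_is_sqrt2_scaling(self):
        s = self._study("a", 1.7)
        out = meta_combine([s, s])
        assert out["Z_meta"].to_numpy() == pytest.approx(math.sqrt(2) * 1.7)

    def test_interpolation_onto_overlap(self):
        a = MetaInput("a", np.array([0.0, 100.0]), np.array([0.0, 10.0]))
        b = MetaInput("b", np.array([50.0, 150.0]), np.array([5.0, 5.0]))
        out = meta_combine([a, b], step_cm=25.0)
        assert out["position_cM"].min() == 50.0
        assert out["position_cM"].max() == 100.0
        # at 50 cM: Z_a = 5, Z_b = 5 -> 10/sqrt(2)
        assert out["Z_meta"].iloc[0] == pytest.approx(10 / math.sqrt(2))

    def test_disjoint_maps_raise(self):
        a = MetaInput("a", np.array([0.0, 10.0]), np.zeros(2))
        b = MetaInput("b", np.array([50.0, 60.0]), np.zeros(2))
        with pytest.raises(ValueError):
            meta_combine([a, b])
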