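import numpy as np
import pytest
from scipy import stats

from dmnconn.inference import (
    PermutationConfig,
    bh_fdr,
    chi_square_2x2,
    edgewise_permutation_test,
    metric_permutation_test,
    two_sample_t_from_summary,
)
from dmnconn.simulate import SimulationSpec, generate_cohorts

from .conftest import make_cohort


class TestBhFdr:
    def test_step_up_thresholds_exactly_met(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        q, sig = bh_fdr(p, q=0.05)
        assert sig.all()

    def test_all_ones(self):
        q, sig = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert not sig.any()
        assert np.allclose(q, 1.0)

    def test_single_p_reduces_to_raw(self):
        q, sig = bh_fdr([0.04], q=0.05)
        assert sig[0]
        assert np.isclose(q[0], 0.04)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-4, 1.0, 60)
        q, sig = bh_fdr(p, q=0.05)
        reject, q_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(q, q_sm)
        assert np.array_equal(sig, reject)

    def test_order_invariance(self, rng):
        p = rng.uniform(1e-4, 1.0, 30)
        perm = rng.permutation(30)
        q1, s1 = bh_fdr(p, 0.05)
        q2, s2 = bh_fdr(p[perm], 0.05)
        assert np.allclose(q1[perm], q2)
        assert np.array_equal(s1[perm], s2)

    def test_monotone_over_sorted_p(self, rng):
        p = np.sort(rng.uniform(1e-4, 1.0, 25))
        q, _ = bh_fdr(p, 0.05)
        assert np.all(np.diff(q) >= -1e-15)
        # q_i = min_{k>=i} m p_k / k, so q is capped by its own term and
        # bounded below by the raw p
        assert np.all(q <= p * 25 / np.arange(1, 26) + 1e-12)
        assert np.all(q >= p - 1e-12)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad, 0.05)


class TestTTestFromSummary:
    def test_printed_group_ages(self):
        # mean 34.93 sd 7.89 n 40 vs mean 36.46 sd 7.42 n 41
        t, p = two_sample_t_from_summary(34.93, 7.89, 40, 36.46, 7.42, 41)
        assert round(p, 2) == 0.37

    def test_equal_groups_give_t_zero(self):
        t, p = two_sample_t_from_summary(10.0, 2.0, 15, 10.0, 2.0, 15)
        assert t == 0.0
        assert p == 1.0

    def test_matches_raw_sample_oracle(self, rng):
        # construct samples with exactly the requested mean and sd
        def sample(mean, sd, n):
            x = rng.normal(size=n)
            x = (x - x.mean()) / x.std(ddof=1)
            return x * sd + mean

        a = sample(34.93, 7.89, 40)
        b = sample(36.46, 7.42, 41)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t, p = two_sample_t_from_summary(34.93, 7.89, 40, 36.46, 7.42, 41)
        assert np.isclose(t, t_raw, atol=1e-10)
        assert np.isclose(p, p_raw, atol=1e-10)

    def test_welch_option(self):
        t_w, p_w = two_sample_t_from_summary(1.0, 1.0, 10, 2.0, 4.0, 30, equal_var=False)
        t_s, p_s = two_sample_t_from_summary(1.0, 1.0, 10, 2.0, 4.0, 30)
        assert p_w != p_s

    @pytest.mark.parametrize("kw", [dict(n_a=1), dict(sd_a=0.0), dict(sd_b=-1.0)])
    def test_invalid_inputs_rejected(self, kw):
        args = dict(mean_a=1.0, sd_a=1.0, n_a=10, mean_b=2.0, sd_b=1.0, n_b=10)
        args.update(kw)
        with pytest.raises(ValueError):
            two_sample_t_from_summary(**args)


class TestChiSquare:
    def test_printed_gender_table(self):
        stat, p = chi_square_2x2([[23, 17], [25, 16]])
        assert round(p, 2) == 0.75

    def test_identical_proportions(self):
        stat, p = chi_square_2x2([[20, 20], [20, 20]])
        assert stat == 0.0
        assert p == 1.0

    def test_matches_hand_formula(self):
        obs = np.array([[23.0, 17.0], [25.0, 16.0]])
        total = obs.sum()
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        by_hand = ((obs - expected) ** 2 / expected).sum()
        stat, p = chi_square_2x2(obs)
        assert np.isclose(stat, by_hand, atol=1e-12)
        assert np.isclose(p, stats.chi2.sf(by_hand, df=1), atol=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[1, 2, 3], [4, 5, 6]])


def _two_cohorts(seed=0, n_a=12, n_b=12, planted=()):
    spec = SimulationSpec(n_a=n_a, n_b=n_b, planted_edges=list(planted), seed=seed)
    a, b, _ = generate_cohorts(spec)
    return a, b


class TestEdgewisePermutation:
    def test_identical_cohorts_give_p_one(self, rng):
        X = rng.normal(size=(10, 5))
        a = make_cohort(X, group="patient")
        b = make_cohort(X, group="control")
        res = edgewise_permutation_test(a, b, PermutationConfig(200, seed=1))
        assert np.allclose(res.observed, 0.0)
        assert np.allclose(res.pvalues, 1.0)
        assert not res.significant.any()

    def test_deterministic_given_seed(self):
        a, b = _two_cohorts(seed=3)
        cfg = PermutationConfig(150, seed=9)
        r1 = edgewise_permutation_test(a, b, cfg)
        r2 = edgewise_permutation_test(a, b, cfg)
        assert np.array_equal(r1.pvalues, r2.pvalues)
        assert np.array_equal(r1.qvalues, r2.qvalues)

    def test_different_seed_changes_null(self):
        a, b = _two_cohorts(seed=3)
        r1 = edgewise_permutation_test(a, b, PermutationConfig(150, seed=1))
        r2 = edgewise_permutation_test(a, b, PermutationConfig(150, seed=2))
        assert not np.array_equal(r1.pvalues, r2.pvalues)

    def test_add_one_floor(self):
        a, b = _two_cohorts(seed=5, planted=[("HIP.L", "PCG.L", -0.6)])
        res = edgewise_permutation_test(a, b, PermutationConfig(99, seed=4))
        assert np.all(res.pvalues >= 1.0 / 100.0)
        assert np.all(res.pvalues <= 1.0)

    def test_swapping_groups_negates_observed(self):
        a, b = _two_cohorts(seed=6)
        cfg = PermutationConfig(50, seed=2)
        fwd = edgewise_permutation_test(a, b, cfg)
        rev = edgewise_permutation_test(b, a, cfg)
        assert np.allclose(fwd.observed, -rev.observed, atol=1e-12)

    def test_planted_edge_has_smallest_p(self):
        a, b = _two_cohorts(seed=11, n_a=40, n_b=41, planted=[("HIP.L", "PCG.L", -0.5)])
        res = edgewise_permutation_test(a, b, PermutationConfig(1000, seed=8))
        idx = res.labels.index("PCG.L - HIP.L")
        assert res.pvalues[idx] == res.pvalues.min()
        assert res.pvalues[idx] <= 0.05
        assert res.direction[idx] == -1.0

    def test_91_edges_for_default_atlas(self):
        a, b = _two_cohorts(seed=2)
        res = edgewise_permutation_test(a, b, PermutationConfig(20, seed=0))
        assert len(res.labels) == 91
        assert res.fdr_family_size == 91

    def test_sidedness_less_matches_sign_convention(self):
        a, b = _two_cohorts(seed=11, n_a=40, n_b=41, planted=[("HIP.L", "PCG.L", -0.5)])
        res = edgewise_permutation_test(
            a, b, PermutationConfig(500, seed=8, sidedness="less")
        )
        idx = res.labels.index("PCG.L - HIP.L")
        assert res.pvalues[idx] <= 0.01

    def test_zero_variance_observed_group_rejected(self, rng):
        X = rng.normal(size=(8, 4))
        X[:, 0] = 1.0
        a = make_cohort(X, group="patient")
        b = make_cohort(rng.normal(size=(8, 4)), group="control")
        with pytest.raises(ValueError, match="zero-variance"):
            edgewise_permutation_test(a, b, PermutationConfig(10, seed=0))

    def test_mismatched_voi_order_rejected(self, rng):
        a = make_cohort(rng.normal(size=(5, 3)), voi_names=("A", "B", "C"))
        b = make_cohort(rng.normal(size=(5, 3)), voi_names=("B", "A", "C"))
        with pytest.raises(ValueError, match="VOI order"):
            edgewise_permutation_test(a, b, PermutationConfig(10, seed=0))

    def test_null_pvalues_roughly_uniform(self):
        # 120 independent null replicates; KS on one designated edge
        ps = []
        for rep in range(120):
            a, b = _two_cohorts(seed=10_000 + rep, n_a=10, n_b=10)
            res = edgewise_permutation_test(a, b, PermutationConfig(100, seed=rep))
            ps.append(res.pvalues[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMetricPermutation:
    def test_identical_cohorts_give_p_one(self, rng):
        X = np.abs(rng.normal(1.0, 0.1, size=(10, 5)))
        a = make_cohort(X, group="patient")
        b = make_cohort(X, group="control")
        for metric in ("global_efficiency", "degree_centrality"):
            res = metric_permutation_test(a, b, metric, PermutationConfig(50, seed=1))
            assert np.allclose(res.observed, 0.0)
            assert np.allclose(res.pvalues, 1.0)

    def test_scalar_metric_shapes(self):
        a, b = _two_cohorts(seed=4)
        res = metric_permutation_test(
            a, b, "global_efficiency", PermutationConfig(50, seed=3)
        )
        assert res.observed.shape == (1,)
        assert res.fdr_family_size == 1
        assert res.labels == ["global_efficiency"]

    def test_nodal_metric_bh_family_is_node_count(self):
        a, b = _two_cohorts(seed=4)
        res = metric_permutation_test(
            a, b, "nodal_efficiency", PermutationConfig(50, seed=3)
        )
        assert res.observed.shape == (14,)
        assert res.fdr_family_size == 14
        assert list(res.labels) == list(a[0].voi_names)

    def test_deterministic_given_seed(self):
        a, b = _two_cohorts(seed=4)
        cfg = PermutationConfig(60, seed=5)
        r1 = metric_permutation_test(a, b, "degree_centrality", cfg)
        r2 = metric_permutation_test(a, b, "degree_centrality", cfg)
        assert np.array_equal(r1.pvalues, r2.pvalues)

    def test_uniform_strength_increase_detected(self):
        # group B weakened everywhere: strong positive global-efficiency difference
        base = np.full((14, 14), 0.3)
        np.fill_diagonal(base, 1.0)
        # default base (0.5/0.7) is much stronger than the 0.3 matrix
        a, _, _ = generate_cohorts(SimulationSpec(n_a=60, n_b=3, seed=22))
        _, b, _ = generate_cohorts(SimulationSpec(n_a=3, n_b=60, base_correlation=base, seed=23))
        res = metric_permutation_test(
            a, b, "global_efficiency", PermutationConfig(200, seed=2)
        )
        assert res.observed[0] > 0
        assert res.pvalues[0] <= 0.05

    def test_unknown_metric_rejected(self):
        a, b = _two_cohorts(seed=4)
        with pytest.raises(ValueError, match="metric"):
            metric_permutation_test(a, b, "betweenness", PermutationConfig(10, seed=0))


class TestPermutationConfig:
    @pytest.mark.parametrize(
        "kw",
        [dict(n_permutations=0), dict(fdr_q=0.0), dict(fdr_q=1.0), dict(sidedness="both")],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            PermutationConfig(**kw)
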