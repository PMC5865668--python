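import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from rppaflow import synthetic_data as synth
from rppaflow.differential import (
    BumFit,
    GroupComparisonResult,
    fdr_cutoff,
    fit_bum,
    hierarchical_cluster,
    pooled_t,
    select_top,
    signed_fold,
    two_group_test,
)
from rppaflow.normalization import NON_SCC, SCC, ExpressionMatrix
from rppaflow.synthetic_data import SimulationConfig


def two_group_matrix(x, y):
    vals = {f"a{i}": [v] for i, v in enumerate(x)}
    vals.update({f"b{i}": [v] for i, v in enumerate(y)})
    hist = {f"a{i}": SCC for i in range(len(x))}
    hist.update({f"b{i}": NON_SCC for i in range(len(y))})
    return ExpressionMatrix(values=pd.DataFrame(vals, index=["P"]), histology=hist)


class TestTwoGroupTest:
    def test_identical_groups(self):
        res = two_group_test(two_group_matrix([1.0, 2.0], [1.0, 2.0]))[0]
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0
        assert res.fold_change_signed == 1.0

    def test_fold_sign_convention(self):
        # -1.770 log2 units displays as a 3.41-fold decrease
        assert signed_fold(-1.7697) == pytest.approx(-3.41, abs=0.005)
        assert signed_fold(1.0) == pytest.approx(2.0)
        assert signed_fold(0.0) == 1.0

    def test_against_hand_coded_pooled_t(self, rng):
        x = np.array([0.0, 0.0, 0.0, 0.0]) + rng.normal(0, 1e-6, 4)
        y = np.array([1.0, 1.0, 1.0, 1.0]) + rng.normal(0, 1e-6, 4)
        res = two_group_test(two_group_matrix(x, y))[0]
        # independent oracle: textbook pooled-variance formula
        sp2 = (3 * x.var(ddof=1) + 3 * y.var(ddof=1)) / 6
        t_expected = (x.mean() - y.mean()) / np.sqrt(sp2 * 0.5)
        assert res.t_statistic == pytest.approx(t_expected, rel=1e-12)
        assert abs(res.t_statistic) > 1e4
        assert res.p_value < 1e-6
        assert res.degrees_of_freedom == 6

    def test_antisymmetry_under_label_swap(self, rng):
        x, y = rng.normal(0, 1, 5), rng.normal(0.4, 1, 7)
        fwd = two_group_test(two_group_matrix(x, y))[0]
        rev = two_group_test(two_group_matrix(x, y), group_a=NON_SCC, group_b=SCC)[0]
        assert rev.t_statistic == pytest.approx(-fwd.t_statistic, rel=1e-12)
        assert rev.delta_log2 == pytest.approx(-fwd.delta_log2, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)
        assert np.sign(rev.fold_change_signed) == -np.sign(fwd.fold_change_signed)

    def test_undersized_group_omitted(self):
        m = two_group_matrix([1.0], [2.0, 3.0])
        assert two_group_test(m) == []

    def test_missing_values_dropped(self):
        m = two_group_matrix([1.0, 2.0, np.nan], [3.0, 4.0])
        res = two_group_test(m)[0]
        assert res.delta_log2 == pytest.approx(1.5 - 3.5)


class TestBum:
    def test_uniform_density_at_lambda_one(self):
        fit = BumFit(lambda_mix=1.0, a_shape=0.5, log_likelihood=0.0)
        p = np.linspace(0.01, 1.0, 50)
        assert np.allclose(fit.density(p), 1.0)

    def test_loglik_zero_for_uniform_model(self, rng):
        p = rng.uniform(size=100)
        fit = BumFit(lambda_mix=1.0, a_shape=0.5, log_likelihood=0.0)
        assert np.log(fit.density(p)).sum() == pytest.approx(0.0)

    @given(
        lam=st.floats(0.0, 1.0),
        a=st.floats(0.01, 0.99),
    )
    @settings(max_examples=30, deadline=None)
    def test_density_integrates_to_one(self, lam, a):
        fit = BumFit(lambda_mix=lam, a_shape=a, log_likelihood=0.0)
        # QAGS handles the p**(a-1) endpoint singularity by extrapolation
        val, err = quad(fit.density, 0.0, 1.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-9 + 10 * err)

    def test_uniform_pvalues_give_high_pi0(self):
        rng = np.random.default_rng(0)
        fit = fit_bum(rng.uniform(size=5000))
        assert fit.pi0_upper >= 0.95

    def test_input_validation(self):
        with pytest.raises(ValueError, match="p-values"):
            fit_bum(np.array([0.0] + [0.5] * 20))
        with pytest.raises(ValueError, match="at least 10"):
            fit_bum(np.array([0.5] * 5))

    def test_p_equal_one_accepted(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(size=50), [1.0, 1.0]])
        fit = fit_bum(p)
        assert 0.0 < fit.pi0_upper <= 1.0

    def test_mixture_recovery_against_small_grid(self):
        # grid-search ML oracle at coarse resolution; the full 200x200
        # comparison runs in the acceptance suite
        rng = np.random.default_rng(7)
        p = np.concatenate([rng.uniform(size=4000), rng.beta(0.3, 1.0, 1000)])
        fit = fit_bum(p)
        lams = np.linspace(0.0025, 0.9975, 100)
        shapes = np.linspace(0.0025, 0.9975, 100)
        best = (-np.inf, None, None)
        for a in shapes:
            dens = lams[:, None] + (1 - lams[:, None]) * a * p[None, :] ** (a - 1)
            ll = np.log(dens).sum(axis=1)
            i = int(np.argmax(ll))
            if ll[i] > best[0]:
                best = (ll[i], lams[i], a)
        assert abs(fit.lambda_mix - best[1]) < 0.05
        assert abs(fit.a_shape - best[2]) < 0.05
        assert fit.log_likelihood >= best[0] - 1e-6


class TestFdrCutoff:
    def test_pure_null_no_rejections(self):
        fit = BumFit(lambda_mix=1.0, a_shape=0.5, log_likelihood=0.0)
        dec = fdr_cutoff(fit, 0.01)
        assert dec.tau_cutoff == 0.0
        assert dec.n_significant == 0

    def test_fdr_at_one_equals_pi0(self):
        fit = BumFit(lambda_mix=0.8, a_shape=0.3, log_likelihood=0.0)
        assert fit.estimated_fdr(1.0) == pytest.approx(fit.pi0_upper, rel=1e-12)

    def test_cutoff_matches_grid_scan(self):
        fit = BumFit(lambda_mix=0.8, a_shape=0.3, log_likelihood=0.0)
        dec = fdr_cutoff(fit, 0.01)
        taus = np.geomspace(1e-12, 1.0, 1_000_000)
        ok = taus[fit.estimated_fdr(taus) <= 0.01]
        assert dec.tau_cutoff == pytest.approx(ok.max(), rel=1e-4)

    def test_fdr_monotone_in_tau(self):
        fit = BumFit(lambda_mix=0.7, a_shape=0.25, log_likelihood=0.0)
        taus = np.geomspace(1e-10, 1.0, 10000)
        fdr = fit.estimated_fdr(taus)
        assert np.all(np.diff(fdr) >= -1e-12)

    def test_invalid_q_rejected(self):
        fit = BumFit(lambda_mix=0.8, a_shape=0.3, log_likelihood=0.0)
        with pytest.raises(ValueError, match="nominal_q"):
            fdr_cutoff(fit, 1.5)

    def test_significant_list_populated(self):
        fit = BumFit(lambda_mix=0.5, a_shape=0.2, log_likelihood=0.0)
        results = [
            GroupComparisonResult("p1", 1.0, 2.0, 5.0, 10, 1e-8),
            GroupComparisonResult("p2", 0.1, 1.07, 0.5, 10, 0.6),
        ]
        dec = fdr_cutoff(fit, 0.05, results=results)
        assert dec.significant == ["p1"]
        assert dec.n_significant == 1


class TestSelectTop:
    def test_no_hits(self):
        results = [GroupComparisonResult("p", 0, 1, 0, 10, 0.5)] * 3
        assert select_top(results, 0.05) == []

    def test_threshold_strict(self):
        results = [
            GroupComparisonResult("a", 0, 1, 0, 10, 0.01),
            GroupComparisonResult("b", 0, 1, 0, 10, 0.04),
            GroupComparisonResult("c", 0, 1, 0, 10, 0.06),
        ]
        assert select_top(results, 0.05) == ["a", "b"]

    def test_tie_break_by_name(self):
        results = [
            GroupComparisonResult("z", 0, 1, 0, 10, 0.01),
            GroupComparisonResult("a", 0, 1, 0, 10, 0.01),
        ]
        assert select_top(results, 0.05) == ["a", "z"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_top([], 0.05)

    def test_power_on_planted_effects(self):
        # Monte-Carlo power oracle: 30 planted 1.5-fold effects among 200
        # proteins, n = 34 vs 106, noise sd 0.5 -> recall >= 80% at p < 0.05
        effects = [(f"hit{i:02d}", 1.5) for i in range(30)]
        config = SimulationConfig(
            seed=21, n_scc=34, n_nonscc=106, effect_table=effects,
            n_null_proteins=170, protein_noise_sd=0.5, duplicate_fraction=0.0,
        )
        matrix, _ = synth.generate_cohort_matrix(config)
        results = two_group_test(matrix)
        top = set(select_top(results, 0.05))
        planted = {name for name, _ in effects}
        recall = len(top & planted) / len(planted)
        assert recall >= 0.80


def brute_force_average_linkage(dist):
    """Independent oracle: enumerate all pair distances at every step."""
    clusters = [[i] for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0] - 1e-15:
                    best = (d, (i, j))
        d, (i, j) = best
        merges.append((frozenset(clusters[i]), frozenset(clusters[j]), d))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return merges


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, -2.0]],
            index=["a", "b", "c"], columns=["x", "y", "z"],
        )
        res = hierarchical_cluster(df)
        assert res.row_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert sorted(res.row_linkage[0, :2]) == [0, 1]

    def test_scale_invariance(self):
        df = pd.DataFrame(
            np.random.default_rng(3).normal(size=(4, 6)),
            index=list("abcd"),
        )
        scaled = df.mul([2.0, 5.0, 0.5, 11.0], axis=0)
        r1 = hierarchical_cluster(df)
        r2 = hierarchical_cluster(scaled)
        assert np.allclose(r1.row_linkage, r2.row_linkage)
        assert r1.row_order == r2.row_order

    def test_matches_brute_force_oracle(self):
        df = pd.DataFrame(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.1, 2.2, 2.9, 4.2],
                [4.0, 3.0, 2.0, 1.0],
                [0.5, 3.0, 1.0, 3.5],
            ],
            index=list("abcd"),
        )
        from rppaflow.differential import correlation_distance_matrix

        dist, _ = correlation_distance_matrix(df.to_numpy())
        expected = brute_force_average_linkage(dist)
        res = hierarchical_cluster(df)
        # same merge heights in the same order
        got_heights = res.row_linkage[:, 2]
        assert np.allclose(got_heights, [m[2] for m in expected], atol=1e-12)

    def test_zero_variance_row_max_distance(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=["flat", "up", "down"],
        )
        res = hierarchical_cluster(df)
        assert "flat" in res.degenerate_rows
        # flat row joins last, at distance 2
        assert res.row_linkage[-1, 2] == pytest.approx(2.0)

    def test_missing_imputed_by_row_median(self):
        df = pd.DataFrame(
            [[1.0, np.nan, 3.0], [1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]],
            index=list("abc"),
        )
        res = hierarchical_cluster(df)  # must not raise
        assert len(res.row_order) == 3

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]))

    def test_newick_output_parses(self):
        df = pd.DataFrame(
            np.random.default_rng(5).normal(size=(5, 4)), index=list("abcde")
        )
        res = hierarchical_cluster(df)
        assert res.row_newick.endswith(";")
        for leaf in "abcde":
            assert leaf in res.row_newick
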