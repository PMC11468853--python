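import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from klsnet.stats import (
    adjusted_group_test,
    demographic_tests,
    fdr_correct,
    nbs,
    partial_correlation,
    power_required_n,
)


def covariates(rng, n):
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(46, 12, n),
        "education": rng.normal(11, 4, n),
    })


class TestAdjustedGroupTest:
    def test_mirrored_outcome_has_zero_group_effect(self, rng):
        vals = rng.random(20)
        y = np.concatenate([vals, vals])          # both groups identical
        g = np.r_[np.ones(20), np.zeros(20)]
        res = adjusted_group_test(y, g, cov=None)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)
        # with noise covariates the adjusted effect stays negligible
        res2 = adjusted_group_test(y, g, covariates(rng, 40))
        assert abs(res2.t) < 0.7 and res2.p > 0.4

    def test_reduces_to_plain_t_test_without_covariates(self, rng):
        y = rng.normal(size=30)
        g = np.r_[np.ones(15), np.zeros(15)]
        res = adjusted_group_test(y, g, cov=None)
        t_ref, p_ref = sps.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert res.t == pytest.approx(t_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_power_against_a_two_sd_planted_shift(self, rng):
        hits = 0
        for _ in range(200):
            g = np.r_[np.ones(30), np.zeros(30)]
            y = rng.normal(size=60) + 2.0 * g
            cov = covariates(rng, 60)
            if adjusted_group_test(y, g, cov).p < 0.001:
                hits += 1
        assert hits >= 190                         # >= 95% of simulations

    def test_covariate_mediated_effect_is_removed(self, rng):
        """If the group difference is entirely carried by age, adjusting for
        age leaves a null test (uniform p over simulations)."""
        pvals = []
        for _ in range(200):
            g = np.r_[np.ones(30), np.zeros(30)]
            age = rng.normal(46, 5, 60) + 6 * g
            y = 0.1 * age + rng.normal(scale=0.2, size=60)
            cov = pd.DataFrame({"age": age})
            pvals.append(adjusted_group_test(y, g, cov).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_rank_deficient_design_rejected(self, rng):
        y = rng.normal(size=20)
        g = np.r_[np.ones(10), np.zeros(10)]
        cov = pd.DataFrame({"dup": g})             # collinear with group
        with pytest.raises(ValueError, match="rank"):
            adjusted_group_test(y, g, cov)

    def test_minimum_group_size(self, rng):
        y = rng.normal(size=5)
        with pytest.raises(ValueError):
            adjusted_group_test(y, np.array([1, 1, 0, 0, 0]), None)


class TestFdr:
    def test_hand_computed_step_up(self):
        adj = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged_and_all_ones(self):
        assert fdr_correct(np.array([0.2]))[0] == pytest.approx(0.2)
        assert np.all(fdr_correct(np.ones(5)) == 1.0)

    def test_order_invariance_and_monotonicity(self, rng):
        p = rng.random(50)
        perm = rng.permutation(50)
        assert np.allclose(fdr_correct(p)[perm], fdr_correct(p[perm]))
        assert np.all(fdr_correct(p) >= p - 1e-15)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([]))


def _random_edge_stack(rng, n_sub, n_nodes):
    stack = rng.random((n_sub, n_nodes, n_nodes))
    stack = (stack + stack.transpose(0, 2, 1)) / 2
    for k in range(n_sub):
        np.fill_diagonal(stack[k], 0)
    return stack


class TestNbs:
    def test_relabeling_invariance(self, rng):
        n_sub, n_nodes = 24, 10
        stack = _random_edge_stack(rng, n_sub, n_nodes)
        group = np.r_[np.ones(12), np.zeros(12)]
        # plant a strong component so observed statistics are stable
        for i, j in [(0, 1), (1, 2), (0, 2)]:
            stack[group == 1, i, j] -= 0.8
            stack[group == 1, j, i] -= 0.8
        cov = covariates(rng, n_sub).to_numpy()
        order = rng.permutation(n_sub)
        res1 = nbs(stack, group, cov, n_perm=300, rng_seed=5)
        res2 = nbs(stack[order], group[order], cov[order], n_perm=300, rng_seed=5)
        assert [c.size for c in res1.components] == [c.size for c in res2.components]
        assert {frozenset(c.edges) for c in res1.components} == \
               {frozenset(c.edges) for c in res2.components}
        assert [c.p_fwe for c in res1.significant] == [c.p_fwe for c in res2.significant]

    def test_planted_component_is_detected(self, rng):
        n_sub = 40
        stack = _random_edge_stack(rng, n_sub, 12)
        group = np.r_[np.ones(20), np.zeros(20)]
        planted = [(a, b) for a in range(5) for b in range(a + 1, 5)]
        for i, j in planted:
            stack[group == 1, i, j] -= 0.45
            stack[group == 1, j, i] -= 0.45
        res = nbs(stack, group, None, n_perm=300, rng_seed=1)
        assert res.significant
        comp = res.significant[0]
        recovered = sum(1 for e in comp.edges if tuple(sorted(e)) in planted)
        assert recovered >= 8

    def test_empty_result_with_warning_not_error(self, rng, caplog):
        stack = _random_edge_stack(rng, 20, 8)
        group = np.r_[np.ones(10), np.zeros(10)]
        with caplog.at_level("WARNING"):
            res = nbs(stack, group, None, edge_p=1e-10, n_perm=50, rng_seed=0)
        assert res.components == []
        assert any("no edge survives" in r.message for r in caplog.records)

    def test_p_fwe_never_zero(self, rng):
        stack = _random_edge_stack(rng, 24, 8)
        group = np.r_[np.ones(12), np.zeros(12)]
        stack[group == 1, 0, 1] -= 2.0
        stack[group == 1, 1, 0] -= 2.0
        res = nbs(stack, group, None, n_perm=100, rng_seed=0)
        for c in res.components:
            assert c.p_fwe >= 1 / 101

    def test_increase_tail_finds_positive_shifts(self, rng):
        stack = _random_edge_stack(rng, 30, 8)
        group = np.r_[np.ones(15), np.zeros(15)]
        stack[group == 1, 2, 3] += 1.5
        stack[group == 1, 3, 2] += 1.5
        res = nbs(stack, group, None, n_perm=200, tail="increase", rng_seed=2)
        assert any((2, 3) in c.edges for c in res.significant)


class TestPartialCorrelation:
    def test_perfect_dependence(self, rng):
        x = rng.normal(size=30)
        r, p = partial_correlation(x, x.copy(), covariates(rng, 30))
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_correlation_with_a_covariate_vanishes(self, rng):
        # y dominated by a covariate (plus slight noise so residual variance
        # survives); adjustment should strip the association with x = age
        cov = covariates(rng, 60)
        age = cov["age"].to_numpy()
        y = age + rng.normal(scale=1e-3 * age.std(), size=60)
        x = 0.8 * age + rng.normal(scale=5.0, size=60)
        raw = np.corrcoef(x, y)[0, 1]
        r, _ = partial_correlation(x, y, cov)
        assert abs(raw) > 0.5
        assert abs(r) < 0.05

    def test_null_p_values_are_uniform(self, rng):
        pvals = []
        cov = covariates(rng, 55)
        for _ in range(1000):
            x, y = rng.normal(size=55), rng.normal(size=55)
            pvals.append(partial_correlation(x, y, cov)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        cov = covariates(rng, 40)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        df = cov.assign(x=x, y=y)
        ref = pingouin.partial_corr(df, x="x", y="y",
                                    covar=["sex", "age", "education"])
        r, p = partial_correlation(x, y, cov)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_zero_residual_variance_rejected(self, rng):
        cov = pd.DataFrame({"age": rng.normal(size=20)})
        x = 2.0 * cov["age"].to_numpy()            # fully explained by age
        with pytest.raises(ValueError):
            partial_correlation(x, rng.normal(size=20), cov)


class TestDemographics:
    def test_balanced_categorical_gives_p_one(self):
        table = pd.DataFrame({
            "group": [1] * 20 + [0] * 20,
            "sex": ([0] * 10 + [1] * 10) * 2,
        })
        res = demographic_tests(table, categorical=("sex",))
        row = res.set_index("variable").loc["sex"]
        assert row["statistic"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_separated_continuous_variable(self, rng):
        table = pd.DataFrame({
            "group": [1] * 50 + [0] * 50,
            "score": np.r_[rng.normal(0, 1, 50), rng.normal(3, 1, 50)],
        })
        res = demographic_tests(table).set_index("variable")
        assert res.loc["score", "test"] == "mannwhitney"
        assert res.loc["score", "p"] < 1e-6

    def test_sparse_category_falls_back_to_fisher(self, rng):
        table = pd.DataFrame({
            "group": [1] * 12 + [0] * 12,
            "sex": [0] * 12 + [0] * 11 + [1],
        })
        with pytest.warns(UserWarning, match="Fisher"):
            res = demographic_tests(table, categorical=("sex",))
        assert res.set_index("variable").loc["sex", "test"] == "fisher"


class TestPower:
    def test_reference_computation(self):
        assert power_required_n(0.80, 0.05, 0.8) == 26

    def test_huge_effect_needs_minimum_fittable_n(self):
        assert power_required_n(1e6, 0.05, 0.8) == 2

    def test_agrees_with_independent_power_solver(self):
        statsmodels_power = pytest.importorskip("statsmodels.stats.power")
        solver = statsmodels_power.TTestIndPower()
        for d in (0.5, 0.8, 1.2):
            ref = int(np.ceil(solver.solve_power(
                effect_size=d, alpha=0.05, power=0.8, alternative="two-sided"
            )))
            assert power_required_n(d, 0.05, 0.8) == ref

    def test_monotone_in_effect_size_and_alpha(self):
        assert power_required_n(0.5) >= power_required_n(0.8) >= power_required_n(1.2)
        assert power_required_n(0.8, alpha=0.01) >= power_required_n(0.8, alpha=0.05)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            power_required_n(-1.0)
        with pytest.raises(ValueError):
            power_required_n(0.8, alpha=1.5)
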