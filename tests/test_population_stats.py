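"""Statistical-layer tests: quantile convention, group tests, ANOVA oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from saltatrack.population_stats import (
    SpeedPopulation,
    check_loss_quantile,
    chi_square_table,
    mixed_rm_anova,
    percent_fast,
    quantile_group_contrast,
    speed_percentiles,
    t_from_summary,
    t_from_values,
)


def brute_force_quantile(values, tau, grid=None):
    """Check-loss minimiser by dense search; midpoint of the flat region."""
    values = np.sort(np.asarray(values, dtype=float))
    lo, hi = values.min() - 1, values.max() + 1
    grid = np.unique(np.concatenate([values, np.linspace(lo, hi, 4001)]))
    loss = np.array(
        [
            (tau * np.clip(values - q, 0, None) + (1 - tau) * np.clip(q - values, 0, None)).sum()
            for q in grid
        ]
    )
    minimisers = grid[loss <= loss.min() + 1e-12]
    return 0.5 * (minimisers.min() + minimisers.max())


class TestQuantiles:
    def test_median_of_odd_sample(self):
        pop = SpeedPopulation("g", np.array([1, 2, 3, 4, 5.0]))
        assert speed_percentiles(pop, [0.5])[0] == 3.0

    def test_constant_population(self):
        pop = SpeedPopulation("g", np.full(17, 0.4))
        np.testing.assert_allclose(speed_percentiles(pop, [0.1, 0.5, 0.9]), 0.4)

    @settings(deadline=None, max_examples=60)
    @given(
        hst.lists(hst.floats(0, 10, allow_nan=False), min_size=2, max_size=40),
        hst.sampled_from([0.1, 0.25, 0.5, 0.75, 0.9]),
    )
    def test_matches_brute_force_check_loss_minimiser(self, values, tau):
        got = check_loss_quantile(np.array(values), tau)
        want = brute_force_quantile(values, tau)
        assert got == pytest.approx(want, abs=1e-6)

    def test_non_decreasing_in_tau(self, rng):
        pop = SpeedPopulation("g", rng.exponential(0.05, 500))
        qs = speed_percentiles(pop, [0.1, 0.25, 0.5, 0.75, 0.9])
        assert (np.diff(qs) >= 0).all()

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            speed_percentiles(SpeedPopulation("g", np.array([])), [0.5])


class TestQuantileContrast:
    def test_shifted_sample_exact_median_difference(self):
        c = SpeedPopulation("c", np.array([1.0, 2.0, 3.0]))
        p = SpeedPopulation("p", np.array([2.0, 3.0, 4.0]))
        res = quantile_group_contrast(c, p, [0.5], n_boot=200, seed=0)
        assert res[0].estimate == pytest.approx(1.0)

    def test_identical_populations_zero_estimate(self, rng):
        x = rng.exponential(0.05, 200)
        c = SpeedPopulation("c", x)
        p = SpeedPopulation("p", x.copy())
        for r in quantile_group_contrast(c, p, [0.1, 0.5, 0.9], n_boot=200, seed=1):
            assert r.estimate == 0.0

    def test_location_shift_recovered_within_ci(self, rng):
        delta = 0.02
        base = rng.gamma(4.0, 0.015, 800) + delta
        c = SpeedPopulation("c", base)
        p = SpeedPopulation("p", base - delta)
        taus = [0.25, 0.5, 0.75]
        for r in quantile_group_contrast(c, p, taus, n_boot=300, seed=2):
            assert r.ci95[0] - 1e-6 <= -delta <= r.ci95[1] + 1e-6
            assert r.estimate == pytest.approx(-delta, abs=0.01)

    def test_estimate_equals_independent_quantile_difference(self, rng):
        c = SpeedPopulation("c", rng.exponential(0.06, 150))
        p = SpeedPopulation("p", rng.exponential(0.03, 170))
        taus = [0.1, 0.5, 0.9]
        res = quantile_group_contrast(c, p, taus, n_boot=200, seed=3)
        for tau, r in zip(taus, res):
            want = check_loss_quantile(p.speeds, tau) - check_loss_quantile(c.speeds, tau)
            assert r.estimate == pytest.approx(want, abs=1e-12)

    def test_too_few_bootstrap_rejected(self):
        c = SpeedPopulation("c", np.ones(5))
        with pytest.raises(ValueError):
            quantile_group_contrast(c, c, [0.5], n_boot=50, seed=0)


class TestTTests:
    def test_viability_summary_t(self):
        # survival after oxidative challenge: 98.71±11.09 vs 68.57±5.85, n=5/5
        r = t_from_summary(98.71, 11.09, 5, 68.57, 5.85, 5)
        assert r.statistic == pytest.approx(2.404, abs=5e-4)
        assert r.df == 8

    def test_equal_means_zero_t(self):
        assert t_from_summary(5.0, 1.0, 5, 5.0, 2.0, 5).statistic == 0.0

    def test_organelle_count_summary_t(self):
        # 80.4±4.46 vs 58.06±3.83 per process, n=5/5; printed 3.808 from
        # unrounded inputs, recomputed from rounded summaries within 0.5%
        r = t_from_summary(80.4, 4.46, 5, 58.06, 3.83, 5)
        assert r.statistic == pytest.approx(3.808, rel=0.005)

    def test_summary_and_raw_value_t_agree(self, rng):
        g1 = rng.normal(10, 2, 8)
        g2 = rng.normal(12, 2, 8)
        raw = t_from_values(g1, g2)
        # pooled t from raw values equals scipy's reference implementation
        want = sps.ttest_ind(g1, g2)
        assert raw.statistic == pytest.approx(want.statistic, rel=1e-10)
        assert raw.p == pytest.approx(want.pvalue, rel=1e-9)
        # equal-n summary t uses sem1²+sem2² = pooled formula: identical
        summ = t_from_summary(g1.mean(), sps.sem(g1), 8, g2.mean(), sps.sem(g2), 8)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)

    def test_zero_variance_flagged(self):
        r = t_from_values([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert not np.isfinite(r.statistic) and r.note

    def test_invalid_sem_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1, 0.0, 5, 2, 1.0, 5)


class TestChiSquare:
    def test_independent_table_zero(self):
        r = chi_square_table([[10, 10], [10, 10]])
        assert r.statistic == 0.0 and r.df == 1

    def test_diagonal_table_hand_value(self):
        r = chi_square_table([[20, 0], [0, 20]])
        assert r.statistic == pytest.approx(40.0)

    def test_matches_direct_sum_and_scipy(self, rng):
        obs = rng.integers(1, 50, (3, 3)).astype(float)
        r = chi_square_table(obs)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert r.statistic == pytest.approx((((obs - expected) ** 2) / expected).sum())
        ref = sps.chi2_contingency(obs, correction=False)
        assert r.statistic == pytest.approx(ref.statistic)
        assert r.df == ref.dof

    def test_invariant_under_row_and_column_permutation(self, rng):
        obs = rng.integers(1, 30, (3, 4)).astype(float)
        r0 = chi_square_table(obs)
        r1 = chi_square_table(obs[::-1][:, ::-1])
        assert r0.statistic == pytest.approx(r1.statistic)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_table([[0, 0], [5, 5]])


class TestMixedRMAnova:
    @staticmethod
    def _design():
        table = pd.DataFrame(
            {"baseline": [10.0, 12.0, 20.0, 22.0], "H2O2": [14.0, 18.0, 26.0, 30.0]},
            index=["c1", "c2", "p1", "p2"],
        )
        between = {"c1": "control", "c2": "control", "p1": "patient", "p2": "patient"}
        return table, between

    def test_hand_worked_two_by_two(self):
        # SS by hand: group 242 (err 18, df 2), condition 72, interaction 2,
        # residual 2 (df 2) -> F = 242/9, 72/1, 2/1
        table, between = self._design()
        res = mixed_rm_anova(table, between)
        assert res["group"]["F"] == pytest.approx(242 / 9, abs=1e-8)
        assert res["condition"]["F"] == pytest.approx(72.0, abs=1e-8)
        assert res["interaction"]["F"] == pytest.approx(2.0, abs=1e-8)
        assert res["group"]["df"] == (1, 2)
        assert res["condition"]["df"] == (1, 2)

    def test_matches_pingouin_reference(self):
        import pingouin as pg

        table, between = self._design()
        long = table.reset_index().melt(id_vars="index", var_name="cond", value_name="y")
        long["group"] = long["index"].map(between)
        ref = pg.mixed_anova(long, dv="y", within="cond", subject="index", between="group")
        res = mixed_rm_anova(table, between)
        f_group = float(ref.loc[ref["Source"] == "group", "F"].iloc[0])
        f_inter = float(ref.loc[ref["Source"] == "Interaction", "F"].iloc[0])
        f_cond = float(ref.loc[ref["Source"] == "cond", "F"].iloc[0])
        assert res["group"]["F"] == pytest.approx(f_group, rel=1e-9)
        assert res["condition"]["F"] == pytest.approx(f_cond, rel=1e-9)
        assert res["interaction"]["F"] == pytest.approx(f_inter, rel=1e-9)

    def test_all_equal_values_guarded(self):
        table = pd.DataFrame(
            {"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0, 1.0]},
            index=["c1", "c2", "p1", "p2"],
        )
        res = mixed_rm_anova(table, {"c1": "g1", "c2": "g1", "p1": "g2", "p2": "g2"})
        assert res["group"]["F"] == 0.0 and res["condition"]["F"] == 0.0

    def test_pure_group_offset_no_condition_effect(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, 5.0, 6.0], "b": [1.0, 2.0, 5.0, 6.0]},
            index=["c1", "c2", "p1", "p2"],
        )
        res = mixed_rm_anova(table, {"c1": "g1", "c2": "g1", "p1": "g2", "p2": "g2"})
        assert res["condition"]["F"] == 0.0
        assert res["interaction"]["F"] == 0.0
        assert res["group"]["F"] > 0

    def test_group_f_collapses_to_oneway_anova_on_condition_means(self, rng):
        vals = rng.normal(10, 2, (6, 3))
        table = pd.DataFrame(vals, index=[f"s{i}" for i in range(6)], columns=list("abc"))
        between = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = mixed_rm_anova(table, between)
        means = table.mean(axis=1)
        ref = sps.f_oneway(means[:3], means[3:])
        assert res["group"]["F"] == pytest.approx(ref.statistic, rel=1e-9)

    def test_unbalanced_design_rejected(self):
        table, between = self._design()
        between = dict(between, p2="extra_group")  # 1-subject group
        with pytest.raises(ValueError):
            mixed_rm_anova(table, between)


class TestPercentFast:
    def test_simple_fractions(self):
        pop = SpeedPopulation("g", np.array([0.05] * 9 + [0.2]))
        assert percent_fast(pop)["overall_percent"] == pytest.approx(10.0)
        pop0 = SpeedPopulation("g", np.array([0.05] * 10))
        assert percent_fast(pop0)["overall_percent"] == 0.0

    def test_per_line_aggregation_within_ci(self, rng):
        # 5 synthetic lines x 400 tracks at generative fast fraction 0.10
        speeds, lines = [], []
        for li in range(5):
            fast = rng.random(400) < 0.10
            speeds.append(np.where(fast, 0.2, 0.05))
            lines.append(np.full(400, f"line{li}"))
        pop = SpeedPopulation("g", np.concatenate(speeds), np.concatenate(lines))
        out = percent_fast(pop)
        assert len(out["per_line_percent"]) == 5
        assert abs(out["line_mean"] / 100 - 0.10) <= 1.96 * np.sqrt(0.1 * 0.9 / 2000)
        assert out["line_sem"] > 0
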