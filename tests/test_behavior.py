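"""Behavioral statistics: pruning against a sort-based quantile oracle,
RM-ANOVAs against independent implementations, adaptation magnitude, and
the noncentral-F sample-size computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from numadapt.behavior import (PowerSpec, adaptation_magnitude,
                               prune_estimates, required_sample_size,
                               rm_anova_oneway, rm_anova_power,
                               rm_anova_twoway)
from numadapt.synthetic import (BehavioralGenSpec, generate_behavior,
                                simulate_experiment)


def quantile_oracle(values, q):
    """Sort-based linear-interpolation quantile, written independently."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def make_table(matrix, conditions=("Baseline", "Adaptation", "Neutral")):
    """participant x condition means -> minimal trial table."""
    rows = []
    for p, row in enumerate(np.atleast_2d(matrix)):
        for cond, val in zip(conditions, row):
            rows.append((p, 1, cond, 30, "left", val))
    return pd.DataFrame(rows, columns=["participant", "block", "condition",
                                       "numerosity", "hemifield", "estimate"])


class TestPruning:
    def test_constant_data_untouched(self):
        res = prune_estimates([30] * 20)
        assert res.removed_fraction == 0
        assert len(res.kept) == 20

    def test_outliers_removed_per_quantile_oracle(self):
        values = [10, 28, 29, 30, 31, 32, 100]
        q1 = quantile_oracle(values, 0.25)
        q3 = quantile_oracle(values, 0.75)
        res = prune_estimates(values)
        assert res.bounds_used == (q1 / 2, 2 * q3)
        assert 100 not in res.kept  # exceeds twice the upper quartile
        assert 10 not in res.kept   # below half the lower quartile
        assert sorted(res.kept) == [28, 29, 30, 31, 32]

    def test_idempotent_on_clean_data(self):
        first = prune_estimates([30.0] * 10 + [31.0] * 10)
        second = prune_estimates(first.kept)
        assert second.removed_fraction == 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            prune_estimates([30, 31, 32])

    @given(st.lists(st.floats(1, 100), min_size=4, max_size=50))
    def test_interquartile_values_never_removed(self, values):
        q1 = quantile_oracle(values, 0.25)
        q3 = quantile_oracle(values, 0.75)
        kept = set(prune_estimates(values).kept)
        for v in values:
            if q1 <= v <= q3:
                assert v in kept


class TestOnewayRmAnova:
    def test_identical_conditions_give_zero_f(self):
        y = np.array([[28.0, 28.0, 28.0], [30.0, 30.0, 30.0],
                      [31.0, 31.0, 31.0], [25.0, 25.0, 25.0]])
        res = rm_anova_oneway(make_table(y))
        assert res.F == 0.0

    def test_matches_independent_ss_decomposition(self):
        """Hand-made 4x3 table against a from-scratch cell-mean SS oracle
        and against statsmodels AnovaRM."""
        y = np.array([[27.0, 24.0, 29.0], [30.0, 25.0, 30.0],
                      [28.0, 22.0, 27.0], [33.0, 26.0, 31.0]])
        res = rm_anova_oneway(make_table(y))

        # oracle 1: explicit deviation sums, loops only
        n, k = y.shape
        grand = y.sum() / y.size
        ss_cond = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
        ss_err = sum((y[i, j] - y[i].mean() - y[:, j].mean() + grand) ** 2
                     for i in range(n) for j in range(k))
        f_oracle = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        assert res.F == pytest.approx(f_oracle, rel=1e-10)
        assert res.df == (2, 6)

        # oracle 2: statsmodels repeated-measures ANOVA
        from statsmodels.stats.anova import AnovaRM
        table = make_table(y)
        sm = AnovaRM(table, depvar="estimate", subject="participant",
                     within=["condition"]).fit()
        assert res.F == pytest.approx(sm.anova_table["F Value"].iloc[0],
                                      rel=1e-8)
        assert res.p == pytest.approx(sm.anova_table["Pr > F"].iloc[0],
                                      abs=1e-10)

    def test_scenario_posthoc_pattern(self, experiment):
        """Adaptation differs from Baseline and Neutral (p < .001), while
        Baseline and Neutral do not differ."""
        res = rm_anova_oneway(experiment["behavior"])
        assert res.p < 0.001
        ph = {frozenset(k): v for k, v in res.posthoc.items()}
        assert ph[frozenset(("Adaptation", "Baseline"))] < 0.001
        assert ph[frozenset(("Adaptation", "Neutral"))] < 0.001
        assert ph[frozenset(("Baseline", "Neutral"))] > 0.05

    @given(st.floats(-20, 20), st.floats(0.1, 5))
    def test_f_invariant_under_affine_transform(self, shift, scale):
        y = np.array([[27.0, 24.0, 29.0], [30.0, 25.0, 30.0],
                      [28.0, 22.0, 27.0], [33.0, 26.0, 31.0]])
        base = rm_anova_oneway(make_table(y))
        moved = rm_anova_oneway(make_table(y * scale + shift))
        assert moved.F == pytest.approx(base.F, rel=1e-8)

    def test_missing_cell_names_participant_and_condition(self):
        t0 = make_table(np.array([[27.0, 24.0, 29.0]]))
        t1 = make_table(np.array([[30.0, 25.0, 30.0]]))
        t1["participant"] = 1
        broken = pd.concat([t0, t1[t1.condition != "Neutral"]],
                           ignore_index=True)
        with pytest.raises(ValueError, match="missing cell.*Neutral"):
            rm_anova_oneway(broken)

    def test_type_one_error_calibrated(self):
        """Null RM-ANOVA (n=25) rejects at alpha=.05 in 5% +- 2% of sims."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            y = rng.normal(30, 2, size=(25, 3))
            res = rm_anova_oneway(make_table(y))
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestTwowayRmAnova:
    def test_duplicated_condition_gives_zero_f(self):
        spec = BehavioralGenSpec(n_participants=6, trials_per_condition=4,
                                 seed=4)
        table = generate_behavior(spec)
        base = table[table.condition == "Baseline"].copy()
        dup = base.copy()
        dup["condition"] = "Neutral"
        res = rm_anova_twoway(pd.concat([base, dup], ignore_index=True),
                              prune=False)
        assert res["condition"].F == 0.0
        assert res["interaction"].F == 0.0

    def test_estimates_increase_with_numerosity(self, experiment):
        means = (experiment["behavior"]
                 .query("condition == 'Baseline'")
                 .groupby("numerosity")["estimate"].mean())
        assert means.is_monotonic_increasing

    def test_matches_statsmodels_on_cell_means(self):
        spec = BehavioralGenSpec(n_participants=8, seed=9)
        table = generate_behavior(spec)
        res = rm_anova_twoway(table, prune=False)
        from statsmodels.stats.anova import AnovaRM
        cells = (table.query("condition in ('Baseline','Neutral') and "
                             "numerosity in (22,26,35,41)")
                 .groupby(["participant", "condition", "numerosity"])
                 ["estimate"].mean().reset_index())
        sm = AnovaRM(cells, depvar="estimate", subject="participant",
                     within=["condition", "numerosity"]).fit().anova_table
        assert res["condition"].F == pytest.approx(
            sm.loc["condition", "F Value"], rel=1e-8)
        assert res["numerosity"].F == pytest.approx(
            sm.loc["numerosity", "F Value"], rel=1e-8)
        assert res["interaction"].F == pytest.approx(
            sm.loc["condition:numerosity", "F Value"], rel=1e-8)

    def test_type_one_error_calibrated_under_null_generator(self):
        """With no adaptation effect, the Condition main effect rejects in
        ~5% of replicate experiments."""
        rejections = 0
        n_reps = 500
        for s in range(n_reps):
            spec = BehavioralGenSpec(n_participants=10, trials_per_condition=4,
                                     underestimation_fraction=0.0, seed=10000 + s)
            table = generate_behavior(spec)
            res = rm_anova_twoway(table, prune=False)
            rejections += res["condition"].p < 0.05
        assert 0.03 <= rejections / n_reps <= 0.07


class TestAdaptationMagnitude:
    def test_percent_arithmetic(self):
        table = make_table(np.array([[30.0, 24.0, 30.0]]))
        mag = adaptation_magnitude(table, prune=False)
        assert mag["percent"].iloc[0] == pytest.approx(20.0)
        assert mag["difference"].iloc[0] == pytest.approx(6.0)

    def test_all_participants_adapt_in_default_scenario(self, experiment):
        mag = adaptation_magnitude(experiment["behavior"])
        assert (mag["difference"] > 0).all()

    def test_null_generator_magnitudes_centered_on_zero(self):
        """Sign test on per-participant magnitudes stays non-significant in
        ~95% of null replicates."""
        significant = 0
        n_reps = 100
        for s in range(n_reps):
            spec = BehavioralGenSpec(underestimation_fraction=0.0,
                                     filling_numerosities=(), seed=20000 + s)
            mag = adaptation_magnitude(generate_behavior(spec))
            k = int((mag["difference"] > 0).sum())
            p = stats.binomtest(k, len(mag), 0.5).pvalue
            significant += p < 0.05
        assert significant / n_reps <= 0.10

    def test_missing_condition_rejected(self):
        table = make_table(np.array([[30.0, 24.0]]),
                           conditions=("Baseline", "Adaptation"))
        with pytest.raises(ValueError, match="Neutral"):
            adaptation_magnitude(table, prune=False)


class TestSampleSize:
    def test_reproduces_a_priori_n(self):
        # f=0.30, alpha=.05, power=.90, 3 measurements, rho=.5 -> n=25
        assert required_sample_size(PowerSpec()) == 25

    def test_monotone_in_effect_size(self):
        for f_small, f_large in [(0.2, 0.4), (0.25, 0.5), (0.3, 0.6)]:
            n_small = required_sample_size(PowerSpec(f=f_large))
            n_large = required_sample_size(PowerSpec(f=f_small))
            assert n_small <= n_large

    def test_matches_grid_search_oracle(self):
        """f=0.25, power=0.80: independent grid search over n evaluating
        the noncentral-F CDF directly."""
        spec = PowerSpec(f=0.25, power=0.80)
        n_oracle = None
        for n in range(2, 200):
            lam = 0.25 ** 2 * n * 3 / 0.5
            crit = stats.f.isf(0.05, 2, (n - 1) * 2)
            if 1 - stats.ncf.cdf(crit, 2, (n - 1) * 2, lam) >= 0.80:
                n_oracle = n
                break
        assert required_sample_size(spec) == n_oracle

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError):
            required_sample_size(PowerSpec(f=0.01), n_max=50)

    def test_power_increases_with_n(self):
        spec = PowerSpec()
        powers = [rm_anova_power(n, spec) for n in range(5, 60, 5)]
        assert all(a < b for a, b in zip(powers, powers[1:]))
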