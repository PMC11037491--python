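"""GLM effect estimation: parameter recovery, directions, correlations."""

import numpy as np
import pandas as pd
import pytest

from dotlattice import (
    AnalysisError,
    ExperimentDesign,
    ObserverParams,
    ResponseTable,
    correlate_effects,
    fit_l1_effect,
    fit_l2_effects,
    predict_experiment,
)

from conftest import ARS


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def synthetic_l1_table(beta0, beta1, n, rng=None):
    """Binomial counts from logit p(r1=0) = beta0 + beta1 * centered logAR."""
    clog = np.log(ARS) - np.mean(np.log(ARS))
    rows = []
    for ar, x in zip(ARS, clog):
        p = _logistic(beta0 + beta1 * x)
        k = rng.binomial(n, p) if rng is not None else n * p
        rows.append((ar, 0.0, 0.0, 0.0, k))
        rows.append((ar, 0.0, 90.0, 0.0, n - k))
    df = pd.DataFrame(rows, columns=["ar", "phi", "r1", "r2", "count"])
    return ResponseTable(df, n, "sampled" if rng is not None else "expected")


def synthetic_l2_table(beta0, beta_ar, beta_r1, n, rng):
    """Counts from logit p(r2=0) = beta0 + beta_ar * clogAR + beta_r1 * contrast."""
    clog = np.log(ARS) - np.mean(np.log(ARS))
    rows = []
    for ar, x in zip(ARS, clog):
        for r1, c in ((0.0, 0.5), (90.0, -0.5)):
            p = _logistic(beta0 + beta_ar * x + beta_r1 * c)
            k = int(rng.binomial(n, p))
            rows.append((ar, 0.0, r1, 0.0, k))
            rows.append((ar, 0.0, r1, 60.0, n - k))
    df = pd.DataFrame(rows, columns=["ar", "phi", "r1", "r2", "count"])
    return ResponseTable(df, 2 * n, "sampled")


class TestL1Fit:
    def test_recovers_known_slope(self):
        rng = np.random.default_rng(0)
        slope, se, sep = fit_l1_effect(synthetic_l1_table(0.3, -2.0, 100_000, rng))
        assert not sep
        assert abs(slope - (-2.0)) < 3 * se

    def test_null_slope_recovered(self):
        rng = np.random.default_rng(1)
        slope, se, _ = fit_l1_effect(synthetic_l1_table(0.0, 0.0, 100_000, rng))
        assert abs(slope) < 3 * se

    def test_baseline_proximity_negative(self, baseline, design):
        table = predict_experiment(baseline, design)
        slope, _, _ = fit_l1_effect(table)
        assert slope < 0

    def test_needs_two_ar_levels(self, baseline):
        table = predict_experiment(baseline, ExperimentDesign(aspect_ratios=(1.0,)))
        with pytest.raises(AnalysisError):
            fit_l1_effect(table)

    def test_scale_invariance_of_expected_estimates(self, baseline):
        t1 = predict_experiment(baseline, ExperimentDesign(n_per_condition=100))
        t2 = predict_experiment(baseline, ExperimentDesign(n_per_condition=200))
        s1, _, _ = fit_l1_effect(t1)
        s2, _, _ = fit_l1_effect(t2)
        assert abs(s1 - s2) < 1e-6


class TestL2Fit:
    def test_recovers_both_coefficients(self):
        rng = np.random.default_rng(2)
        table = synthetic_l2_table(-0.5, 1.2, 2.0, 100_000, rng)
        fit = fit_l2_effects(table)
        assert abs(fit["adaptation"] - 1.2) < 3 * fit["adaptation_se"]
        assert abs(fit["hysteresis"] - 2.0) < 3 * fit["hysteresis_se"]

    def test_baseline_directions(self, baseline, design):
        fit = fit_l2_effects(predict_experiment(baseline, design))
        assert fit["adaptation"] > 0
        assert fit["hysteresis"] > 0

    def test_stimulus_prior_variant_no_hysteresis(self, design):
        params = ObserverParams(variant="stimulus_prior", w_percL1=0.0)
        table = predict_experiment(params, design)
        # the table itself is exactly r1-symmetric ...
        d = table.data
        k = d[d.r2 == 0.0].pivot(index="ar", columns="r1", values="count")
        n = d.groupby(["ar", "r1"])["count"].sum().unstack()
        assert (k[0.0] / n[0.0] - k[90.0] / n[90.0]).abs().max() < 1e-12
        # ... so the fitted contrast is zero within estimation precision
        fit = fit_l2_effects(table)
        assert abs(fit["hysteresis"]) < 3 * fit["hysteresis_se"]
        assert abs(fit["hysteresis"]) < 1e-3

    def test_missing_r1_level_rejected(self, baseline, design):
        table = predict_experiment(baseline, design)
        broken = ResponseTable(
            table.data[table.data.r1 == 0.0].copy(), table.n_per_condition, "expected"
        )
        with pytest.raises(AnalysisError):
            fit_l2_effects(broken)


class TestCorrelations:
    def _frame(self, prox, adapt, hyst):
        n = len(prox)
        return pd.DataFrame(
            {
                "id": np.arange(n),
                "proximity": prox, "adaptation": adapt, "hysteresis": hyst,
                "proximity_se": 0.1, "adaptation_se": 0.1, "hysteresis_se": 0.1,
                "separated": False,
            }
        )

    def test_identical_vectors_give_r_one(self):
        x = np.linspace(0, 1, 20)
        rep = correlate_effects(self._frame(x, x, x), n_boot=100, seed=0)
        assert rep.r("hysteresis", "adaptation") == pytest.approx(1.0)

    def test_shuffled_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=75)
        y = rng.permutation(rng.normal(size=75))
        z = rng.normal(size=75)
        rep = correlate_effects(self._frame(x, y, z), n_boot=100, seed=0)
        assert abs(rep.r("hysteresis", "adaptation")) < 0.3

    def test_zero_variance_rejected(self):
        x = np.linspace(0, 1, 10)
        with pytest.raises(AnalysisError):
            correlate_effects(self._frame(np.zeros(10), x, x), n_boot=10, seed=0)

    def test_too_few_individuals_rejected(self):
        x = np.array([0.0, 1.0])
        with pytest.raises(AnalysisError):
            correlate_effects(self._frame(x, x, x))

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 0.8 * x + 0.3 * rng.normal(size=50)
        z = rng.normal(size=50)
        rep = correlate_effects(self._frame(z, y, x), n_boot=500, seed=1)
        lo, hi = rep.ci("hysteresis", "adaptation")
        assert lo <= rep.r("hysteresis", "adaptation") <= hi
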