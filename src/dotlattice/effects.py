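"""Per-individual context-effect estimation and cross-individual correlation.

Three effects summarize an observer's response table:

* ``proximity``: slope of the first-lattice 0-deg response on centered
  log aspect ratio (binomial GLM, logit link); negative at baseline — the
  larger the AR, the less often the 0-deg axis wins.
* ``adaptation``: slope of the second-lattice 0-deg response on centered
  log AR; positive at baseline — repulsion away from the previously
  supported orientation.
* ``hysteresis``: coefficient of the first-lattice-percept contrast
  (+0.5 for r1 = 0 deg, -0.5 for r1 = 90 deg) in the same model; positive
  at baseline — attraction toward the previous percept.

Estimation is per-individual maximum likelihood on (possibly fractional)
counts, with a small ridge fallback under complete separation.  Population
structure is summarized by Pearson correlations among the three effects
with nonparametric bootstrap confidence intervals over individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import AnalysisError
from .experiment import ResponseTable

_SEPARATION_NORM = 1e3
_RIDGE_ALPHA = 1e-6


@dataclass(frozen=True)
class FitResult:
    coef: np.ndarray
    se: np.ndarray
    separated: bool


def _centered_log_ar(ar: np.ndarray, levels: np.ndarray) -> np.ndarray:
    return np.log(ar) - np.log(levels).mean()


def _fit_binomial(endog: np.ndarray, exog: np.ndarray) -> FitResult:
    """Binomial GLM on (successes, failures) with a ridge fallback that is
    engaged (and flagged) under complete separation."""
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(tol=1e-12, maxiter=200)
        if np.all(np.isfinite(res.params)) and np.linalg.norm(res.params) < _SEPARATION_NORM:
            return FitResult(np.asarray(res.params), np.asarray(res.bse), False)
    except Exception:
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(alpha=_RIDGE_ALPHA, L1_wt=0.0)
    coef = np.asarray(res.params)
    return FitResult(coef, np.full_like(coef, np.nan), True)


def fit_l1_effect(table: ResponseTable) -> tuple[float, float, bool]:
    """Proximity slope (+ SE, separation flag) from the first-lattice
    marginal counts: logit p(r1 = 0) ~ centered log AR."""
    counts = table.l1_counts()
    levels = np.sort(counts.ar.unique())
    if levels.size < 2:
        raise AnalysisError("proximity fit needs at least two aspect-ratio levels")
    k = counts[counts.r1 == 0.0].set_index(["ar", "phi"])["count"]
    n = counts.groupby(["ar", "phi"])["count"].sum()
    cells = pd.concat([k.rename("k"), n.rename("n")], axis=1).reset_index()
    exog = sm.add_constant(_centered_log_ar(cells.ar.to_numpy(), levels))
    endog = np.column_stack([cells.k, cells.n - cells.k])
    fit = _fit_binomial(endog, exog)
    return float(fit.coef[1]), float(fit.se[1]), fit.separated


def fit_l2_effects(table: ResponseTable) -> dict[str, float | bool]:
    """Adaptation slope and hysteresis contrast (+ SEs) from the
    second-lattice responses: logit p(r2 = 0) ~ centered log AR + r1
    contrast (+0.5 when r1 = 0 deg, -0.5 when r1 = 90 deg)."""
    d = table.data
    if set(d.r1.unique()) != {0.0, 90.0}:
        raise AnalysisError("adaptation/hysteresis fit needs both r1 conditions")
    levels = np.sort(d.ar.unique())
    k = d[d.r2 == 0.0].set_index(["ar", "phi", "r1"])["count"]
    n = d.groupby(["ar", "phi", "r1"])["count"].sum()
    cells = pd.concat([k.rename("k"), n.rename("n")], axis=1).reset_index()
    cells = cells[cells.n > 0]
    exog = sm.add_constant(
        np.column_stack(
            [
                _centered_log_ar(cells.ar.to_numpy(), levels),
                np.where(cells.r1.to_numpy() == 0.0, 0.5, -0.5),
            ]
        )
    )
    endog = np.column_stack([cells.k, cells.n - cells.k])
    fit = _fit_binomial(endog, exog)
    return {
        "adaptation": float(fit.coef[1]),
        "adaptation_se": float(fit.se[1]),
        "hysteresis": float(fit.coef[2]),
        "hysteresis_se": float(fit.se[2]),
        "separated": fit.separated,
    }


def estimate_effects(tables: dict[int, ResponseTable]) -> pd.DataFrame:
    """Per-individual effect estimates: one row per response table."""
    rows = []
    for ind_id, table in tables.items():
        prox, prox_se, sep1 = fit_l1_effect(table)
        l2 = fit_l2_effects(table)
        rows.append(
            {
                "id": ind_id,
                "proximity": prox,
                "proximity_se": prox_se,
                "adaptation": l2["adaptation"],
                "adaptation_se": l2["adaptation_se"],
                "hysteresis": l2["hysteresis"],
                "hysteresis_se": l2["hysteresis_se"],
                "separated": bool(sep1 or l2["separated"]),
            }
        )
    return pd.DataFrame(rows)


EFFECT_PAIRS = (
    ("hysteresis", "adaptation"),
    ("adaptation", "proximity"),
    ("hysteresis", "proximity"),
)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations among the three effects with
    bootstrap confidence intervals (resampling individuals)."""

    table: pd.DataFrame  # columns: effect_a, effect_b, r, ci_low, ci_high
    n_individuals: int
    n_boot: int
    ci_level: float

    def r(self, a: str, b: str) -> float:
        row = self.table[(self.table.effect_a == a) & (self.table.effect_b == b)]
        if row.empty:
            row = self.table[(self.table.effect_a == b) & (self.table.effect_b == a)]
        return float(row.r.iloc[0])

    def ci(self, a: str, b: str) -> tuple[float, float]:
        row = self.table[(self.table.effect_a == a) & (self.table.effect_b == b)]
        if row.empty:
            row = self.table[(self.table.effect_a == b) & (self.table.effect_b == a)]
        return float(row.ci_low.iloc[0]), float(row.ci_high.iloc[0])

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "correlations": self.table.to_dict(orient="records"),
        }


def correlate_effects(
    estimates: pd.DataFrame,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CorrelationReport:
    """Pearson correlations among proximity, adaptation and hysteresis
    with percentile bootstrap CIs over individuals."""
    if len(estimates) < 3:
        raise AnalysisError("correlation needs at least three individuals")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(estimates)
    rows = []
    for a, b in EFFECT_PAIRS:
        x = estimates[a].to_numpy()
        y = estimates[b].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            raise AnalysisError(f"correlation undefined: zero variance in {a} or {b}")
        r = float(stats.pearsonr(x, y).statistic)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            xs, ys = x[idx], y[idx]
            if np.std(xs) == 0 or np.std(ys) == 0:
                boots[i] = np.nan
            else:
                boots[i] = np.corrcoef(xs, ys)[0, 1]
        alpha = (1.0 - ci_level) / 2.0
        lo, hi = np.nanquantile(boots, [alpha, 1.0 - alpha])
        rows.append((a, b, r, float(lo), float(hi)))
    table = pd.DataFrame(
        rows, columns=["effect_a", "effect_b", "r", "ci_low", "ci_high"]
    )
    return CorrelationReport(table, n, n_boot, ci_level)
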