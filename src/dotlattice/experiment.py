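"""Experimental-design enumeration and response-table simulation.

The behavioral task crosses seven aspect ratios (symmetric around 1 on the
log scale) with absolute lattice orientations, records the perceived
orientation of the rectangular lattice (r1: 0/90) and of the hexagonal
lattice (r2: 0/60/120).  Two simulation modes are provided:

``expected``
    deterministic expected response frequencies
    ``n * p(r1) * p(r2 | r1)`` per design cell;
``sampled``
    seeded multinomial draws over the joint (r1, r2) outcome, the
    stochastic counterpart used to exercise the analysis pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .observer import (
    L1_ORIENTATIONS,
    L2_ORIENTATIONS,
    ObserverParams,
    OrientationGrid,
    predict_trial,
)

#: the seven aspect-ratio levels of the behavioral paradigm
DEFAULT_ASPECT_RATIOS = (1 / 1.3, 1 / 1.2, 1 / 1.1, 1.0, 1.1, 1.2, 1.3)


@dataclass(frozen=True)
class ExperimentDesign:
    """Aspect-ratio levels, absolute orientations, and trials per cell."""

    aspect_ratios: tuple[float, ...] = DEFAULT_ASPECT_RATIOS
    orientations: tuple[float, ...] | None = None
    n_per_condition: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.aspect_ratios) == 0 or any(a <= 0 for a in self.aspect_ratios):
            raise ConfigurationError("aspect ratios must be positive and nonempty")
        if self.n_per_condition < 1:
            raise ConfigurationError("n_per_condition must be >= 1")

    def phis_for(self, params: ObserverParams) -> tuple[float, ...]:
        """Absolute orientations to enumerate.  Defaults to the single
        representative ``phi = 0`` under the rotation-invariant uniform
        prior, and to the full one-degree sweep under the natural prior."""
        if self.orientations is not None:
            return self.orientations
        if params.prior_kind == "natural":
            return tuple(np.arange(0.0, 180.0, 1.0))
        return (0.0,)


@dataclass
class ResponseTable:
    """Joint response counts keyed by (AR, phi, r1, r2).

    ``data`` columns: ``ar``, ``phi``, ``r1``, ``r2``, ``count``.  In
    expected mode counts are real-valued expected frequencies; in sampled
    mode they are integer draws.  Per-(ar, phi) counts sum to
    ``n_per_condition``.
    """

    data: pd.DataFrame
    n_per_condition: int
    mode: str  # "expected" | "sampled"
    params: ObserverParams | None = field(default=None, repr=False)

    def l1_counts(self) -> pd.DataFrame:
        """Marginal first-lattice counts: columns ar, phi, r1, count."""
        return (
            self.data.groupby(["ar", "phi", "r1"], as_index=False)["count"].sum()
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _cell_probs(params: ObserverParams, ar: float, phi: float, grid: OrientationGrid):
    pred = predict_trial(params, ar, phi, grid)
    joint = {}
    for i, r1 in enumerate(L1_ORIENTATIONS):
        for j, r2 in enumerate(L2_ORIENTATIONS):
            joint[(r1, r2)] = float(pred.p_l1[i] * pred.p_l2[r1][j])
    return joint


def predict_experiment(
    params: ObserverParams,
    design: ExperimentDesign,
    grid: OrientationGrid | None = None,
) -> ResponseTable:
    """Expected response frequencies for every design cell."""
    grid = grid or OrientationGrid()
    rows = []
    n = design.n_per_condition
    for ar in design.aspect_ratios:
        for phi in design.phis_for(params):
            for (r1, r2), p in _cell_probs(params, ar, phi, grid).items():
                rows.append((ar, phi, r1, r2, n * p))
    data = pd.DataFrame(rows, columns=["ar", "phi", "r1", "r2", "count"])
    return ResponseTable(data, n, "expected", params)


def sample_experiment(
    params: ObserverParams,
    design: ExperimentDesign,
    grid: OrientationGrid | None = None,
    rng: np.random.Generator | None = None,
) -> ResponseTable:
    """Multinomial response draws for every design cell (seeded)."""
    if rng is None:
        if design.seed is None:
            raise ConfigurationError(
                "sampled mode needs design.seed (or an explicit rng) for "
                "reproducibility"
            )
        rng = np.random.default_rng(design.seed)
    grid = grid or OrientationGrid()
    rows = []
    n = design.n_per_condition
    for ar in design.aspect_ratios:
        for phi in design.phis_for(params):
            joint = _cell_probs(params, ar, phi, grid)
            keys = list(joint)
            counts = rng.multinomial(n, [joint[k] for k in keys])
            for (r1, r2), k in zip(keys, counts):
                rows.append((ar, phi, r1, r2, int(k)))
    data = pd.DataFrame(rows, columns=["ar", "phi", "r1", "r2", "count"])
    return ResponseTable(data, n, "sampled", params)


def empirical_logit(k, n):
    """``log((k + 0.5) / (n - k + 0.5))``, the finite-sample logit."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return np.log((k + 0.5) / (n - k + 0.5))


def summarize_logit(table: ResponseTable) -> dict[str, pd.DataFrame]:
    """Logit response curves averaged over absolute orientation.

    Returns ``{"l1": ..., "l2": ...}``: per-AR logit of p(0 deg | L1), and
    per-(AR, r1) mean logit of p(0 deg | L2).  Expected mode uses the exact
    ``logit(p)``; sampled mode uses the empirical logit with the +0.5
    continuity correction.
    """
    if table.data.empty:
        raise ConfigurationError("cannot summarize an empty response table")

    def cell_logit(k, n):
        if n == 0:
            return np.nan
        if table.mode == "expected":
            p = k / n
            if p <= 0 or p >= 1:
                return empirical_logit(k, n)
            return float(np.log(p / (1 - p)))
        return float(empirical_logit(k, n))

    l1 = table.l1_counts()
    l1["n"] = l1.groupby(["ar", "phi"])["count"].transform("sum")
    l1 = l1[l1.r1 == 0.0].rename(columns={"count": "k"})
    l1["logit_p0"] = [cell_logit(r.k, r.n) for r in l1.itertuples()]
    l1_out = l1.groupby("ar", as_index=False)["logit_p0"].mean()

    d = table.data
    totals = d.groupby(["ar", "phi", "r1"])["count"].sum().rename("n")
    zeros = d[d.r2 == 0.0].set_index(["ar", "phi", "r1"])["count"].rename("k")
    cells = pd.concat([zeros, totals], axis=1).reset_index()
    empty = cells[cells.n == 0]
    if not empty.empty:
        warnings.warn(f"dropping {len(empty)} empty (ar, phi, r1) cells", stacklevel=2)
        cells = cells[cells.n > 0]
    cells["logit_p0"] = [cell_logit(r.k, r.n) for r in cells.itertuples()]
    l2_out = (
        cells.groupby(["ar", "r1"], as_index=False)["logit_p0"].mean()
    )
    return {"l1": l1_out, "l2": l2_out}
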