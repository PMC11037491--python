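"""Simulated individual differences in context-effect parameters.

Individuals differ in three parameters: the aspect-ratio sensitivity
``c_stim`` and the two temporal-integration weights ``w_stimL1`` (stimulus
level) and ``w_percL1`` (percept level).  The triples are drawn from a
truncated multivariate normal on a raw 0-10 scale for the weights (means
5, 6.5 and 5; the two raw weights strongly positively correlated, which is
the mechanism that propagates into a positive correlation between
individuals' repulsive and attractive context effects), then the weights
are rescaled by 10 into [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .experiment import ExperimentDesign, ResponseTable, predict_experiment, sample_experiment
from .observer import ObserverParams

#: raw-scale covariance of (c_stim, w_stimL1_raw, w_percL1_raw): sd 5 for
#: c_stim, sd 3 for each raw weight, covariance 8.95 between the weights
#: (correlation ~0.994), weights independent of c_stim.
DEFAULT_COVARIANCE = np.array(
    [
        [25.0, 0.0, 0.0],
        [0.0, 9.0, 8.95],
        [0.0, 8.95, 9.0],
    ]
)


@dataclass(frozen=True)
class PopulationSpec:
    """Truncated multivariate normal over (c_stim, w_stimL1_raw, w_percL1_raw)."""

    n_individuals: int = 75
    means: tuple[float, float, float] = (5.0, 6.5, 5.0)
    covariance: np.ndarray = field(default_factory=lambda: DEFAULT_COVARIANCE.copy())
    lower: tuple[float, float, float] = (0.0, 0.0, 0.0)
    upper: tuple[float, float, float] = (np.inf, 10.0, 10.0)
    weight_rescale: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "covariance", cov)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise InvalidParameterError("covariance must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise InvalidParameterError("covariance must be positive definite")
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")
        if self.weight_rescale <= 0:
            raise InvalidParameterError("weight_rescale must be > 0")


@dataclass(frozen=True)
class IndividualParams:
    """One simulated observer: id plus its full parameter set."""

    id: int
    params: ObserverParams


def truncated_mvn(
    n: int,
    mean: np.ndarray,
    cov: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
    min_acceptance: float = 1e-4,
) -> np.ndarray:
    """Draw ``n`` samples from a box-truncated multivariate normal by
    rejection from the unconstrained normal (exact, and efficient for the
    high-acceptance default specification)."""
    out = np.empty((0, mean.size))
    proposed = accepted = 0
    batch = max(4 * n, 256)
    while out.shape[0] < n:
        cand = rng.multivariate_normal(mean, cov, size=batch)
        keep = np.all((cand > lower) & (cand < upper), axis=1)
        proposed += batch
        accepted += int(keep.sum())
        out = np.vstack([out, cand[keep]])
        if proposed >= 1e6 and accepted / proposed < min_acceptance:
            raise InvalidParameterError(
                "truncated-normal acceptance rate below 1e-4; check that the "
                "bounds and covariance are compatible"
            )
    return out[:n]


def draw_individuals(
    spec: PopulationSpec,
    shared: ObserverParams | None = None,
    rng: np.random.Generator | None = None,
) -> list[IndividualParams]:
    """Sample a population of observers.

    ``shared`` supplies every parameter that does not vary across
    individuals (concentrations, prior kind, variant); defaults to the
    baseline observer.
    """
    if rng is None:
        if spec.seed is None:
            raise InvalidParameterError("population sampling needs spec.seed or an rng")
        rng = np.random.default_rng(spec.seed)
    shared = shared or ObserverParams()
    draws = truncated_mvn(
        spec.n_individuals,
        np.asarray(spec.means, dtype=float),
        spec.covariance,
        np.asarray(spec.lower, dtype=float),
        np.asarray(spec.upper, dtype=float),
        rng,
    )
    individuals = []
    for i, (c, w_stim_raw, w_perc_raw) in enumerate(draws):
        params = shared.with_(
            c_stim=float(c),
            w_stimL1=float(w_stim_raw / spec.weight_rescale),
            w_percL1=float(w_perc_raw / spec.weight_rescale),
        )
        individuals.append(IndividualParams(i, params))
    return individuals


def individuals_manifest(individuals: list[IndividualParams]) -> pd.DataFrame:
    """Parameter manifest: one row per individual."""
    return pd.DataFrame(
        {
            "id": [ind.id for ind in individuals],
            "c_stim": [ind.params.c_stim for ind in individuals],
            "w_stimL1": [ind.params.w_stimL1 for ind in individuals],
            "w_percL1": [ind.params.w_percL1 for ind in individuals],
        }
    )


def simulate_population(
    individuals: list[IndividualParams],
    design: ExperimentDesign,
    mode: str = "expected",
    rng: np.random.Generator | None = None,
) -> dict[int, ResponseTable]:
    """Run the experiment once per individual.

    ``expected`` mode is deterministic; ``sampled`` mode draws responses
    with one child generator per individual spawned from ``rng`` (or from
    ``design.seed``).
    """
    if mode not in ("expected", "sampled"):
        raise InvalidParameterError(f"mode must be 'expected' or 'sampled', got {mode!r}")
    tables: dict[int, ResponseTable] = {}
    if mode == "sampled":
        if rng is None:
            if design.seed is None:
                raise InvalidParameterError("sampled mode needs design.seed or an rng")
            rng = np.random.default_rng(design.seed)
        child_rngs = rng.spawn(len(individuals))
    for i, ind in enumerate(individuals):
        if mode == "expected":
            tables[ind.id] = predict_experiment(ind.params, design)
        else:
            tables[ind.id] = sample_experiment(ind.params, design, rng=child_rngs[i])
    return tables
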