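"""Two-stage Bayesian observer for consecutive dot lattices.

A trial shows a rectangular lattice (two dominant orientations, 0/90 deg
relative to the lattice axis, relative dominance set by the aspect ratio
AR = |a|/|b|) followed by a hexagonal lattice (three equally dominant
orientations at 0/60/120 deg) at the same absolute orientation ``phi``.

Stage 1 forms a two-peak likelihood from the expected sensory measurements
of the 0 and 90 deg axes, weighted by ``AR ** c_stim``, and combines it
with the long-term prior.  Between stages, two distinct summaries of the
first lattice are carried forward:

* a *stimulus frequency* distribution (mixture of long-term prior and the
  stage-1 posterior, weight ``w_stimL1``) which re-shapes the efficient
  stimulus-to-sensory mapping for stage 2 and thereby produces repulsion
  from the previously supported orientation (adaptation);
* a *perceptual prior* (mixture of long-term prior and a von Mises bump at
  the stage-1 percept, weight ``w_percL1``) which pulls the stage-2
  posterior toward the previous percept (hysteresis).

Model variants: ``hierarchical`` is the full model; ``stimulus_prior``
reuses the stimulus frequency distribution as the stage-2 prior (no
percept-level information, so no hysteresis); ``no_efficient_coding``
keeps the perceptual prior but fixes the identity mapping for both
lattices (no likelihood repulsion, so no adaptation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .encoding import (
    DensityOnGrid,
    Mapping,
    OrientationGrid,
    cumulative_mapping,
    make_prior,
    measurement_likelihood,
    vm_pdf,
)
from .errors import InvalidConditionError, InvalidParameterError

PriorKind = Literal["uniform", "natural"]
Variant = Literal["hierarchical", "stimulus_prior", "no_efficient_coding"]

L1_ORIENTATIONS = (0.0, 90.0)
L2_ORIENTATIONS = (0.0, 60.0, 120.0)

#: parameter set that reproduces the average attraction/repulsion pattern
BASELINE = dict(
    c_stim=5.0,
    kappa_stimL1=20.0,
    kappa_sensL1=20.0,
    kappa_stimL2=20.0,
    kappa_sensL2=18.0,
    kappa_percL1=10.0,
    w_stimL1=0.60,
    w_percL1=0.50,
)


@dataclass(frozen=True)
class ObserverParams:
    """Free parameters and structural flags of the observer.

    Concentrations are dimensionless axial von Mises precisions; the two
    weights are mixture weights in [0, 1]; ``c_stim`` is the exponent
    turning the aspect ratio into likelihood-peak dominance.
    """

    c_stim: float = BASELINE["c_stim"]
    kappa_stimL1: float = BASELINE["kappa_stimL1"]
    kappa_sensL1: float = BASELINE["kappa_sensL1"]
    kappa_stimL2: float = BASELINE["kappa_stimL2"]
    kappa_sensL2: float = BASELINE["kappa_sensL2"]
    kappa_percL1: float = BASELINE["kappa_percL1"]
    w_stimL1: float = BASELINE["w_stimL1"]
    w_percL1: float = BASELINE["w_percL1"]
    prior_kind: PriorKind = "uniform"
    variant: Variant = "hierarchical"

    def __post_init__(self) -> None:
        if self.c_stim <= 0:
            raise InvalidParameterError(f"c_stim must be > 0, got {self.c_stim}")
        for name in ("kappa_stimL1", "kappa_sensL1", "kappa_stimL2", "kappa_sensL2", "kappa_percL1"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        for name in ("w_stimL1", "w_percL1"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {w}")
        if self.prior_kind not in ("uniform", "natural"):
            raise InvalidParameterError(f"unknown prior_kind {self.prior_kind!r}")
        if self.variant not in ("hierarchical", "stimulus_prior", "no_efficient_coding"):
            raise InvalidParameterError(f"unknown variant {self.variant!r}")
        if self.kappa_sensL2 > self.kappa_sensL1:
            warnings.warn(
                "kappa_sensL2 > kappa_sensL1: the second lattice is presented "
                "more briefly, so its sensory precision is expected to be lower",
                stacklevel=2,
            )

    def with_(self, **changes) -> "ObserverParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class TrialCondition:
    """One trial cell: aspect ratio, absolute orientation, and (for the
    second lattice) the conditioning first-lattice percept ``r1`` in
    {0, 90} deg relative to ``phi``."""

    aspect_ratio: float
    phi: float = 0.0
    r1: float | None = None

    def __post_init__(self) -> None:
        if self.aspect_ratio <= 0:
            raise InvalidConditionError(
                f"aspect ratio must be > 0, got {self.aspect_ratio}"
            )
        if self.r1 is not None and self.r1 not in L1_ORIENTATIONS:
            raise InvalidConditionError(f"r1 must be 0 or 90 deg, got {self.r1}")


@dataclass
class StageDensities:
    prior: DensityOnGrid
    likelihood: DensityOnGrid
    posterior: DensityOnGrid


@dataclass
class TrialPrediction:
    """Response probabilities for one (AR, phi) cell.

    ``p_l1``: probabilities of perceiving relative 0/90 in the first
    lattice.  ``p_l2[r1]``: probabilities of relative 0/60/120 in the
    second lattice given each first-lattice percept.
    """

    condition: TrialCondition
    p_l1: np.ndarray
    p_l2: dict[float, np.ndarray]
    l1_densities: StageDensities | None = None
    l2_densities: dict[float, StageDensities] = field(default_factory=dict)

    @property
    def p0_l1(self) -> float:
        return float(self.p_l1[0])

    def p0_l2(self, r1: float) -> float:
        return float(self.p_l2[r1][0])


def ar_weights(aspect_ratio: float, c_stim: float) -> tuple[float, float]:
    """Mixture weights of the 0- and 90-deg likelihood components.

    ``w_AR = AR ** c_stim`` expresses the 90-deg axis' dominance; the two
    components get weights ``1 / (1 + w_AR)`` and ``w_AR / (1 + w_AR)``.
    """
    w_ar = aspect_ratio**c_stim
    return 1.0 / (1.0 + w_ar), w_ar / (1.0 + w_ar)


def l1_mapping(params: ObserverParams, grid: OrientationGrid) -> Mapping:
    """Stimulus-to-sensory mapping for the first lattice."""
    if params.variant == "no_efficient_coding":
        return Mapping.identity(grid)
    return cumulative_mapping(make_prior(params.prior_kind, grid))


def l1_likelihood(
    cond: TrialCondition, params: ObserverParams, mapping: Mapping
) -> DensityOnGrid:
    """Two-peak likelihood for the rectangular lattice.

    Mixture of the single-measurement likelihoods at the expected sensory
    measurements of ``phi`` and ``phi + 90``; the raw (unnormalized in
    theta) components are mixed so the weights act on densities in
    measurement space, then the mixture is normalized for display.
    """
    grid = mapping.grid
    w0, w90 = ar_weights(cond.aspect_ratio, params.c_stim)
    values = w0 * measurement_likelihood(
        mapping.at(cond.phi), mapping, params.kappa_stimL1, params.kappa_sensL1,
        normalize=False,
    ) + w90 * measurement_likelihood(
        mapping.at(cond.phi + 90.0), mapping, params.kappa_stimL1, params.kappa_sensL1,
        normalize=False,
    )
    return DensityOnGrid.from_values(grid, values)


def l1_posterior(
    cond: TrialCondition,
    params: ObserverParams,
    prior: DensityOnGrid,
    mapping: Mapping,
) -> DensityOnGrid:
    """Pointwise product of prior and two-peak likelihood, renormalized."""
    lik = l1_likelihood(cond, params, mapping)
    return DensityOnGrid.from_values(prior.grid, prior.values * lik.values)


def l1_response_probs(posterior: DensityOnGrid, cond: TrialCondition) -> np.ndarray:
    """Probabilities of perceiving relative 0 vs 90 deg, read as the
    relative posterior density at the two dominant orientations."""
    d = np.array([posterior.at(cond.phi + rel) for rel in L1_ORIENTATIONS])
    return d / d.sum()


def stimulus_frequency(
    prior_l1: DensityOnGrid, posterior_l1: DensityOnGrid, w_stimL1: float
) -> DensityOnGrid:
    """Stimulus frequency distribution carried to the second lattice:
    ``(1 - w) * prior + w * posterior``.  It regenerates the efficient
    mapping for the second lattice (not its prior)."""
    return prior_l1.mix(posterior_l1, w_stimL1)


def perceptual_prior(
    prior_l1: DensityOnGrid,
    r1_abs: float,
    kappa_percL1: float,
    w_percL1: float,
) -> DensityOnGrid:
    """Perceptual prior for the second lattice: long-term prior mixed with
    a von Mises bump at the perceived first-lattice orientation."""
    bump = DensityOnGrid(
        prior_l1.grid, vm_pdf(prior_l1.grid.points, r1_abs, kappa_percL1)
    )
    return prior_l1.mix(bump, w_percL1)


def l2_predict(
    cond: TrialCondition,
    params: ObserverParams,
    prior_l1: DensityOnGrid,
    posterior_l1: DensityOnGrid,
    *,
    keep_densities: bool = False,
) -> tuple[np.ndarray, StageDensities | None]:
    """Response probabilities for the hexagonal lattice given one trial.

    Builds the stage-2 mapping from the stimulus frequency distribution
    (identity under ``no_efficient_coding``), forms the equal-weight
    three-peak likelihood, multiplies by the variant's prior and reads the
    relative posterior density at 0/60/120 deg.
    """
    grid = prior_l1.grid
    if params.variant != "stimulus_prior" and cond.r1 is None:
        raise InvalidConditionError(
            "second-lattice prediction needs the first-lattice percept r1"
        )

    stim_freq = stimulus_frequency(prior_l1, posterior_l1, params.w_stimL1)
    if params.variant == "no_efficient_coding":
        mapping2 = Mapping.identity(grid)
    else:
        mapping2 = cumulative_mapping(stim_freq)

    values = np.zeros(grid.n)
    for rel in L2_ORIENTATIONS:
        values += measurement_likelihood(
            mapping2.at(cond.phi + rel),
            mapping2,
            params.kappa_stimL2,
            params.kappa_sensL2,
            normalize=False,
        ) / len(L2_ORIENTATIONS)
    likelihood = DensityOnGrid.from_values(grid, values)

    if params.variant == "stimulus_prior":
        prior2 = stim_freq
    else:
        prior2 = perceptual_prior(
            prior_l1, cond.phi + cond.r1, params.kappa_percL1, params.w_percL1
        )

    posterior = DensityOnGrid.from_values(grid, prior2.values * likelihood.values)
    d = np.array([posterior.at(cond.phi + rel) for rel in L2_ORIENTATIONS])
    probs = d / d.sum()
    dens = StageDensities(prior2, likelihood, posterior) if keep_densities else None
    return probs, dens


def predict_trial(
    params: ObserverParams,
    aspect_ratio: float,
    phi: float = 0.0,
    grid: OrientationGrid | None = None,
    *,
    keep_densities: bool = False,
) -> TrialPrediction:
    """Full per-trial prediction: first-lattice response probabilities and
    second-lattice probabilities conditioned on each first-lattice percept."""
    grid = grid or OrientationGrid()
    cond = TrialCondition(aspect_ratio, phi)
    prior = make_prior(params.prior_kind, grid)
    mapping = l1_mapping(params, grid)
    post1 = l1_posterior(cond, params, prior, mapping)
    p_l1 = l1_response_probs(post1, cond)

    p_l2: dict[float, np.ndarray] = {}
    l2_dens: dict[float, StageDensities] = {}
    for r1 in L1_ORIENTATIONS:
        c2 = TrialCondition(aspect_ratio, phi, r1)
        probs, dens = l2_predict(
            c2, params, prior, post1, keep_densities=keep_densities
        )
        p_l2[r1] = probs
        if dens is not None:
            l2_dens[r1] = dens

    l1_dens = None
    if keep_densities:
        l1_dens = StageDensities(prior, l1_likelihood(cond, params, mapping), post1)
    return TrialPrediction(cond, p_l1, p_l2, l1_dens, l2_dens)


def predict_trial_averaged(
    params: ObserverParams,
    aspect_ratio: float,
    grid: OrientationGrid | None = None,
    phis: np.ndarray | None = None,
) -> TrialPrediction:
    """Trial prediction averaged over absolute lattice orientations.

    With the uniform prior every quantity is rotation invariant, so a
    single representative ``phi = 0`` suffices.  With the natural prior the
    full sweep over one degree steps is run and probabilities averaged.
    """
    grid = grid or OrientationGrid()
    if phis is None:
        phis = grid.points if params.prior_kind == "natural" else np.array([0.0])
    preds = [predict_trial(params, aspect_ratio, phi, grid) for phi in phis]
    p_l1 = np.mean([p.p_l1 for p in preds], axis=0)
    p_l2 = {
        r1: np.mean([p.p_l2[r1] for p in preds], axis=0) for r1 in L1_ORIENTATIONS
    }
    return TrialPrediction(TrialCondition(aspect_ratio, float(phis[0])), p_l1, p_l2)
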