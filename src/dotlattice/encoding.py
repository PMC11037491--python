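"""Circular orientation math and efficient sensory encoding.

Orientation is an axial quantity: a grating or dot-row oriented at theta
looks identical at theta + 180 deg.  All densities in this package therefore
live on the half-circle [0, 180) deg and are represented by the semicircular
(axial) von Mises family, obtained from the ordinary von Mises by angle
doubling.  Densities are tabulated per *radian* on a uniform grid.

Efficient coding enters through a monotone stimulus-to-sensory mapping:
orientations that occur frequently claim more sensory resolution.  The
mapping is the (rescaled) cumulative distribution of the generating
frequency distribution, so a uniform environment yields the identity and a
peaked environment stretches sensory space around its peaks.  Sensory noise
that is symmetric in sensory space then becomes asymmetric in stimulus
space, which is the source of likelihood repulsion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ive

from .errors import ConfigurationError, InvalidDensityError, InvalidParameterError

DEG_PER_HALF_TURN = 180.0
#: period of axial orientation space, in radians
HALF_TURN_RAD = np.pi

_NORM_TOL = 1e-9


def _deg2rad(x):
    return np.asarray(x, dtype=float) * (np.pi / 180.0)


@dataclass(frozen=True)
class OrientationGrid:
    """Uniform grid on the half-circle [0, 180) degrees.

    Parameters
    ----------
    step : float
        Grid spacing in degrees.  ``180 / step`` must be an integer so the
        grid tiles the half-circle exactly once.
    """

    step: float = 1.0
    points: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ConfigurationError(f"grid step must be positive, got {self.step}")
        n = DEG_PER_HALF_TURN / self.step
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"180 / step must be an integer, got step={self.step}"
            )
        object.__setattr__(
            self, "points", np.arange(int(round(n))) * self.step
        )

    @property
    def n(self) -> int:
        return self.points.size

    @property
    def step_rad(self) -> float:
        return float(self.step * np.pi / 180.0)

    def index_of(self, theta_deg: float) -> int:
        """Index of the grid point at ``theta_deg`` (mod 180), snapping
        to the nearest point with a warning when off-grid."""
        theta = float(theta_deg) % DEG_PER_HALF_TURN
        idx = theta / self.step
        nearest = int(round(idx)) % self.n
        if abs(idx - round(idx)) > 1e-6:
            warnings.warn(
                f"orientation {theta_deg} deg is not on the {self.step} deg grid; "
                f"snapping to {self.points[nearest]} deg",
                stacklevel=2,
            )
        return nearest


@dataclass(frozen=True)
class DensityOnGrid:
    """A probability density (per radian) tabulated on an orientation grid.

    The Riemann sum ``values.sum() * grid.step_rad`` must equal 1; use
    :meth:`from_values` to normalize raw nonnegative weights.
    """

    grid: OrientationGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != self.grid.points.shape:
            raise InvalidDensityError(
                f"density has {vals.shape} values for a {self.grid.n}-point grid"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise InvalidDensityError("density values must be finite and >= 0")
        total = vals.sum() * self.grid.step_rad
        if abs(total - 1.0) > _NORM_TOL:
            raise InvalidDensityError(
                f"density integrates to {total!r}, expected 1 within {_NORM_TOL}"
            )

    @classmethod
    def from_values(cls, grid: OrientationGrid, values: np.ndarray) -> "DensityOnGrid":
        """Normalize nonnegative weights into a density on ``grid``."""
        vals = np.asarray(values, dtype=float)
        total = vals.sum() * grid.step_rad
        if total <= 0 or not np.isfinite(total):
            raise InvalidDensityError("cannot normalize: total mass is not positive")
        return cls(grid, vals / total)

    def at(self, theta_deg: float) -> float:
        """Density value at the grid point nearest ``theta_deg``."""
        return float(self.values[self.grid.index_of(theta_deg)])

    def mix(self, other: "DensityOnGrid", w_other: float) -> "DensityOnGrid":
        """Convex mixture ``(1 - w) * self + w * other``, renormalized."""
        if not 0.0 <= w_other <= 1.0:
            raise InvalidParameterError(f"mixture weight must be in [0, 1], got {w_other}")
        if other.grid != self.grid:
            raise InvalidDensityError("mixture components live on different grids")
        return DensityOnGrid.from_values(
            self.grid, (1.0 - w_other) * self.values + w_other * other.values
        )


def vm_pdf(theta_deg, mu_deg, kappa: float) -> np.ndarray | float:
    """Semicircular (axial) von Mises density, per radian.

    The density of an axial orientation ``theta`` around mean ``mu`` with
    concentration ``kappa`` is ``exp(kappa * cos(2 * (theta - mu))) /
    (pi * I0(kappa))``: a standard von Mises on the doubled angle, folded
    to period 180 deg.  ``kappa = 0`` gives the uniform density ``1 / pi``.
    """
    if kappa < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {kappa}")
    delta = _deg2rad(np.asarray(theta_deg, dtype=float) - np.asarray(mu_deg, dtype=float))
    # exp(k cos 2d) / I0(k) == exp(k (cos 2d - 1)) / ive(k); stable for large k
    out = np.exp(kappa * (np.cos(2.0 * delta) - 1.0)) / (np.pi * ive(0, kappa))
    if np.isscalar(theta_deg) and np.isscalar(mu_deg):
        return float(out)
    return out


def make_prior(kind: str, grid: OrientationGrid) -> DensityOnGrid:
    """Long-term orientation prior on ``grid``.

    ``uniform``
        Constant ``1 / pi`` per radian: every absolute orientation equally
        frequent, as in the dot-lattice experiment itself.
    ``natural``
        Proportional to ``2 - |sin(2 theta)|``, peaked at the cardinal
        orientations (0 and 90 deg) as in natural scenes; the analytic
        normalization constant is ``1 / (2 pi - 2)``.
    """
    theta = _deg2rad(grid.points)
    if kind == "uniform":
        return DensityOnGrid(grid, np.full(grid.n, 1.0 / np.pi))
    if kind == "natural":
        # renormalized on the grid; the analytic constant is 1 / (2 pi - 2)
        return DensityOnGrid.from_values(grid, 2.0 - np.abs(np.sin(2.0 * theta)))
    raise ConfigurationError(f"unknown prior kind {kind!r}; use 'uniform' or 'natural'")


@dataclass(frozen=True)
class Mapping:
    """Monotone stimulus-to-sensory transformation on a grid.

    ``image[i]`` is the sensory coordinate of stimulus orientation
    ``grid.points[i]``, defined as ``180 * CDF(theta)`` of the generating
    frequency distribution.  Sensory space is thereby rescaled to one full
    half-turn, so sensory concentrations are directly comparable to
    stimulus concentrations, and a uniform environment gives the identity.
    """

    grid: OrientationGrid
    image: np.ndarray

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        object.__setattr__(self, "image", img)
        if img.shape != self.grid.points.shape:
            raise InvalidDensityError("mapping image does not match its grid")
        if np.any(np.diff(img) < -1e-12):
            raise InvalidDensityError("mapping must be monotone nondecreasing")

    @classmethod
    def identity(cls, grid: OrientationGrid) -> "Mapping":
        return cls(grid, grid.points.copy())

    def at(self, theta_deg: float) -> float:
        """Sensory coordinate of the grid point nearest ``theta_deg``."""
        return float(self.image[self.grid.index_of(theta_deg)])


def cumulative_mapping(freq: DensityOnGrid) -> Mapping:
    """Efficient-coding mapping induced by a frequency distribution.

    The sensory coordinate of stimulus orientation ``theta`` is
    ``180 * CDF(theta)``: cumulative mass below ``theta``, rescaled to the
    half-turn.  Where the frequency distribution is dense the mapping is
    steep, i.e. sensory resolution is fine.
    """
    # trapezoidal cumulative mass: exact for the uniform density, and
    # second-order accurate against the analytic CDF elsewhere
    vals = freq.values
    cell = 0.5 * (vals + np.roll(vals, -1)) * freq.grid.step_rad
    cdf = np.concatenate(([0.0], np.cumsum(cell)[:-1]))
    return Mapping(freq.grid, DEG_PER_HALF_TURN * cdf)


def measurement_likelihood(
    m: float,
    mapping: Mapping,
    kappa_stim: float,
    kappa_sens: float,
    *,
    normalize: bool = True,
) -> DensityOnGrid | np.ndarray:
    """Likelihood over stimulus orientation of one sensory measurement.

    The measurement model is ``m = F(theta + d_stim) + d_sens`` with
    stimulus noise ``d_stim`` (axial von Mises, concentration
    ``kappa_stim``, symmetric in stimulus space) and sensory noise
    ``d_sens`` (axial von Mises, concentration ``kappa_sens``, symmetric
    in the rescaled sensory space).  For each hypothesized ``theta`` the
    likelihood is the grid quadrature of

        p(m | theta) = int vm(m - F(t); k_sens) vm(t - theta; k_stim) dt.

    With the identity mapping this is an even function of ``theta - m``;
    with a non-uniform mapping the sensory noise folds back asymmetrically
    in stimulus space and the likelihood leans away from high-frequency
    orientations.

    Returns a normalized :class:`DensityOnGrid` (default), or the raw
    quadrature values (a density in ``m``, not in ``theta``) when
    ``normalize=False`` — the raw values are what enter the multi-peak
    lattice likelihood mixtures.
    """
    if kappa_stim < 0 or kappa_sens < 0:
        raise InvalidParameterError("noise concentrations must be >= 0")
    grid = mapping.grid
    if grid.n == 0:
        raise ConfigurationError("empty orientation grid")
    sens = vm_pdf(float(m), mapping.image, kappa_sens)
    values = _axial_correlate(sens, kappa_stim, grid)
    if normalize:
        return DensityOnGrid.from_values(grid, values)
    return values


def _axial_correlate(weights: np.ndarray, kappa_stim: float, grid: OrientationGrid) -> np.ndarray:
    """Quadrature of ``sum_t weights[t] * vm(t - theta; kappa_stim) * dt``
    for every grid ``theta``, via FFT on the circulant kernel."""
    kernel = vm_pdf(grid.points, 0.0, kappa_stim)  # vm(t - theta) = kernel[t - theta]
    # correlation: out[theta] = sum_t weights[t] kernel[(t - theta) mod n]
    out = np.fft.irfft(
        np.fft.rfft(weights) * np.conj(np.fft.rfft(kernel)), n=grid.n
    )
    return np.maximum(out, 0.0) * grid.step_rad


def density_to_frame(density: DensityOnGrid):
    """Export a density as a two-column table (theta_deg, density)."""
    import pandas as pd

    return pd.DataFrame(
        {"theta_deg": density.grid.points, "density": density.values}
    )
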