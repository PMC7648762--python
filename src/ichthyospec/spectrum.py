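"""Forward size-spectrum trophic transfer model.

The model propagates a Gaussian size distribution of primary production up a
five-level food web.  Each transfer multiplies total production by the trophic
transfer efficiency ``alpha`` and redistributes it across body sizes according
to a Gaussian predator-prey size-ratio kernel (preferred prey size is the
fraction ``phi`` of the predator's size; ``sigma`` is the spread of the diet
around that preference, measured in log10 body size by default).  Production at
the top of the web is mapped onto a fossil tooth-length axis through a power-law
(allometric) tooth-to-body-size relationship, giving a predicted tooth-size
productivity density directly comparable to kernel-smoothed ichthyolith data.

Discretisation note: diet proportions (rows of :class:`DietMatrix`) are
normalised over prey bins, so every predator's diet sums to one.  Propagation
uses the complementary *flow* matrix, in which each prey bin's production is
partitioned across its predators; that matrix is column-stochastic, which makes
``alpha`` the sole control of between-level mass transfer and keeps level
totals exactly on the ``alpha**(l-1)`` law on any grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .axes import SizeGrid, ToothAxis, rebin_mass

__all__ = [
    "AllometricModel",
    "TrophicParams",
    "DietMatrix",
    "TrophicSolution",
    "PredictedToothDensity",
    "tooth_to_body",
    "body_to_tooth",
    "make_diet_matrix",
    "primary_production_distribution",
    "propagate",
    "predict_tooth_density",
    "DEFAULT_PP_TOTAL",
    "DEFAULT_LEVELS",
]

#: Total primary production in relative units per Myr.  With a trophic
#: efficiency near 0.1, four transfers leave total top-level production of
#: order one, matching the convention that the reference solution has total
#: productivity of one unit per Myr.
DEFAULT_PP_TOTAL = 1.0e4

#: Trophic levels whose production is compared with the tooth record.  Levels
#: 1-2 (phytoplankton and primary consumers) are toothless; using the single
#: top level keeps the predicted shape exactly invariant under changes of
#: alpha or total primary production (see docs/methods.md).
DEFAULT_LEVELS: tuple[int, ...] = (5,)

N_LEVELS = 5


@dataclass(frozen=True)
class AllometricModel:
    """Power-law tooth-to-body scaling ``body = a * tooth**b``.

    Tooth lengths enter as the dimensionless ratio (length / 1 um); the result
    is body size in the model's grid units (metres).  ``a`` and ``b`` are
    community-average effective parameters calibrated from the record rather
    than a species-level allometry.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"allometric coefficient a must be > 0, got {self.a}")
        if not (self.b > 0):
            raise ValueError(f"allometric exponent b must be > 0, got {self.b}")


@dataclass(frozen=True)
class TrophicParams:
    """The seven-parameter vector driving the forward model.

    alpha
        Trophic transfer efficiency (fraction of production passed up one
        level), 0 < alpha < 1.
    phi
        Preferred prey size as a fraction of predator size, 0 < phi < 1.
    sigma
        Spread of the diet kernel around the preferred prey size (log10 body
        size units under the default kernel space).
    p_mu, p_sigma
        Mean and standard deviation (micrometres) of the Gaussian primary
        production size distribution.
    allometry
        The tooth-to-body scaling (a, b).
    """

    alpha: float
    phi: float
    sigma: float
    p_mu: float
    p_sigma: float
    allometry: AllometricModel

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 < self.phi < 1):
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.p_mu > 0):
            raise ValueError(f"p_mu must be > 0, got {self.p_mu}")
        if not (self.p_sigma > 0):
            raise ValueError(f"p_sigma must be > 0, got {self.p_sigma}")

    @property
    def a(self) -> float:
        return self.allometry.a

    @property
    def b(self) -> float:
        return self.allometry.b

    def replace(self, **kwargs) -> "TrophicParams":
        """Return a copy with selected fields replaced.

        ``a`` and ``b`` may be passed directly and are routed into the nested
        allometric model.
        """
        allo = kwargs.pop("allometry", self.allometry)
        a = kwargs.pop("a", allo.a)
        b = kwargs.pop("b", allo.b)
        return replace(self, allometry=AllometricModel(a, b), **kwargs)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "alpha": self.alpha,
            "sigma": self.sigma,
            "phi": self.phi,
            "p_mu": self.p_mu,
            "p_sigma": self.p_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrophicParams":
        return cls(
            alpha=d["alpha"],
            phi=d["phi"],
            sigma=d["sigma"],
            p_mu=d["p_mu"],
            p_sigma=d["p_sigma"],
            allometry=AllometricModel(d["a"], d["b"]),
        )


def tooth_to_body(tooth_length: np.ndarray | float, allometry: AllometricModel) -> np.ndarray | float:
    """Map tooth length (um) to body size via ``a * x**b``; strictly increasing."""
    x = np.asarray(tooth_length, dtype=float)
    if np.any(x <= 0):
        raise ValueError("tooth_length must be strictly positive")
    out = allometry.a * x**allometry.b
    return float(out) if np.isscalar(tooth_length) else out


def body_to_tooth(body_size: np.ndarray | float, allometry: AllometricModel) -> np.ndarray | float:
    """Exact inverse of :func:`tooth_to_body`."""
    y = np.asarray(body_size, dtype=float)
    if np.any(y <= 0):
        raise ValueError("body_size must be strictly positive")
    out = (y / allometry.a) ** (1.0 / allometry.b)
    return float(out) if np.isscalar(body_size) else out


@dataclass(frozen=True)
class DietMatrix:
    """Diet proportions and the derived between-level flow matrix.

    ``proportions[i, j]`` is the fraction of prey size-bin ``j`` in the diet of
    a predator in size-bin ``i``; every row sums to one.  ``flow[i, j]`` is the
    fraction of prey bin ``j``'s production consumed by predators in bin ``i``
    (diet weights renormalised within each prey column); every column sums to
    one, so propagation conserves mass exactly up to the factor ``alpha``.
    """

    proportions: np.ndarray
    flow: np.ndarray
    log_kernel: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return self.proportions.shape[0]


def make_diet_matrix(grid: SizeGrid, phi: float, sigma: float, space: str = "log") -> DietMatrix:
    """Gaussian predator-prey size-ratio kernel on the grid.

    For each predator bin the kernel is a Gaussian over prey size centred on
    ``phi`` times the predator size.  Under ``space="log"`` (default) the
    kernel argument is ``log10(s_prey) - log10(phi * s_pred)`` and ``sigma`` is
    a spread in log10 size; ``space="linear"`` evaluates the same Gaussian in
    arithmetic size (metres).  Rows are renormalised to sum to one; for very
    small ``sigma`` each row degenerates to a one-hot vector at the bin nearest
    the preferred prey size (never an all-zero row).
    """
    if not (0 < phi < 1):
        raise ValueError(f"phi must be in (0, 1), got {phi}")
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    centers = grid.bin_centers
    if space == "log":
        u = np.log10(centers)
        pref = u + np.log10(phi)  # preferred prey, log10 m, per predator
        dev = u[None, :] - pref[:, None]
    elif space == "linear":
        pref = phi * centers
        dev = centers[None, :] - pref[:, None]
    else:
        raise ValueError("space must be 'log' or 'linear'")
    log_kernel = -0.5 * (dev / sigma) ** 2

    # Row-stochastic diet proportions (stable softmax per predator row).
    g = np.exp(log_kernel - log_kernel.max(axis=1, keepdims=True))
    proportions = g / g.sum(axis=1, keepdims=True)

    # Column-stochastic flow: weight exp(L_ij)/rowsum_i, renormalised per prey
    # column, all in log space so distant-tail columns never underflow to zero.
    log_row = logsumexp(log_kernel, axis=1)
    log_w = log_kernel - log_row[:, None]
    f = np.exp(log_w - log_w.max(axis=0, keepdims=True))
    flow = f / f.sum(axis=0, keepdims=True)

    return DietMatrix(proportions=proportions, flow=flow, log_kernel=log_kernel)


def primary_production_distribution(
    grid: SizeGrid,
    p_mu: float,
    p_sigma: float,
    total: float = 1.0,
) -> np.ndarray:
    """Gaussian primary-production size distribution evaluated at bin centers.

    The Gaussian is evaluated in arithmetic size (micrometres, the units in
    which its mean and spread are expressed) and rescaled so the vector sums to
    ``total``.  A mean outside the grid span triggers a warning; the
    distribution then concentrates in the nearest boundary bins.
    """
    if not (total > 0):
        raise ValueError(f"total must be > 0, got {total}")
    if not (p_mu > 0 and p_sigma > 0):
        raise ValueError("p_mu and p_sigma must be > 0")
    centers_um = grid.bin_centers * 1e6
    if not (centers_um[0] <= p_mu <= centers_um[-1]):
        warnings.warn(
            f"primary production mean size {p_mu} um lies outside the grid span "
            f"[{centers_um[0]:.3g}, {centers_um[-1]:.3g}] um",
            stacklevel=2,
        )
    log_g = -0.5 * ((p_mu - centers_um) / p_sigma) ** 2
    g = np.exp(log_g - log_g.max())
    return total * g / g.sum()


@dataclass(frozen=True)
class TrophicSolution:
    """Productivity per size bin per trophic level (columns l = 1..n_levels)."""

    productivity: np.ndarray  # (n_bins, n_levels)
    grid: SizeGrid

    @property
    def n_levels(self) -> int:
        return self.productivity.shape[1]

    def level_totals(self) -> np.ndarray:
        return self.productivity.sum(axis=0)

    def aggregate(self, levels: Sequence[int]) -> np.ndarray:
        """Summed productivity of the 1-based trophic levels in ``levels``."""
        idx = [l - 1 for l in levels]
        if any(i < 0 or i >= self.n_levels for i in idx):
            raise ValueError(f"levels {levels} outside 1..{self.n_levels}")
        return self.productivity[:, idx].sum(axis=1)


def propagate(
    p1: np.ndarray,
    diet: DietMatrix,
    alpha: float,
    n_levels: int = N_LEVELS,
    grid: SizeGrid | None = None,
) -> TrophicSolution:
    """Propagate primary production up ``n_levels`` trophic levels.

    ``P[:, l] = alpha * flow @ P[:, l-1]``, so level totals obey
    ``sum(P[:, l]) = alpha**(l-1) * sum(P[:, 1])`` exactly.  ``alpha = 0`` is
    accepted as the degenerate no-transfer case (levels above the first are
    identically zero).
    """
    p1 = np.asarray(p1, dtype=float)
    if np.any(p1 < 0) or not np.all(np.isfinite(p1)):
        raise ValueError("p1 must be finite and non-negative")
    if not (0 <= alpha < 1):
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if p1.shape != (diet.n_bins,):
        raise ValueError("p1 length must match the diet matrix")
    P = np.empty((diet.n_bins, n_levels))
    P[:, 0] = p1
    for l in range(1, n_levels):
        P[:, l] = alpha * (diet.flow @ P[:, l - 1])
    if grid is None:
        grid = SizeGrid(np.logspace(-7, 1, diet.n_bins + 1))
    return TrophicSolution(productivity=P, grid=grid)


@dataclass(frozen=True)
class PredictedToothDensity:
    """Model-predicted tooth-size productivity density."""

    tooth_axis: ToothAxis
    density: np.ndarray  # per um, >= 0
    total: float  # integral over the axis, relative units per Myr

    def normalized_shape(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalise a zero-mass density")
        return self.density / self.total


def predict_tooth_density(
    params: TrophicParams,
    grid: SizeGrid,
    tooth_axis: ToothAxis,
    levels: Sequence[int] = DEFAULT_LEVELS,
    pp_total: float = DEFAULT_PP_TOTAL,
    pp_multiplier: float = 1.0,
    scale: float = 1.0,
    kernel_space: str = "log",
) -> PredictedToothDensity:
    """Predicted tooth-size productivity density for a parameter vector.

    Production of the chosen trophic levels is mapped from body size onto the
    tooth axis through the inverse allometry and rebinned conserving mass; the
    returned density has units of (relative production per Myr) per um.
    ``scale`` applies an overall normalisation (e.g. ``1 / total`` of a
    calibrated reference solution, so that the reference prediction has total
    productivity of exactly one unit per Myr).
    """
    if pp_multiplier <= 0:
        raise ValueError("pp_multiplier must be > 0")
    diet = make_diet_matrix(grid, params.phi, params.sigma, space=kernel_space)
    p1 = primary_production_distribution(grid, params.p_mu, params.p_sigma, total=pp_total * pp_multiplier)
    solution = propagate(p1, diet, params.alpha, grid=grid)
    body_mass = solution.aggregate(levels)

    tooth_edges = body_to_tooth(grid.bin_edges, params.allometry)
    mass = rebin_mass(tooth_edges, body_mass, tooth_axis.bin_edges, space="log")
    total = float(mass.sum())
    if total <= 0:
        raise ValueError(
            "allometry (a={:.4g}, b={:.4g}) maps all trophic-level production "
            "outside the tooth axis [{:.4g}, {:.4g}] um".format(
                params.a, params.b, tooth_axis.bin_edges[0], tooth_axis.bin_edges[-1]
            )
        )
    density = scale * mass / tooth_axis.widths
    return PredictedToothDensity(tooth_axis=tooth_axis, density=density, total=scale * total)
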