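"""Discrete size axes shared across the package.

Two axes appear throughout: a logarithmic body-size grid (metres) on which the
trophic model is solved, and a tooth-length axis (micrometres) on which observed
and predicted tooth-size densities are compared.  Both store bin *edges*; bin
centers are geometric means, so each center lies inside its bin on either a
linear or a logarithmic view of the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SizeGrid", "ToothAxis", "rebin_mass"]


def _validate_edges(edges: np.ndarray) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("edges must be a 1-D array with at least two entries")
    if np.any(edges <= 0):
        raise ValueError("edges must be strictly positive")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    return edges


@dataclass(frozen=True)
class SizeGrid:
    """Logarithmic body-size axis shared by all trophic levels.

    The default construction spans 1e-7 to 1e1 metres, covering the food web
    from picophytoplankton to the largest pelagic predators.
    """

    bin_edges: np.ndarray  # metres, length n_bins + 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", _validate_edges(self.bin_edges))

    @classmethod
    def logarithmic(cls, n_bins: int = 200, lower: float = 1e-7, upper: float = 1e1) -> "SizeGrid":
        if n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if not (0 < lower < upper):
            raise ValueError("require 0 < lower < upper")
        return cls(np.logspace(np.log10(lower), np.log10(upper), n_bins + 1))

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin midpoints in metres."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def log10_centers(self) -> np.ndarray:
        return np.log10(self.bin_centers)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SizeGrid) and np.array_equal(self.bin_edges, other.bin_edges)

    def __hash__(self) -> int:
        return hash(self.bin_edges.tobytes())


@dataclass(frozen=True)
class ToothAxis:
    """Tooth-length axis in micrometres.

    The default spans 106 um (the picking threshold of the record the package
    is built around) to 2000 um, log-spaced.
    """

    bin_edges: np.ndarray = field(default_factory=lambda: np.logspace(np.log10(106.0), np.log10(2000.0), 65))

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", _validate_edges(self.bin_edges))

    @classmethod
    def logarithmic(cls, lower: float = 106.0, upper: float = 2000.0, n_bins: int = 64) -> "ToothAxis":
        return cls(np.logspace(np.log10(lower), np.log10(upper), n_bins + 1))

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        """Linear bin widths in micrometres (used for integrals)."""
        return np.diff(self.bin_edges)

    def integrate(self, density: np.ndarray) -> float:
        return float(np.sum(np.asarray(density, dtype=float) * self.widths))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ToothAxis) and np.array_equal(self.bin_edges, other.bin_edges)

    def __hash__(self) -> int:
        return hash(self.bin_edges.tobytes())


def rebin_mass(
    src_edges: np.ndarray,
    mass: np.ndarray,
    dst_edges: np.ndarray,
    space: str = "log",
) -> np.ndarray:
    """Redistribute per-bin mass from one edge set to another, conserving mass.

    Mass is assumed uniformly distributed within each source bin in the chosen
    coordinate (``"log"`` or ``"linear"``).  Mass falling outside the
    destination edges is dropped; the caller decides whether that is an error.
    """
    src_edges = _validate_edges(src_edges)
    dst_edges = _validate_edges(dst_edges)
    mass = np.asarray(mass, dtype=float)
    if mass.shape != (src_edges.size - 1,):
        raise ValueError("mass must have one entry per source bin")
    if space == "log":
        s, d = np.log(src_edges), np.log(dst_edges)
    elif space == "linear":
        s, d = src_edges, dst_edges
    else:
        raise ValueError("space must be 'log' or 'linear'")

    # Cumulative mass below coordinate t: each source bin contributes its
    # mass times the clipped fractional overlap.  Evaluate at destination
    # edges and difference.
    lo, hi = s[:-1], s[1:]
    frac = np.clip((d[:, None] - lo[None, :]) / (hi - lo)[None, :], 0.0, 1.0)
    cum = frac @ mass
    return np.diff(cum)
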