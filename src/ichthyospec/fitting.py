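"""Least-squares calibration of the trophic model against tooth-size densities.

The central object is :class:`ToothSpectrumModel`, built from a list of
per-time-bin observed (kernel-smoothed) tooth densities sharing one tooth axis.
``fit()`` calibrates the static seven-parameter reference solution by
minimising the pooled sum of squared density residuals with multi-start
Nelder-Mead plus an L-BFGS-B polish.  The time-varying experiments then
re-optimise a single named parameter (trophic efficiency ``alpha``, a total
primary-production multiplier ``total_pp``, preferred prey fraction ``phi`` or
diet spread ``sigma``) independently in each time bin while holding the other
parameters at their reference values, optionally under a per-bin
percent-change constraint or with the primary-production mean size co-varying
with the production multiplier.

Model comparison uses the RMSE reduction factor: reference total RMSE divided
by the time-varying fit's total RMSE (per-bin RMSE is over size bins; total
RMSE pools all bin x size residuals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from .axes import SizeGrid, ToothAxis
from .data import ToothDensity
from .spectrum import (
    DEFAULT_LEVELS,
    DEFAULT_PP_TOTAL,
    PredictedToothDensity,
    TrophicParams,
    predict_tooth_density,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "DEFAULT_START",
    "TIME_VARYING_PARAMETERS",
    "ModelConfig",
    "misfit",
    "sum_squares",
    "ToothSpectrumModel",
    "ReferenceFitResults",
    "TimeVaryingFitResults",
]

logger = logging.getLogger(__name__)

#: Generous boxes around ecologically plausible values for the optimiser.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "a": (1e-12, 1e3),
    "b": (0.3, 2.0),
    "alpha": (0.01, 0.5),
    "sigma": (0.01, 2.0),
    "phi": (0.001, 0.5),
    "p_mu": (1.0, 500.0),
    "p_sigma": (0.5, 100.0),
}

#: Neutral optimiser start: mid-range efficiency and predator-prey geometry.
DEFAULT_START = TrophicParams.from_dict(
    {"a": 1e-4, "b": 1.5, "alpha": 0.1, "sigma": 0.25, "phi": 0.1, "p_mu": 50.0, "p_sigma": 5.0}
)

#: The four single-parameter time-varying experiments.
TIME_VARYING_PARAMETERS = ("alpha", "total_pp", "phi", "sigma")

# Optimiser coordinates: log10 for scale-like parameters.
_VECTOR_FIELDS = ("a", "b", "alpha", "sigma", "phi", "p_mu", "p_sigma")
_LOG_FIELDS = {"a", "p_mu", "p_sigma"}
_PENALTY = 1e12


@dataclass(frozen=True)
class ModelConfig:
    """Forward-model configuration shared by all fits.

    levels are the 1-based trophic levels aggregated into the tooth
    prediction; pp_total is total primary production in relative units/Myr;
    kernel_space selects log10 (default) or arithmetic diet kernels.
    """

    grid: SizeGrid = field(default_factory=SizeGrid.logarithmic)
    levels: tuple[int, ...] = DEFAULT_LEVELS
    pp_total: float = DEFAULT_PP_TOTAL
    kernel_space: str = "log"

    def to_dict(self) -> dict:
        return {
            "grid_n_bins": self.grid.n_bins,
            "grid_lower_m": float(self.grid.bin_edges[0]),
            "grid_upper_m": float(self.grid.bin_edges[-1]),
            "levels": list(self.levels),
            "pp_total": self.pp_total,
            "kernel_space": self.kernel_space,
        }


def sum_squares(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pooled sum of squared density residuals."""
    f = np.asarray(observed, dtype=float)
    fhat = np.asarray(predicted, dtype=float)
    if f.shape != fhat.shape:
        raise ValueError(f"density shapes differ: {f.shape} vs {fhat.shape}")
    return float(np.sum((f - fhat) ** 2))


def misfit(predicted: PredictedToothDensity | ToothDensity, observed: ToothDensity) -> float:
    """Sum-of-squares misfit between two densities on the same tooth axis."""
    if predicted.tooth_axis != observed.tooth_axis:
        raise ValueError("predicted and observed densities are on different tooth axes")
    return sum_squares(observed.density, predicted.density)


def _params_to_vector(params: TrophicParams) -> np.ndarray:
    d = params.to_dict()
    return np.array([np.log10(d[k]) if k in _LOG_FIELDS else d[k] for k in _VECTOR_FIELDS])


def _vector_to_params(x: np.ndarray) -> TrophicParams:
    d = {k: (10.0 ** x[i] if k in _LOG_FIELDS else float(x[i])) for i, k in enumerate(_VECTOR_FIELDS)}
    return TrophicParams.from_dict(d)


def _vector_bounds(bounds: dict[str, tuple[float, float]]) -> list[tuple[float, float]]:
    out = []
    for k in _VECTOR_FIELDS:
        lo, hi = bounds[k]
        if k in _LOG_FIELDS:
            lo, hi = np.log10(lo), np.log10(hi)
        out.append((lo, hi))
    return out


@dataclass
class ReferenceFitResults:
    """Calibrated static reference solution."""

    params: TrophicParams
    ss: float
    rmse_per_bin: np.ndarray
    rmse_total: float
    bin_centers: np.ndarray
    converged: bool
    n_starts: int
    optimizer_trace: list = field(default_factory=list)
    model: "ToothSpectrumModel | None" = field(default=None, repr=False)

    @property
    def predicted_total(self) -> float:
        """Total productivity (relative units/Myr) of the reference solution."""
        return float(self.model.predict_density(self.params).total) if self.model is not None else np.nan

    def summary(self) -> str:
        p = self.params.to_dict()
        lines = [
            "Static reference fit (trophic size-spectrum model)",
            "=" * 52,
            f"time bins: {len(self.bin_centers)}   converged: {self.converged}   starts: {self.n_starts}",
            f"sum of squares: {self.ss:.6g}    total RMSE: {self.rmse_total:.6g}",
            "-" * 52,
        ]
        for k in _VECTOR_FIELDS:
            lines.append(f"  {k:8s} = {p[k]:.6g}")
        return "\n".join(lines)


@dataclass
class TimeVaryingFitResults:
    """Per-bin single-parameter re-optimisation around a reference fit."""

    parameter_name: str
    trajectory: np.ndarray
    bin_centers: np.ndarray
    ss: float
    rmse_per_bin: np.ndarray
    rmse_total: float
    reference_rmse_total: float
    constraint_pct: float | None = None
    size_scaling_slope: float | None = None
    rmse_ratio_vs_unscaled: float | None = None
    converged: bool = True

    @property
    def reduction_factor(self) -> float:
        """Reference RMSE / time-varying RMSE (>= 1 up to optimiser noise)."""
        if self.rmse_total == 0.0:
            return 1.0 if self.reference_rmse_total == 0.0 else np.inf
        return self.reference_rmse_total / self.rmse_total

    def max_pct_change_per_bin(self) -> float:
        """Largest realised per-bin percent change along the trajectory."""
        t = self.trajectory
        if t.size < 2:
            return 0.0
        return float(100.0 * np.max(np.abs(np.diff(t)) / t[:-1]))

    def summary(self) -> str:
        lines = [
            f"Time-varying fit: parameter '{self.parameter_name}'",
            "=" * 52,
            f"bins: {len(self.bin_centers)}   constraint: "
            + (f"{self.constraint_pct}%/bin" if self.constraint_pct is not None else "none"),
            f"total RMSE: {self.rmse_total:.6g}   reference RMSE: {self.reference_rmse_total:.6g}",
            f"RMSE reduction factor vs reference: {self.reduction_factor:.4g}",
            f"max realised change per bin: {self.max_pct_change_per_bin():.3g}%",
        ]
        if self.size_scaling_slope is not None:
            lines.append(f"size-productivity scaling slope: {self.size_scaling_slope:.4g}")
        if self.rmse_ratio_vs_unscaled is not None:
            lines.append(f"RMSE ratio vs unscaled PP fit: {self.rmse_ratio_vs_unscaled:.4g}")
        lines.append("-" * 52)
        for t, v in zip(self.bin_centers, self.trajectory):
            lines.append(f"  {t:7.2f} Ma   {v:.6g}")
        return "\n".join(lines)


class ToothSpectrumModel:
    """Trophic size-spectrum model bound to observed tooth-size densities.

    Parameters
    ----------
    observed
        Per-time-bin densities on a shared tooth axis (ordered oldest or
        youngest first; order is preserved).
    config
        Forward-model configuration (grid, aggregated levels, kernel space).
    """

    def __init__(self, observed: Sequence[ToothDensity], config: ModelConfig | None = None):
        observed = list(observed)
        if not observed:
            raise ValueError("need at least one observed density")
        axis = observed[0].tooth_axis
        for d in observed[1:]:
            if d.tooth_axis != axis:
                raise ValueError("all observed densities must share one tooth axis")
        self.observed = observed
        self.tooth_axis: ToothAxis = axis
        self.config = config or ModelConfig()
        self.F = np.vstack([d.density for d in observed])  # (B, K)
        self.bin_centers = np.array([np.nan if d.bin_center is None else d.bin_center for d in observed])

    # ----- forward model ---------------------------------------------------
    def predict_density(self, params: TrophicParams, pp_multiplier: float = 1.0) -> PredictedToothDensity:
        return predict_tooth_density(
            params,
            self.config.grid,
            self.tooth_axis,
            levels=self.config.levels,
            pp_total=self.config.pp_total,
            pp_multiplier=pp_multiplier,
            kernel_space=self.config.kernel_space,
        )

    def _predict_safe(self, params: TrophicParams, pp_multiplier: float = 1.0) -> np.ndarray | None:
        try:
            return self.predict_density(params, pp_multiplier).density
        except (ValueError, FloatingPointError):
            return None

    # ----- objectives ------------------------------------------------------
    def loss(self, params: TrophicParams) -> float:
        """Pooled sum of squares of the static model against all bins."""
        fhat = self._predict_safe(params)
        if fhat is None:
            return _PENALTY
        return float(np.sum((self.F - fhat[None, :]) ** 2))

    def _bin_loss(self, b: int, params: TrophicParams, pp_multiplier: float = 1.0) -> float:
        fhat = self._predict_safe(params, pp_multiplier)
        if fhat is None:
            return _PENALTY
        return float(np.sum((self.F[b] - fhat) ** 2))

    def _rmse_stats(self, ss_per_bin: np.ndarray) -> tuple[float, np.ndarray, float]:
        K = self.F.shape[1]
        ss = float(np.sum(ss_per_bin))
        rmse_per_bin = np.sqrt(ss_per_bin / K)
        rmse_total = float(np.sqrt(ss / self.F.size))
        return ss, rmse_per_bin, rmse_total

    def _static_ss_per_bin(self, params: TrophicParams) -> np.ndarray:
        fhat = self._predict_safe(params)
        if fhat is None:
            raise ValueError("reference parameters map all production outside the tooth axis")
        return np.sum((self.F - fhat[None, :]) ** 2, axis=1)

    # ----- static reference calibration ------------------------------------
    def fit(
        self,
        start: TrophicParams | None = None,
        bounds: dict[str, tuple[float, float]] | None = None,
        n_starts: int = 20,
        seed: int = 0,
        maxfev: int = 2000,
        polish: bool = True,
    ) -> ReferenceFitResults:
        """Calibrate the static reference parameters.

        Runs Nelder-Mead from ``n_starts`` Latin-hypercube points inside the
        bounds (plus the supplied or default start) and polishes the best
        candidates with L-BFGS-B.  The returned fit never has a larger sum of
        squares than its best initialisation (descent guarantee).
        """
        bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
        vb = _vector_bounds(bounds)
        lo = np.array([b[0] for b in vb])
        hi = np.array([b[1] for b in vb])

        def objective(x: np.ndarray) -> float:
            try:
                params = _vector_to_params(np.clip(x, lo, hi))
            except ValueError:
                return _PENALTY
            return self.loss(params)

        starts = [_params_to_vector(start or DEFAULT_START)]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(_VECTOR_FIELDS), seed=seed)
            starts.extend(lo + sampler.random(n_starts - 1) * (hi - lo))

        trace = []
        candidates = []
        for i, x0 in enumerate(starts):
            x0 = np.clip(x0, lo, hi)
            f0 = objective(x0)
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                bounds=vb,
                options={"maxfev": maxfev, "xatol": 1e-8, "fatol": 1e-12, "adaptive": True},
            )
            best_x, best_f = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
            trace.append({"start": i, "ss": float(best_f), "nfev": int(res.nfev)})
            candidates.append((best_f, best_x, bool(res.success)))
        candidates.sort(key=lambda c: c[0])

        best_f, best_x, success = candidates[0]
        if polish:
            for f0, x0, _ in candidates[: min(3, len(candidates))]:
                res = optimize.minimize(
                    objective, x0, method="L-BFGS-B", bounds=vb, options={"maxfun": 4000, "ftol": 1e-15, "gtol": 1e-12}
                )
                if res.fun < best_f:
                    best_f, best_x, success = res.fun, res.x, True
                trace.append({"polish_from_ss": float(f0), "ss": float(res.fun)})
        if best_f >= _PENALTY:
            raise RuntimeError(f"reference fit failed from every start; trace: {trace}")

        params = _vector_to_params(np.clip(best_x, lo, hi))
        ss_per_bin = self._static_ss_per_bin(params)
        ss, rmse_per_bin, rmse_total = self._rmse_stats(ss_per_bin)
        return ReferenceFitResults(
            params=params,
            ss=ss,
            rmse_per_bin=rmse_per_bin,
            rmse_total=rmse_total,
            bin_centers=self.bin_centers,
            converged=success,
            n_starts=len(starts),
            optimizer_trace=trace,
            model=self,
        )

    def evaluate(self, params: TrophicParams) -> ReferenceFitResults:
        """Score a fixed parameter vector as a (non-optimised) reference."""
        ss_per_bin = self._static_ss_per_bin(params)
        ss, rmse_per_bin, rmse_total = self._rmse_stats(ss_per_bin)
        return ReferenceFitResults(
            params=params,
            ss=ss,
            rmse_per_bin=rmse_per_bin,
            rmse_total=rmse_total,
            bin_centers=self.bin_centers,
            converged=True,
            n_starts=0,
            optimizer_trace=[{"evaluate": True}],
            model=self,
        )

    # ----- time-varying machinery -------------------------------------------
    def _coordinate(self, parameter_name: str, reference: ReferenceFitResults):
        """Reference value, global bounds and per-bin objective for one coordinate."""
        if parameter_name not in TIME_VARYING_PARAMETERS:
            raise ValueError(f"unknown parameter {parameter_name!r}; allowed: {TIME_VARYING_PARAMETERS}")
        ref_params = reference.params
        if parameter_name == "total_pp":
            ref_value = 1.0
            lo, hi = 1e-3, 1e3

            def bin_loss(b: int, v: float) -> float:
                return self._bin_loss(b, ref_params, pp_multiplier=v)

        else:
            ref_value = getattr(ref_params, parameter_name)
            lo, hi = DEFAULT_BOUNDS[parameter_name]

            def bin_loss(b: int, v: float) -> float:
                try:
                    p = ref_params.replace(**{parameter_name: v})
                except ValueError:
                    return _PENALTY
                return self._bin_loss(b, p)

        return ref_value, (lo, hi), bin_loss

    @staticmethod
    def _minimize_bin(bin_loss, b: int, lo: float, hi: float, start: float) -> tuple[float, float]:
        """Bounded 1-D minimisation in log10 of the value, with a keep-best guard."""
        f_start = bin_loss(b, start)
        res = optimize.minimize_scalar(
            lambda u: bin_loss(b, 10.0**u),
            bounds=(np.log10(lo), np.log10(hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        v, f = 10.0**res.x, res.fun
        if f_start <= f:
            return start, f_start
        return float(v), float(f)

    def fit_time_varying(self, parameter_name: str, reference: ReferenceFitResults) -> TimeVaryingFitResults:
        """Re-optimise one parameter independently in each time bin.

        All other parameters are held at their reference values; for
        ``total_pp`` the optimised quantity is a per-bin multiplier on total
        primary production (reference solution = 1).
        """
        ref_value, (lo, hi), bin_loss = self._coordinate(parameter_name, reference)
        B = self.F.shape[0]
        trajectory = np.empty(B)
        ss_per_bin = np.empty(B)
        for b in range(B):
            trajectory[b], ss_per_bin[b] = self._minimize_bin(bin_loss, b, lo, hi, ref_value)
        ss, rmse_per_bin, rmse_total = self._rmse_stats(ss_per_bin)
        return TimeVaryingFitResults(
            parameter_name=parameter_name,
            trajectory=trajectory,
            bin_centers=self.bin_centers,
            ss=ss,
            rmse_per_bin=rmse_per_bin,
            rmse_total=rmse_total,
            reference_rmse_total=reference.rmse_total,
        )

    def fit_constrained_variation(
        self,
        parameter_name: str,
        max_pct: float,
        reference: ReferenceFitResults,
        warm_start: np.ndarray | None = None,
        polish: bool = True,
    ) -> TimeVaryingFitResults:
        """Time-varying fit with the per-bin change bounded to ``max_pct`` percent.

        The constraint chains forward in time from the reference value: each
        bin's value must lie within +/- ``max_pct`` percent of the previous
        bin's fitted value (the first bin is anchored to the reference value).
        A greedy forward pass supplies a feasible trajectory which a joint
        L-BFGS-B polish over per-bin ratio variables then refines; the best of
        greedy, warm start and polish is returned, so the result never
        degrades a supplied feasible warm start.
        """
        if max_pct < 0:
            raise ValueError("max_pct must be >= 0")
        ref_value, (glo, ghi), bin_loss = self._coordinate(parameter_name, reference)
        B = self.F.shape[0]
        p = max_pct / 100.0

        def trajectory_ss(traj: np.ndarray) -> np.ndarray:
            return np.array([bin_loss(b, traj[b]) for b in range(B)])

        if max_pct == 0:
            trajectory = np.full(B, ref_value)
            ss_per_bin = trajectory_ss(trajectory)
        else:
            # greedy forward pass
            greedy = np.empty(B)
            prev = ref_value
            for b in range(B):
                lo = max(prev * (1 - p), glo if prev * (1 - p) <= 0 else prev * (1 - p), 1e-12)
                hi = prev * (1 + p)
                greedy[b], _ = self._minimize_bin(bin_loss, b, lo, hi, prev)
                prev = greedy[b]

            candidates = [greedy]
            if warm_start is not None:
                candidates.append(np.asarray(warm_start, dtype=float))

            def to_r(traj: np.ndarray) -> np.ndarray:
                prevs = np.concatenate([[ref_value], traj[:-1]])
                return np.clip(traj / prevs - 1.0, -p, p)

            def to_traj(r: np.ndarray) -> np.ndarray:
                return ref_value * np.cumprod(1.0 + r)

            def objective(r: np.ndarray) -> float:
                return float(np.sum(trajectory_ss(to_traj(r))))

            best = min(candidates, key=lambda t: float(np.sum(trajectory_ss(t))))
            if polish:
                res = optimize.minimize(
                    objective,
                    to_r(best),
                    method="L-BFGS-B",
                    bounds=[(-p, p)] * B,
                    options={"maxfun": 3000, "ftol": 1e-15},
                )
                polished = to_traj(res.x)
                candidates.append(polished)
            scored = [(float(np.sum(trajectory_ss(t))), t) for t in candidates]
            scored.sort(key=lambda c: c[0])
            trajectory = scored[0][1]
            ss_per_bin = trajectory_ss(trajectory)

        ss, rmse_per_bin, rmse_total = self._rmse_stats(ss_per_bin)
        return TimeVaryingFitResults(
            parameter_name=parameter_name,
            trajectory=trajectory,
            bin_centers=self.bin_centers,
            ss=ss,
            rmse_per_bin=rmse_per_bin,
            rmse_total=rmse_total,
            reference_rmse_total=reference.rmse_total,
            constraint_pct=max_pct,
        )

    def constrained_sweep(
        self,
        parameter_name: str,
        reference: ReferenceFitResults,
        pcts: Sequence[float] = (5, 10, 20, 30, 40, 50, 100),
        polish: bool = True,
    ) -> dict[float, TimeVaryingFitResults]:
        """Constrained-variation sensitivity over a ladder of percent limits.

        Each level warm-starts from the previous (feasible) solution, which
        makes the total RMSE non-increasing along the ladder by construction.
        """
        results: dict[float, TimeVaryingFitResults] = {}
        warm = None
        for pct in sorted(pcts):
            res = self.fit_constrained_variation(parameter_name, pct, reference, warm_start=warm, polish=polish)
            results[pct] = res
            warm = res.trajectory
        return results

    def fit_pp_with_size_scaling(
        self,
        reference: ReferenceFitResults,
        slope: float = 1.0,
        unscaled: TimeVaryingFitResults | None = None,
    ) -> TimeVaryingFitResults:
        """Time-varying primary production with size-productivity scaling.

        The mean size of the primary-production distribution co-varies linearly
        with the per-bin production multiplier ``m``:
        ``p_mu(m) = p_mu_ref * (1 + slope * (m - 1))``, so richer systems are
        built on larger phytoplankton.  ``slope = 0`` reduces exactly to the
        unscaled time-varying production fit; negative slopes are rejected.
        If an ``unscaled`` fit is supplied, the ratio of this fit's RMSE to the
        unscaled fit's RMSE is reported.
        """
        if slope < 0:
            raise ValueError("size-productivity scaling slope must be non-negative")
        ref_params = reference.params
        p_mu_ref = ref_params.p_mu
        lo, hi = 1e-3, 1e3
        if slope > 0:
            # keep p_mu positive along the line
            lo = max(lo, 1.0 - 1.0 / slope + 1e-9)

        def bin_loss(b: int, m: float) -> float:
            try:
                params = ref_params.replace(p_mu=p_mu_ref * (1.0 + slope * (m - 1.0)))
            except ValueError:
                return _PENALTY
            return self._bin_loss(b, params, pp_multiplier=m)

        B = self.F.shape[0]
        trajectory = np.empty(B)
        ss_per_bin = np.empty(B)
        for b in range(B):
            trajectory[b], ss_per_bin[b] = self._minimize_bin(bin_loss, b, lo, hi, 1.0)
        ss, rmse_per_bin, rmse_total = self._rmse_stats(ss_per_bin)
        ratio = None if unscaled is None else (rmse_total / unscaled.rmse_total if unscaled.rmse_total > 0 else np.inf)
        return TimeVaryingFitResults(
            parameter_name="total_pp",
            trajectory=trajectory,
            bin_centers=self.bin_centers,
            ss=ss,
            rmse_per_bin=rmse_per_bin,
            rmse_total=rmse_total,
            reference_rmse_total=reference.rmse_total,
            size_scaling_slope=slope,
            rmse_ratio_vs_unscaled=ratio,
        )
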