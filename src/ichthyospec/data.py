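"""Ichthyolith measurement tables, age models, accumulation rates and densities.

This module owns all file I/O of the package.  Input schemas (CSV):

measurements
    ``sample_id, depth_m (optional), age_ma (optional), length_um`` — one row
    per ichthyolith.
samples
    ``sample_id, depth_m, age_ma, area_cm2, duration_myr, count`` — one row per
    sediment sample; IAR derives from these.
age model
    ``depth_m, age_ma`` control points, strictly monotone in both coordinates.
temperature
    ``age_ma, temp_c``.

Ages are in Ma (millions of years before present), depths in metres below
seafloor, tooth lengths in micrometres, IAR in ichthyoliths/cm2/Myr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import ToothAxis

__all__ = [
    "MIN_TOOTH_LENGTH_UM",
    "STUDY_WINDOW_MA",
    "AgeModel",
    "ToothDensity",
    "read_measurements",
    "read_samples",
    "read_age_model",
    "read_temperature",
    "apply_size_filter",
    "assign_ages",
    "compute_iar",
    "bin_series",
    "smooth_tooth_density",
    "intra_bin_sd",
    "bin_tooth_densities",
    "silverman_bandwidth",
]

logger = logging.getLogger(__name__)

#: Picking threshold: only teeth longer than this were recovered from the sieve
#: residue, so all analyses are conditioned on length >= 106 um.
MIN_TOOTH_LENGTH_UM = 106.0

#: Default study window (young edge, old edge) in Ma.
STUDY_WINDOW_MA: tuple[float, float] = (46.0, 62.0)

#: Fallback kernel bandwidth (log10 um) when a bin holds a single measurement
#: or zero spread; with one tooth the density is the kernel itself.
FALLBACK_BANDWIDTH_LOG10 = 0.05


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing required column(s) {missing}; found {list(df.columns)}")


def read_measurements(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ["sample_id", "length_um"], "measurements")
    if "depth_m" not in df.columns and "age_ma" not in df.columns:
        raise ValueError("measurements need at least one of depth_m / age_ma")
    if df["length_um"].isna().any() or (df["length_um"] <= 0).any():
        raise ValueError("length_um must be positive and non-missing")
    return df


def read_samples(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ["sample_id", "age_ma", "area_cm2", "duration_myr", "count"], "samples")
    df = df.copy()
    df["iar"] = compute_iar(df["count"].to_numpy(float), df["area_cm2"].to_numpy(float), df["duration_myr"].to_numpy(float))
    return df


def read_age_model(path: str | Path, delimiter: str = ",") -> "AgeModel":
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ["depth_m", "age_ma"], "age model")
    return AgeModel(df["depth_m"].to_numpy(float), df["age_ma"].to_numpy(float))


def read_temperature(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, ["age_ma", "temp_c"], "temperature")
    if not np.all(np.isfinite(df["temp_c"])):
        raise ValueError("temperature record contains non-finite values")
    return df


def apply_size_filter(measurements: pd.DataFrame, min_length: float = MIN_TOOTH_LENGTH_UM) -> pd.DataFrame:
    """Drop teeth below the picking threshold, logging how many were removed."""
    keep = measurements["length_um"] >= min_length
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("size filter: dropped %d of %d measurements below %.0f um", n_dropped, len(measurements), min_length)
    return measurements.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class AgeModel:
    """Piecewise-linear depth-to-age mapping from monotone control points."""

    depths_m: np.ndarray
    ages_ma: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_m, dtype=float)
        a = np.asarray(self.ages_ma, dtype=float)
        if d.shape != a.shape or d.ndim != 1 or d.size < 2:
            raise ValueError("age model needs matching 1-D depth and age arrays of length >= 2")
        order = np.argsort(d)
        d, a = d[order], a[order]
        if np.any(np.diff(d) <= 0) or np.any(np.diff(a) <= 0):
            raise ValueError("age model control points must be strictly monotone in depth and age")
        object.__setattr__(self, "depths_m", d)
        object.__setattr__(self, "ages_ma", a)

    def __call__(self, depth_m: np.ndarray | float) -> np.ndarray | float:
        depth = np.atleast_1d(np.asarray(depth_m, dtype=float))
        bad = (depth < self.depths_m[0]) | (depth > self.depths_m[-1])
        if bad.any():
            raise ValueError(
                f"depth(s) {np.asarray(depth)[bad][:10]} outside the age-model span "
                f"[{self.depths_m[0]}, {self.depths_m[-1]}] m"
            )
        out = np.interp(depth, self.depths_m, self.ages_ma)
        return float(out[0]) if np.isscalar(depth_m) else out

    def depth_at(self, age_ma: np.ndarray | float) -> np.ndarray | float:
        """Inverse mapping (age -> depth), valid on the control-point span."""
        age = np.atleast_1d(np.asarray(age_ma, dtype=float))
        bad = (age < self.ages_ma[0]) | (age > self.ages_ma[-1])
        if bad.any():
            raise ValueError(f"age(s) outside the age-model span [{self.ages_ma[0]}, {self.ages_ma[-1]}] Ma")
        out = np.interp(age, self.ages_ma, self.depths_m)
        return float(out[0]) if np.isscalar(age_ma) else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"depth_m": self.depths_m, "age_ma": self.ages_ma})


def assign_ages(measurements: pd.DataFrame, age_model: AgeModel) -> pd.DataFrame:
    """Attach interpolated ages to a table that carries depths.

    Rows with a missing ``age_ma`` get the age-model interpolation of their
    depth; existing ages are kept.  Depths outside the model span raise, with
    the offending sample ids in the message.
    """
    df = measurements.copy()
    if "age_ma" not in df.columns:
        df["age_ma"] = np.nan
    needs = df["age_ma"].isna()
    if needs.any():
        if "depth_m" not in df.columns:
            raise ValueError("cannot assign ages: no depth_m column")
        depths = df.loc[needs, "depth_m"].to_numpy(float)
        lo, hi = age_model.depths_m[0], age_model.depths_m[-1]
        bad = (depths < lo) | (depths > hi)
        if bad.any():
            offenders = df.loc[needs].loc[bad, "sample_id"].unique()[:10].tolist()
            raise ValueError(f"samples {offenders} have depths outside the age-model span [{lo}, {hi}] m")
        df.loc[needs, "age_ma"] = age_model(depths)
    return df


def compute_iar(count: np.ndarray | float, area_cm2: np.ndarray | float, duration_myr: np.ndarray | float) -> np.ndarray | float:
    """Ichthyolith accumulation rate: count / (area * duration), per cm2 per Myr."""
    count = np.asarray(count, dtype=float)
    area = np.asarray(area_cm2, dtype=float)
    dur = np.asarray(duration_myr, dtype=float)
    if np.any(area <= 0) or np.any(dur <= 0):
        raise ValueError("area_cm2 and duration_myr must be strictly positive")
    if np.any(count < 0):
        raise ValueError("count must be non-negative")
    out = count / (area * dur)
    return float(out) if out.ndim == 0 else out


def bin_edges_for(window: tuple[float, float], width: float) -> np.ndarray:
    """Uniform bin edges over the study window (young, old) in Ma."""
    young, old = sorted(window)
    span = old - young
    n = span / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"bin width {width} does not divide the window span {span}")
    return young + width * np.arange(round(n) + 1)


def bin_series(
    values: pd.DataFrame,
    window: tuple[float, float] = STUDY_WINDOW_MA,
    width: float = 1.0,
    value_col: str = "iar",
    age_col: str = "age_ma",
) -> pd.DataFrame:
    """Group a point series into uniform time bins.

    Bins are half-open ``[edge, edge + width)`` with the oldest edge closed, so
    every in-window point lands in exactly one bin.  Returns one row per bin
    (empty bins included with ``n = 0`` and logged) with the per-bin mean,
    sample SD (ddof=1, NaN for n < 2) and count.
    """
    edges = bin_edges_for(window, width)
    ages = values[age_col].to_numpy(float)
    vals = values[value_col].to_numpy(float)
    inside = (ages >= edges[0]) & (ages <= edges[-1])
    ages, vals = ages[inside], vals[inside]
    idx = np.minimum(np.searchsorted(edges, ages, side="right") - 1, edges.size - 2)

    rows = []
    for b in range(edges.size - 1):
        v = vals[idx == b]
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "bin_width": width,
                "mean": v.mean() if v.size else np.nan,
                "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                "n": int(v.size),
            }
        )
    out = pd.DataFrame(rows)
    n_empty = int((out["n"] == 0).sum())
    if n_empty:
        logger.warning("%d of %d bins are empty and will be excluded from fitting", n_empty, len(out))
    return out


def silverman_bandwidth(log10_lengths: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth on log10 tooth lengths.

    ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``; falls back to a fixed small
    bandwidth for a single measurement or zero spread.
    """
    u = np.asarray(log10_lengths, dtype=float)
    n = u.size
    if n < 2:
        return FALLBACK_BANDWIDTH_LOG10
    sd = u.std(ddof=1)
    iqr = np.subtract(*np.percentile(u, [75, 25]))
    a = min(sd, iqr / 1.34) if iqr > 0 else sd
    if a <= 0:
        return FALLBACK_BANDWIDTH_LOG10
    return 0.9 * a * n ** (-0.2)


@dataclass(frozen=True)
class ToothDensity:
    """Kernel-smoothed tooth-size density for one time bin.

    ``density`` is per um on ``tooth_axis``; its discrete integral equals
    ``total`` (the bin's relative IAR) exactly by construction.
    """

    tooth_axis: ToothAxis
    density: np.ndarray
    total: float
    bin_center: float | None = None  # Ma
    n_obs: int = 0
    bandwidth: float | None = None  # log10 um

    def integral(self) -> float:
        return self.tooth_axis.integrate(self.density)


def smooth_tooth_density(
    lengths_um: np.ndarray,
    tooth_axis: ToothAxis,
    bandwidth: float | None = None,
    total: float = 1.0,
    bin_center: float | None = None,
) -> ToothDensity:
    """Gaussian kernel density of tooth lengths, rescaled to a target integral.

    The kernel acts on log10 length with a bandwidth from Silverman's rule
    unless given.  With a single measurement the density is the kernel itself.
    The density is truncated to the tooth axis and rescaled so its discrete
    integral equals ``total`` exactly.
    """
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size == 0:
        raise ValueError("smooth_tooth_density needs at least one measurement")
    if np.any(lengths <= 0):
        raise ValueError("tooth lengths must be positive")
    u_obs = np.log10(lengths)
    h = silverman_bandwidth(u_obs) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    x = tooth_axis.bin_centers
    u = np.log10(x)
    # density per log10 um, then converted to per um
    g = np.exp(-0.5 * ((u[:, None] - u_obs[None, :]) / h) ** 2).sum(axis=1)
    g /= lengths.size * h * np.sqrt(2 * np.pi)
    f = g / (x * np.log(10.0))
    raw = tooth_axis.integrate(f)
    if raw <= 0:
        raise ValueError("all kernel mass falls outside the tooth axis")
    f *= total / raw
    return ToothDensity(
        tooth_axis=tooth_axis,
        density=f,
        total=float(total),
        bin_center=bin_center,
        n_obs=int(lengths.size),
        bandwidth=h,
    )


def intra_bin_sd(binned: pd.DataFrame) -> tuple[pd.Series, float]:
    """Within-bin percent standard deviation (100 * sd / mean) and its average.

    Only bins with at least two samples contribute; if none qualify the record
    cannot support a noise estimate and an error is raised.
    """
    ok = binned["n"] >= 2
    if not ok.any():
        raise ValueError("no bin holds >= 2 samples; intra-bin SD is undefined")
    pct = 100.0 * binned.loc[ok, "sd"] / binned.loc[ok, "mean"]
    return pct, float(pct.mean())


def bin_tooth_densities(
    measurements: pd.DataFrame,
    iar_binned: pd.DataFrame,
    tooth_axis: ToothAxis,
    relative: bool = True,
    bandwidth: float | None = None,
) -> list[ToothDensity]:
    """Per-time-bin smoothed densities scaled to (relative) total IAR.

    With ``relative=True`` each bin's integral is its mean IAR divided by the
    record-mean IAR, matching the model's convention that the reference
    solution carries one relative unit of production per Myr.  Empty bins are
    skipped.  Measurements are assigned to bins with the same half-open edges
    as :func:`bin_series`.
    """
    mean_iar = iar_binned.loc[iar_binned["n"] > 0, "mean"].mean()
    densities = []
    for _, row in iar_binned.iterrows():
        if row["n"] == 0 or not np.isfinite(row["mean"]):
            continue
        sel = (measurements["age_ma"] >= row["bin_left"]) & (
            (measurements["age_ma"] < row["bin_right"])
            | ((row["bin_right"] == iar_binned["bin_right"].max()) & (measurements["age_ma"] == row["bin_right"]))
        )
        lengths = measurements.loc[sel, "length_um"].to_numpy(float)
        if lengths.size == 0:
            logger.warning("time bin %.2f Ma has IAR samples but no measured teeth; skipped", row["bin_center"])
            continue
        total = row["mean"] / mean_iar if relative else row["mean"]
        densities.append(
            smooth_tooth_density(lengths, tooth_axis, bandwidth=bandwidth, total=total, bin_center=row["bin_center"])
        )
    return densities
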