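"""Data-layer tests: age models, IAR, binning, kernel-smoothed densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ichthyospec import (
    AgeModel,
    ToothAxis,
    apply_size_filter,
    assign_ages,
    bin_series,
    compute_iar,
    intra_bin_sd,
    smooth_tooth_density,
)
from ichthyospec.data import read_measurements, read_temperature


# ----- age model ------------------------------------------------------------


def test_age_model_linear_midpoint():
    am = AgeModel([0.0, 10.0], [0.0, 10.0])
    assert am(5.0) == pytest.approx(5.0)


def test_age_model_exact_at_control_points():
    am = AgeModel([0.0, 2.0, 7.0], [46.0, 50.0, 62.0])
    assert am(2.0) == 50.0
    assert am(7.0) == 62.0


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_age_model_monotone_against_segment_search(seed):
    """Interpolated ages are monotone and match a brute-force segment lookup."""
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 8)
    depths = np.cumsum(rng.uniform(0.1, 2.0, n))
    ages = np.cumsum(rng.uniform(0.1, 5.0, n))
    am = AgeModel(depths, ages)
    q = rng.uniform(depths[0], depths[-1], 20)
    out = am(np.sort(q))
    assert np.all(np.diff(out) >= 0)
    for d, a in zip(np.sort(q), out):
        k = np.searchsorted(depths, d, side="right") - 1
        k = min(max(k, 0), n - 2)
        frac = (d - depths[k]) / (depths[k + 1] - depths[k])
        assert a == pytest.approx(ages[k] + frac * (ages[k + 1] - ages[k]), rel=1e-12)


def test_age_model_rejects_non_monotone():
    with pytest.raises(ValueError):
        AgeModel([0.0, 1.0, 2.0], [3.0, 2.0, 5.0])


def test_assign_ages_errors_name_offending_samples():
    am = AgeModel([0.0, 1.0], [46.0, 62.0])
    df = pd.DataFrame({"sample_id": ["ok", "bad"], "depth_m": [0.5, 5.0]})
    with pytest.raises(ValueError, match="bad"):
        assign_ages(df, am)


def test_assign_ages_interpolates_missing_only():
    am = AgeModel([0.0, 10.0], [0.0, 10.0])
    df = pd.DataFrame({"sample_id": ["a", "b"], "depth_m": [2.0, 4.0], "age_ma": [99.0, np.nan]})
    out = assign_ages(df, am)
    assert out.loc[0, "age_ma"] == 99.0  # pre-existing age kept
    assert out.loc[1, "age_ma"] == pytest.approx(4.0)


# ----- IAR ------------------------------------------------------------------


def test_compute_iar_arithmetic():
    assert compute_iar(10, 1.0, 0.1) == pytest.approx(100.0)
    assert compute_iar(0, 3.0, 0.5) == 0.0


def test_compute_iar_rejects_degenerate_sample():
    with pytest.raises(ValueError):
        compute_iar(5, 0.0, 0.1)
    with pytest.raises(ValueError):
        compute_iar(5, 1.0, 0.0)


def test_iar_pooling_is_duration_weighted_mean(rng):
    """IAR of pooled adjacent samples equals the duration-weighted mean of parts."""
    counts = rng.integers(0, 200, 5)
    durations = rng.uniform(0.05, 0.5, 5)
    area = 4.0
    parts = compute_iar(counts, area, durations)
    pooled = compute_iar(counts.sum(), area, durations.sum())
    weighted = np.sum(parts * durations) / durations.sum()
    assert pooled == pytest.approx(weighted, rel=1e-12)


# ----- binning --------------------------------------------------------------


def _series(ages, values):
    return pd.DataFrame({"age_ma": ages, "iar": values})


def test_bin_counts_match_window_and_width(rng):
    ages = rng.uniform(46, 62, 300)
    df = _series(ages, np.ones_like(ages))
    assert len(bin_series(df, width=1.0)) == 16
    assert len(bin_series(df, width=0.5)) == 32


def test_binning_is_a_partition(rng):
    """Every in-window point lands in exactly one bin (boundaries included once)."""
    ages = np.concatenate([rng.uniform(46, 62, 500), [46.0, 62.0, 49.5, 50.0]])
    df = _series(ages, np.ones_like(ages))
    out = bin_series(df, width=0.5)
    assert out["n"].sum() == len(ages)


def test_bin_width_must_divide_window():
    with pytest.raises(ValueError):
        bin_series(_series([50.0], [1.0]), width=0.7)


def test_empty_bins_are_flagged():
    out = bin_series(_series([46.2, 46.4], [1.0, 2.0]), width=1.0)
    assert (out["n"] == 0).sum() == 15
    assert out.loc[out["n"] > 0, "mean"].iloc[0] == pytest.approx(1.5)


def test_uniform_data_bin_means_near_global_mean(rng):
    """Monte-Carlo: per-bin means of homogeneous data scatter around the grand mean."""
    ages = rng.uniform(46, 62, 4000)
    vals = rng.normal(10.0, 1.0, ages.size)
    out = bin_series(_series(ages, vals), width=1.0)
    se = 1.0 / np.sqrt(out["n"])
    assert np.all(np.abs(out["mean"] - vals.mean()) < 5 * se)


# ----- smoothed densities ---------------------------------------------------


def test_smoothed_density_integral_matches_total(rng):
    axis = ToothAxis()
    lengths = rng.uniform(120, 900, 50)
    d = smooth_tooth_density(lengths, axis, total=2.7)
    assert d.integral() == pytest.approx(2.7, abs=1e-9)


def test_single_measurement_is_the_kernel_and_concentrates_as_bandwidth_shrinks():
    axis = ToothAxis.logarithmic(106, 2000, 256)
    d = smooth_tooth_density(np.array([300.0]), axis, bandwidth=1e-3, total=1.0)
    mass = d.density * axis.widths
    k = np.abs(axis.bin_centers - 300.0).argmin()
    assert mass[max(0, k - 2) : k + 3].sum() > 0.99


def test_smoothed_density_mean_approaches_sample_mean():
    """With a shrinking kernel the density's log-mean converges to the data's."""
    axis = ToothAxis.logarithmic(106, 2000, 512)
    rng = np.random.default_rng(7)
    lengths = rng.uniform(150, 600, 40)
    target = np.log10(lengths).mean()
    errs = []
    for h in (0.05, 0.02, 0.005):
        d = smooth_tooth_density(lengths, axis, bandwidth=h, total=1.0)
        mean = np.sum(np.log10(axis.bin_centers) * d.density * axis.widths)
        errs.append(abs(mean - target))
    assert errs[-1] < 1e-3
    assert errs[2] <= errs[0]


def test_smooth_density_requires_measurements():
    with pytest.raises(ValueError):
        smooth_tooth_density(np.array([]), ToothAxis())


# ----- intra-bin SD and size filter -----------------------------------------


def test_intra_bin_sd_two_point_hand_value():
    binned = pd.DataFrame({"mean": [100.0], "sd": [np.std([90.0, 110.0], ddof=1)], "n": [2]})
    pct, avg = intra_bin_sd(binned)
    assert avg == pytest.approx(14.142, abs=0.01)


def test_intra_bin_sd_identical_values_is_zero():
    binned = pd.DataFrame({"mean": [5.0], "sd": [0.0], "n": [3]})
    _, avg = intra_bin_sd(binned)
    assert avg == 0.0


def test_intra_bin_sd_requires_replicated_bins():
    binned = pd.DataFrame({"mean": [5.0, 6.0], "sd": [np.nan, np.nan], "n": [1, 1]})
    with pytest.raises(ValueError):
        intra_bin_sd(binned)


def test_size_filter_drops_small_teeth():
    df = pd.DataFrame({"sample_id": ["s"] * 4, "length_um": [50.0, 105.9, 106.0, 300.0]})
    out = apply_size_filter(df)
    assert out["length_um"].tolist() == [106.0, 300.0]


# ----- readers --------------------------------------------------------------


def test_readers_validate_schema(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("foo,bar\n1,2\n")
    with pytest.raises(ValueError, match="missing required column"):
        read_measurements(p)
    with pytest.raises(ValueError, match="missing required column"):
        read_temperature(p)


def test_measurements_reject_nonpositive_lengths(tmp_path):
    p = tmp_path / "m.csv"
    p.write_text("sample_id,depth_m,length_um\ns1,0.5,-3\n")
    with pytest.raises(ValueError, match="length_um"):
        read_measurements(p)
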