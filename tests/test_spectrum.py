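"""Forward-model tests: allometry, diet kernel, propagation, tooth prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ichthyospec import (
    AllometricModel,
    SizeGrid,
    ToothAxis,
    body_to_tooth,
    make_diet_matrix,
    predict_tooth_density,
    primary_production_distribution,
    propagate,
    tooth_to_body,
)
from ichthyospec.simulate import DEFAULT_THETA


# ----- allometry ------------------------------------------------------------


@pytest.mark.parametrize(
    "x, a, b, expected",
    [
        (1.0, 0.095, 0.80, 0.095),  # x**b = 1 at the unit point
        (7.3, 1.0, 1.0, 7.3),  # identity allometry
        (2.0, 0.095, 0.80, np.exp(np.log(0.095) + 0.80 * np.log(2.0))),  # log-space oracle
    ],
)
def test_tooth_to_body_known_values(x, a, b, expected):
    assert tooth_to_body(x, AllometricModel(a, b)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "y, a, b, expected",
    [
        (0.095, 0.095, 0.80, 1.0),  # inverse at the unit point
        (9.0, 1.0, 2.0, 3.0),  # closed form sqrt
    ],
)
def test_body_to_tooth_known_values(y, a, b, expected):
    assert body_to_tooth(y, AllometricModel(a, b)) == pytest.approx(expected, rel=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    x=st.floats(1e-3, 1e6),
    a=st.floats(1e-8, 1e3),
    b=st.floats(0.2, 3.0),
)
def test_allometry_round_trip(x, a, b):
    allo = AllometricModel(a, b)
    assert body_to_tooth(tooth_to_body(x, allo), allo) == pytest.approx(x, rel=1e-10)


def test_allometry_rejects_nonpositive_inputs():
    allo = AllometricModel(0.1, 0.8)
    with pytest.raises(ValueError):
        tooth_to_body(0.0, allo)
    with pytest.raises(ValueError):
        body_to_tooth(-1.0, allo)
    with pytest.raises(ValueError):
        AllometricModel(-1.0, 0.8)


def test_tooth_to_body_strictly_increasing():
    allo = AllometricModel(0.095, 0.80)
    x = np.linspace(1, 1000, 500)
    assert np.all(np.diff(tooth_to_body(x, allo)) > 0)


# ----- diet kernel ----------------------------------------------------------


@pytest.mark.parametrize("phi,sigma", [(0.096, 0.236), (0.01, 1.5), (0.4, 0.05)])
def test_diet_rows_sum_to_one(small_grid, phi, sigma):
    diet = make_diet_matrix(small_grid, phi, sigma)
    assert np.all(diet.proportions >= 0)
    np.testing.assert_allclose(diet.proportions.sum(axis=1), 1.0, atol=1e-12)


def test_diet_row_argmax_matches_bruteforce_scan(small_grid):
    """Each predator's modal prey bin is the bin nearest phi times its size."""
    centers = small_grid.bin_centers
    for phi, sigma in [(0.096, 0.236), (0.05, 0.4), (0.3, 0.1)]:
        diet = make_diet_matrix(small_grid, phi, sigma)
        for i in range(small_grid.n_bins):
            brute = min(
                range(small_grid.n_bins),
                key=lambda j: abs(np.log10(centers[j]) - np.log10(phi * centers[i])),
            )
            assert diet.proportions[i].argmax() == brute


def test_diet_small_sigma_degenerates_to_one_hot(small_grid):
    diet = make_diet_matrix(small_grid, 0.1, 1e-4)
    rows = diet.proportions
    assert np.all(rows.max(axis=1) > 1.0 - 1e-12)
    np.testing.assert_allclose(rows.sum(axis=1), 1.0, atol=1e-12)


def test_diet_rejects_invalid_parameters(small_grid):
    with pytest.raises(ValueError):
        make_diet_matrix(small_grid, 1.5, 0.2)
    with pytest.raises(ValueError):
        make_diet_matrix(small_grid, 0.1, 0.0)


# ----- primary production ---------------------------------------------------


def test_primary_production_peaks_near_mean(default_config):
    grid = default_config.grid
    p1 = primary_production_distribution(grid, 50.01, 5.02, total=1.0)
    centers_um = grid.bin_centers * 1e6
    assert p1.argmax() == np.abs(centers_um - 50.01).argmin()
    assert p1.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(p1 >= 0)


def test_primary_production_scales_linearly_with_total(default_config):
    grid = default_config.grid
    p1 = primary_production_distribution(grid, 50.0, 5.0, total=1.0)
    p2 = primary_production_distribution(grid, 50.0, 5.0, total=2.0)
    np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-12)


def test_primary_production_warns_outside_grid(small_grid):
    with pytest.warns(UserWarning, match="outside the grid span"):
        primary_production_distribution(small_grid, 1e9, 5.0)


# ----- propagation ----------------------------------------------------------


def test_propagate_alpha_zero_gives_empty_upper_levels(small_grid):
    diet = make_diet_matrix(small_grid, 0.1, 0.3)
    p1 = primary_production_distribution(small_grid, 50.0, 5.0, total=10.0)
    sol = propagate(p1, diet, 0.0, grid=small_grid)
    assert np.all(sol.productivity[:, 1:] == 0.0)
    np.testing.assert_allclose(sol.productivity[:, 0], p1)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    alpha=st.floats(0.01, 0.9),
    phi=st.floats(0.001, 0.5),
    sigma=st.floats(0.01, 2.0),
    log_p_mu=st.floats(0.0, np.log10(500.0)),
    log_p_sigma=st.floats(np.log10(0.5), 2.0),
)
def test_mass_flow_law(alpha, phi, sigma, log_p_mu, log_p_sigma):
    """Level totals follow alpha**(l-1) exactly, for any valid parameters."""
    grid = SizeGrid.logarithmic(n_bins=60)
    diet = make_diet_matrix(grid, phi, sigma)
    p1 = primary_production_distribution(grid, 10.0**log_p_mu, 10.0**log_p_sigma, total=3.7)
    sol = propagate(p1, diet, alpha, grid=grid)
    totals = sol.level_totals()
    expected = totals[0] * alpha ** np.arange(5)
    np.testing.assert_allclose(totals, expected, rtol=1e-10)
    assert np.all(np.isfinite(sol.productivity))
    assert np.all(sol.productivity >= 0)


def _brute_force_propagate(p1, proportions, alpha, n_levels=5):
    """Independent nested-loop implementation of the prey-partitioned transfer."""
    N = len(p1)
    col = [sum(proportions[i][j] for i in range(N)) for j in range(N)]
    P = np.zeros((N, n_levels))
    P[:, 0] = p1
    for l in range(1, n_levels):
        for i in range(N):
            acc = 0.0
            for j in range(N):
                acc += (proportions[i][j] / col[j]) * P[j, l - 1]
            P[i, l] = alpha * acc
    return P


@pytest.mark.parametrize("n_bins,phi,sigma,alpha", [(12, 0.1, 0.3, 0.1), (20, 0.096, 0.236, 0.15), (30, 0.05, 0.8, 0.3)])
def test_propagate_matches_bruteforce_triple_loop(n_bins, phi, sigma, alpha):
    grid = SizeGrid.logarithmic(n_bins=n_bins)
    diet = make_diet_matrix(grid, phi, sigma)
    p1 = primary_production_distribution(grid, 50.0, 20.0, total=1.0)
    sol = propagate(p1, diet, alpha, grid=grid)
    brute = _brute_force_propagate(p1, diet.proportions, alpha)
    np.testing.assert_allclose(sol.productivity, brute, rtol=1e-12, atol=1e-12 * brute.max())


def test_propagate_rejects_negative_input(small_grid):
    diet = make_diet_matrix(small_grid, 0.1, 0.3)
    with pytest.raises(ValueError):
        propagate(-np.ones(small_grid.n_bins), diet, 0.1)


# ----- tooth-density prediction ---------------------------------------------


def test_predicted_density_nonnegative_and_total_consistent(theta_true, default_config, tooth_axis):
    pred = predict_tooth_density(theta_true, default_config.grid, tooth_axis)
    assert np.all(pred.density >= 0)
    assert tooth_axis.integrate(pred.density) == pytest.approx(pred.total, rel=1e-12)


def test_reference_normalization_gives_unit_total(theta_true, default_config, tooth_axis):
    raw = predict_tooth_density(theta_true, default_config.grid, tooth_axis)
    normed = predict_tooth_density(theta_true, default_config.grid, tooth_axis, scale=1.0 / raw.total)
    assert normed.total == pytest.approx(1.0, abs=1e-9)


def test_alpha_and_pp_scale_total_but_not_shape(theta_true, default_config, tooth_axis):
    """Energy-flow parameters move the height of the distribution only."""
    grid = default_config.grid
    base = predict_tooth_density(theta_true, grid, tooth_axis)
    up_alpha = predict_tooth_density(theta_true.replace(alpha=0.11), grid, tooth_axis)
    up_pp = predict_tooth_density(theta_true, grid, tooth_axis, pp_multiplier=3.0)
    assert up_alpha.total == pytest.approx(base.total * 1.1**4, rel=1e-10)
    assert up_pp.total == pytest.approx(base.total * 3.0, rel=1e-10)
    for other in (up_alpha, up_pp):
        np.testing.assert_allclose(other.normalized_shape(), base.normalized_shape(), atol=1e-10)


def test_phi_shifts_density_mean_monotonically(theta_true, default_config, tooth_axis):
    """Larger preferred-prey fractions compress the food chain to smaller teeth."""
    x = tooth_axis.bin_centers
    w = tooth_axis.widths
    means = []
    for phi in (0.07, 0.09, 0.11, 0.13):
        pred = predict_tooth_density(theta_true.replace(phi=phi), default_config.grid, tooth_axis)
        means.append(np.sum(np.log10(x) * pred.density * w) / pred.total)
    assert np.all(np.diff(means) < 0)


def test_sigma_broadens_density_monotonically(theta_true, default_config, tooth_axis):
    x = tooth_axis.bin_centers
    w = tooth_axis.widths
    spreads = []
    for sigma in (0.15, 0.20, 0.25, 0.30):
        pred = predict_tooth_density(theta_true.replace(sigma=sigma), default_config.grid, tooth_axis)
        u = np.log10(x)
        m = np.sum(u * pred.density * w) / pred.total
        spreads.append(np.sum((u - m) ** 2 * pred.density * w) / pred.total)
    assert np.all(np.diff(spreads) > 0)


def test_predict_errors_when_allometry_misses_axis(theta_true, default_config, tooth_axis):
    bad = theta_true.replace(a=1e2)  # all body sizes map to sub-micron teeth
    with pytest.raises(ValueError, match="allometry"):
        predict_tooth_density(bad, default_config.grid, tooth_axis)


def test_default_params_are_paperlike(theta_true):
    # sanity on the fixture itself: valid invariants
    assert 0 < theta_true.alpha < 1 and 0 < theta_true.phi < 1
    assert theta_true.sigma > 0 and theta_true.p_mu > 0 and theta_true.p_sigma > 0
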