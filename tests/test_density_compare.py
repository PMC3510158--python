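"""Permutation test of density equality, ISD statistic and reference band."""

import math

import numpy as np
import pytest

from lenfreq import (
    isd_statistic,
    kde_evaluate,
    permutation_density_test,
    reference_band,
)


def isd_bruteforce(d1, d2, grid):
    """Trapezoid rule written out by hand."""
    sq = (d1 - d2) ** 2
    total = 0.0
    for i in range(len(grid) - 1):
        total += 0.5 * (sq[i] + sq[i + 1]) * (grid[i + 1] - grid[i])
    return total


def test_isd_zero_symmetry_and_oracle(rng):
    grid = np.linspace(0, 1000, 401)
    f1 = kde_evaluate(rng.normal(300, 50, 80), 20.0, grid)
    f2 = kde_evaluate(rng.normal(420, 60, 120), 20.0, grid)
    assert isd_statistic(f1, f1) == 0.0
    assert isd_statistic(f1, f2) == isd_statistic(f2, f1)
    assert isd_statistic(f1, f2) == pytest.approx(
        isd_bruteforce(f1.density, f2.density, grid), rel=1e-12
    )


def test_isd_requires_matching_grid_and_bandwidth(rng):
    g1 = np.linspace(0, 1000, 401)
    g2 = np.linspace(0, 1000, 201)
    x = rng.normal(300, 50, 50)
    with pytest.raises(ValueError):
        isd_statistic(kde_evaluate(x, 20.0, g1), kde_evaluate(x, 20.0, g2))
    with pytest.raises(ValueError):
        isd_statistic(kde_evaluate(x, 20.0, g1), kde_evaluate(x, 25.0, g1))


def test_isd_disjoint_single_points_closed_form():
    """Two single-point KDEs with no overlap: T = 2 * R(K) / h, the summed
    roughness of two unit-mass Gaussian kernels."""
    h = 10.0
    grid = np.linspace(-200.0, 1200.0, 4001)
    f1 = kde_evaluate([100.0], h, grid)
    f2 = kde_evaluate([900.0], h, grid)
    expected = 2.0 / (2.0 * math.sqrt(math.pi) * h)
    assert isd_statistic(f1, f2) == pytest.approx(expected, rel=1e-6)


def test_identical_samples_give_p_one(rng):
    x = rng.normal(400, 80, 60)
    res = permutation_density_test(x, x.copy(), n_permutations=200, seed=1)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_swap_symmetry(rng):
    """Exchanging the two samples leaves statistic, p and band unchanged."""
    x1 = rng.normal(350, 70, 80)
    x2 = rng.normal(420, 90, 130)
    a = permutation_density_test(x1, x2, n_permutations=300, seed=7)
    b = permutation_density_test(x2, x1, n_permutations=300, seed=7)
    assert a.statistic == b.statistic
    assert a.p_value == b.p_value
    assert a.h_common == b.h_common
    np.testing.assert_array_equal(a.band.lower, b.band.lower)
    np.testing.assert_array_equal(a.band.upper, b.band.upper)


def test_monte_carlo_stability(rng):
    """Two independent permutation streams at 10,000 permutations agree on
    p to better than 0.02."""
    x1 = rng.normal(350, 80, 80)
    x2 = rng.normal(368, 80, 80)  # modest difference => p away from 0 and 1
    p1 = permutation_density_test(x1, x2, n_permutations=10_000, seed=1).p_value
    p2 = permutation_density_test(x1, x2, n_permutations=10_000, seed=2).p_value
    assert abs(p1 - p2) < 0.02


def test_pure_shift_shape_only_p_is_one(rng):
    """x2 = x1 + 200 standardises to the identical sample, so the shape-only
    test returns T = 0 and p = 1 while the raw test rejects."""
    x1 = rng.normal(350, 60, 90)
    x2 = x1 + 200.0
    raw = permutation_density_test(x1, x2, n_permutations=300, seed=3)
    shape = permutation_density_test(
        x1, x2, n_permutations=300, seed=3, standardize_first=True
    )
    assert raw.p_value < 0.05
    assert shape.statistic == pytest.approx(0.0, abs=1e-30)
    assert shape.p_value == 1.0


def test_result_serialises_to_json(rng):
    import json

    x1 = rng.normal(350, 60, 50)
    x2 = rng.normal(380, 60, 50)
    res = permutation_density_test(x1, x2, n_permutations=50, seed=5)
    payload = json.loads(res.to_json())
    assert payload["n_permutations"] == 50
    assert payload["seed"] == 5
    assert 0.0 < payload["p_value"] <= 1.0
    assert payload["h_common"] == pytest.approx(math.sqrt(res.h1 * res.h2))


def test_band_contains_equal_estimates(rng):
    x = rng.normal(400, 70, 100)
    grid = np.linspace(100, 700, 201)
    band = reference_band(x, x, 25.0, grid)
    f = kde_evaluate(x, 25.0, grid).density
    assert np.all(band.lower <= band.mean + 1e-15)
    assert np.all(band.mean <= band.upper + 1e-15)
    assert np.all(band.lower >= 0.0)
    assert np.all(f < band.upper)
    assert np.all(f > band.lower - 1e-30) and np.all((f > band.lower) | (band.lower == 0))


def test_band_width_scales_as_inverse_sqrt_n(rng):
    """On the sqrt-density scale the band half-width is constant in y and
    halves when both samples quadruple."""
    x1 = rng.normal(400, 70, 100)
    x2 = rng.normal(400, 70, 100)
    y1 = rng.normal(400, 70, 400)
    y2 = rng.normal(400, 70, 400)
    grid = np.linspace(150, 650, 101)
    b_small = reference_band(x1, x2, 25.0, grid)
    b_big = reference_band(y1, y2, 25.0, grid)
    w_small = np.sqrt(b_small.upper) - np.sqrt(np.maximum(b_small.lower, 0.0))
    w_big = np.sqrt(b_big.upper) - np.sqrt(np.maximum(b_big.lower, 0.0))
    # constant in y where lower > 0 (away from the clipped tails)
    interior = b_small.lower > 0
    assert np.ptp(w_small[interior]) < 1e-12
    assert w_big[interior][0] == pytest.approx(w_small[interior][0] / 2.0, rel=1e-9)


def test_separated_samples_exit_band_near_own_modes(rng):
    """Samples 3 SD apart: each KDE escapes the null band at its own mode."""
    x1 = rng.normal(300, 50, 150)
    x2 = rng.normal(450, 50, 150)
    h = 20.0
    grid = np.linspace(100, 650, 221)
    band = reference_band(x1, x2, h, grid)
    f1 = kde_evaluate(x1, h, grid).density
    f2 = kde_evaluate(x2, h, grid).density
    assert np.any(f1 > band.upper)
    assert np.any(f2 > band.upper)


def test_rejects_degenerate_inputs(rng):
    x = rng.normal(400, 60, 30)
    with pytest.raises(Exception):
        permutation_density_test(x, [400.0], n_permutations=10, seed=0)
    with pytest.raises(ValueError):
        permutation_density_test(x, x, n_permutations=0, seed=0)
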