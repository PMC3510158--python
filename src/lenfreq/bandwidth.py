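"""Sheather-Jones direct plug-in bandwidth selection for Gaussian-kernel KDE.

The selector implements the two-stage ("level 2") direct plug-in recursion:
a normal-scale estimate of the eighth density functional seeds a pilot
bandwidth for the sixth functional, which in turn seeds a pilot for the
fourth functional; the final bandwidth is the asymptotic MISE-optimal

    h = ( R(K) / (psi4_hat * n) )^(1/5),   R(K) = 1 / (2 sqrt(pi))

for the Gaussian kernel (second kernel moment mu2 = 1).  The scale that
seeds the recursion is the robust min(sample SD, IQR/1.349).

The kernel-derivative double sums are evaluated either exactly (O(n^2)) or,
by default, on a linearly binned grid of 401 cells, the standard fast path
for plug-in selectors; the two routes agree to well under 0.5% relative for
the sample sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .exceptions import InsufficientDataError, InsufficientSpreadError

__all__ = ["BandwidthResult", "sheather_jones_bandwidth", "geometric_mean_bandwidth"]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
# Gaussian kernel derivative values at zero: K^(4)(0) and K^(6)(0)
_K4_0 = 3.0 / _SQRT_2PI
_K6_0 = -15.0 / _SQRT_2PI
# roughness of the Gaussian kernel, integral of K^2
_RK = 1.0 / (2.0 * math.sqrt(math.pi))


@dataclass(frozen=True)
class BandwidthResult:
    """Selected bandwidth ``h`` (same units as the data, mm here), the sample
    size ``n`` it was selected for, and the robust ``scale_estimate`` that
    seeded the plug-in recursion."""

    h: float
    n: int
    scale_estimate: float


def _phi4(u: np.ndarray) -> np.ndarray:
    """Fourth derivative of the standard normal density."""
    u2 = u * u
    return (u2 * u2 - 6.0 * u2 + 3.0) * np.exp(-0.5 * u2) / _SQRT_2PI


def _phi6(u: np.ndarray) -> np.ndarray:
    """Sixth derivative of the standard normal density."""
    u2 = u * u
    return ((u2 - 15.0) * u2 * u2 + 45.0 * u2 - 15.0) * np.exp(-0.5 * u2) / _SQRT_2PI


def _linear_bin_counts(x: np.ndarray, n_bins: int) -> tuple[np.ndarray, float]:
    """Linear binning of ``x`` onto ``n_bins`` equally spaced grid points
    spanning [min(x), max(x)].  Returns (counts, grid spacing)."""
    a, b = float(x.min()), float(x.max())
    delta = (b - a) / (n_bins - 1)
    pos = (x - a) / delta
    lo = np.floor(pos).astype(np.intp)
    lo = np.clip(lo, 0, n_bins - 2)
    frac = pos - lo
    counts = np.zeros(n_bins)
    np.add.at(counts, lo, 1.0 - frac)
    np.add.at(counts, lo + 1, frac)
    return counts, delta


def _functional_binned(counts: np.ndarray, delta: float, g: float, deriv) -> float:
    """Binned n^-2 sum_ij K^(r)((xi-xj)/g); caller divides by g^(r+1)."""
    n_bins = counts.size
    # autocorrelation of the count vector: w[k] = sum_j c_j c_{j+k}
    w = np.correlate(counts, counts, mode="full")[n_bins - 1 :]
    u = np.arange(n_bins) * delta / g
    kvals = deriv(u)
    total = w[0] * kvals[0] + 2.0 * np.dot(w[1:], kvals[1:])
    n = counts.sum()
    return float(total) / (n * n)


def _functional_exact(x: np.ndarray, g: float, deriv) -> float:
    diff = (x[:, None] - x[None, :]) / g
    return float(deriv(diff).sum()) / (x.size * x.size)


def sheather_jones_bandwidth(
    lengths,
    *,
    binned: bool = True,
    n_bins: int = 401,
) -> BandwidthResult:
    """Select a Gaussian-kernel bandwidth by the two-stage direct plug-in rule.

    Parameters
    ----------
    lengths
        Observations (mm).  At least two values with nonzero spread.
    binned
        Evaluate the kernel-derivative double sums on a linearly binned grid
        (fast, default) instead of the exact O(n^2) sums.
    n_bins
        Number of grid cells for the binned evaluation.

    Returns
    -------
    BandwidthResult
        ``h`` on the scale of the data; scale-equivariant by construction.
    """
    x = np.asarray(lengths, dtype=float).ravel()
    n = x.size
    if n < 2:
        raise InsufficientDataError(
            f"bandwidth selection needs at least 2 observations, got {n}"
        )
    sd = float(np.std(x, ddof=1))
    q75, q25 = np.percentile(x, [75.0, 25.0])
    iqr_scale = float(q75 - q25) / 1.349
    candidates = [s for s in (sd, iqr_scale) if s > 0.0]
    if not candidates:
        raise InsufficientSpreadError(
            "sample has zero spread (SD and IQR both zero); cannot select a bandwidth"
        )
    scale = min(candidates)

    # stage 0: normal-scale eighth functional
    psi8 = 105.0 / (32.0 * math.sqrt(math.pi) * scale**9)
    # stage 1: pilot for the sixth functional
    g1 = (-2.0 * _K6_0 / (psi8 * n)) ** (1.0 / 9.0)
    # stage 2: pilot for the fourth functional
    if binned:
        counts, delta = _linear_bin_counts(x, n_bins)
        psi6 = _functional_binned(counts, delta, g1, _phi6) / g1**7
        g2 = (-2.0 * _K4_0 / (psi6 * n)) ** (1.0 / 7.0)
        psi4 = _functional_binned(counts, delta, g2, _phi4) / g2**5
    else:
        psi6 = _functional_exact(x, g1, _phi6) / g1**7
        g2 = (-2.0 * _K4_0 / (psi6 * n)) ** (1.0 / 7.0)
        psi4 = _functional_exact(x, g2, _phi4) / g2**5

    h = (_RK / (psi4 * n)) ** 0.2
    return BandwidthResult(h=float(h), n=n, scale_estimate=scale)


def geometric_mean_bandwidth(h1: float, h2: float) -> float:
    """Geometric mean sqrt(h1*h2) of two per-sample bandwidths.

    Used as the common smoothing for a two-sample density comparison so that
    the larger sample does not dominate the smoothing choice.
    """
    if h1 <= 0.0 or h2 <= 0.0:
        raise ValueError(f"bandwidths must be positive, got {h1} and {h2}")
    return math.sqrt(h1 * h2)
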