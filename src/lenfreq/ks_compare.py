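"""Two-sample Kolmogorov-Smirnov test with a bootstrap (Monte-Carlo)
p-value that remains valid when the data contain ties.

Length data measured to the nearest mm are full of ties, which invalidate
the classical asymptotic null distribution of the KS statistic.  The
bootstrap version draws pseudo-samples WITH replacement from the pooled
data, splits them into groups of the original sizes, and uses the
resampled D* values as the null reference — ties and all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError

__all__ = ["KSComparison", "ks_statistic", "ks_boot"]


@dataclass(frozen=True)
class KSComparison:
    """Bootstrap KS test result: observed D, Monte-Carlo p-value, number of
    bootstrap resamples and the seed used."""

    d_statistic: float
    p_value: float
    n_boots: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "d_statistic": self.d_statistic,
            "p_value": self.p_value,
            "n_boots": self.n_boots,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _ks_from_sorted(xs1: np.ndarray, xs2: np.ndarray) -> float:
    """D for two pre-sorted samples: sup over the pooled values of the
    absolute difference of the right-continuous ECDFs."""
    pooled = np.concatenate([xs1, xs2])
    cdf1 = np.searchsorted(xs1, pooled, side="right") / xs1.size
    cdf2 = np.searchsorted(xs2, pooled, side="right") / xs2.size
    return float(np.abs(cdf1 - cdf2).max())


def ks_statistic(x1, x2) -> float:
    """Maximum absolute difference between the two ECDFs, evaluated at the
    union of observed values; ties are handled exactly."""
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size == 0 or x2.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    return _ks_from_sorted(np.sort(x1), np.sort(x2))


def ks_boot(x1, x2, n_boots: int = 100_000, seed: int | None = None) -> KSComparison:
    """Two-sample KS test with a bootstrap p-value.

    For each of ``n_boots`` iterations, n1+n2 values are drawn with
    replacement from the pooled sample and split into pseudo-groups of sizes
    n1 and n2; the p-value is (1 + #{D* >= D_obs}) / (1 + n_boots), the
    add-one convention so that p is never exactly zero.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size == 0 or x2.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    if n_boots < 1:
        raise ValueError("n_boots must be >= 1")

    d_obs = ks_statistic(x1, x2)
    pooled = np.concatenate([x1, x2])
    n1, n2 = x1.size, x2.size
    n = n1 + n2
    rng = np.random.default_rng(seed)

    count = 0
    for _ in range(n_boots):
        idx = rng.integers(0, n, size=n)
        resample = pooled[idx]
        d_star = _ks_from_sorted(np.sort(resample[:n1]), np.sort(resample[n1:]))
        if d_star >= d_obs:
            count += 1

    p = (1.0 + count) / (1.0 + n_boots)
    return KSComparison(d_statistic=d_obs, p_value=p, n_boots=n_boots, seed=seed)
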