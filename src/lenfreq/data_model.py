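"""Core data types and CSV I/O for length-frequency records.

The on-disk format is a plain UTF-8 CSV with a header row and (by default)
columns ``species``, ``method`` and ``length_mm`` — one row per measured
fish.  Lengths are fork lengths in mm, stored as real numbers even though
field measurement is to the nearest 1 mm: all downstream statistics are
continuous and ties are handled explicitly by the test procedures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bandwidth import sheather_jones_bandwidth
from .exceptions import ConfigurationError, InsufficientDataError, LengthDataError
from .kde import kde_evaluate, kde_mode

__all__ = [
    "LengthSample",
    "SummaryStats",
    "read_length_csv",
    "write_length_csv",
    "summarize",
]

logger = logging.getLogger(__name__)

DEFAULT_SPECIES_COL = "species"
DEFAULT_METHOD_COL = "method"
DEFAULT_LENGTH_COL = "length_mm"


@dataclass(frozen=True)
class LengthSample:
    """Fork-length observations for one species sampled by one method.

    ``lengths`` preserves input order; every value must be finite and
    positive, and both labels non-empty.
    """

    species: str
    method: str
    lengths: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not self.species:
            raise LengthDataError("species label must be non-empty")
        if not self.method:
            raise LengthDataError("method label must be non-empty")
        arr = np.asarray(self.lengths, dtype=float).ravel()
        if arr.size == 0:
            raise LengthDataError(
                f"{self.species}/{self.method}: sample contains no lengths"
            )
        if not np.all(np.isfinite(arr)):
            raise LengthDataError(
                f"{self.species}/{self.method}: lengths must be finite"
            )
        if np.any(arr <= 0.0):
            raise LengthDataError(
                f"{self.species}/{self.method}: lengths must be > 0 mm"
            )
        object.__setattr__(self, "lengths", arr)

    @property
    def n(self) -> int:
        return int(self.lengths.size)


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics for one length sample.

    ``mode_kde`` is the argmax of a Gaussian KDE built with the sample's own
    Sheather-Jones bandwidth, reported on a regular grid (default 1-mm
    spacing, matching the measurement precision).
    """

    mean: float
    sd: float
    mode_kde: float
    count: int
    min: float
    max: float
    bandwidth: float


def read_length_csv(
    path,
    species_col: str = DEFAULT_SPECIES_COL,
    method_col: str = DEFAULT_METHOD_COL,
    length_col: str = DEFAULT_LENGTH_COL,
) -> list[LengthSample]:
    """Read length records from CSV, one LengthSample per (species, method).

    Column names are configurable.  Raises ``ConfigurationError`` for a
    missing column and ``LengthDataError`` (citing the offending CSV row
    number, header = row 1) for non-numeric or non-positive lengths.
    Groups appear in order of first occurrence; rows keep file order within
    each group.
    """
    # round_trip parsing so write->read reproduces doubles exactly
    df = pd.read_csv(
        path, dtype={species_col: str, method_col: str}, float_precision="round_trip"
    )
    for col in (species_col, method_col, length_col):
        if col not in df.columns:
            raise ConfigurationError(
                f"column '{col}' not found in {path}; available: {list(df.columns)}"
            )
    numeric = pd.to_numeric(df[length_col], errors="coerce")
    bad = numeric.isna() | (numeric <= 0.0) | ~np.isfinite(numeric)
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise LengthDataError(
            f"invalid length {df[length_col].iloc[int(bad.idxmax())]!r} "
            f"at row {row} of {path}: lengths must be positive numbers"
        )
    df = df.assign(**{length_col: numeric})

    samples: list[LengthSample] = []
    for (sp, meth), grp in df.groupby([species_col, method_col], sort=False):
        if grp.empty:
            logger.warning("group (%s, %s) is empty; skipped", sp, meth)
            continue
        samples.append(
            LengthSample(species=sp, method=meth, lengths=grp[length_col].to_numpy())
        )
    return samples


def write_length_csv(
    samples,
    path,
    species_col: str = DEFAULT_SPECIES_COL,
    method_col: str = DEFAULT_METHOD_COL,
    length_col: str = DEFAULT_LENGTH_COL,
) -> None:
    """Write LengthSamples back to the same CSV dialect read_length_csv reads;
    a write/read round trip reproduces every length exactly."""
    frames = [
        pd.DataFrame(
            {
                species_col: s.species,
                method_col: s.method,
                length_col: s.lengths,
            }
        )
        for s in samples
    ]
    # %.17g round-trips IEEE doubles exactly
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def summarize(sample: LengthSample, grid_resolution: float = 1.0) -> SummaryStats:
    """Mean, sample SD (n-1), count, min, max and KDE mode for one sample.

    The mode is the argmax of the KDE built with the sample's own
    Sheather-Jones bandwidth h, on a regular grid from (min - 4h) to
    (max + 4h) at ``grid_resolution`` mm spacing; ties resolve to the
    smallest length.
    """
    if sample.n < 2:
        raise InsufficientDataError(
            f"{sample.species}/{sample.method}: need >= 2 lengths, got {sample.n}"
        )
    if grid_resolution <= 0.0:
        raise ValueError("grid_resolution must be > 0")
    x = sample.lengths
    h = sheather_jones_bandwidth(x).h
    # snap the grid to multiples of the resolution so modes land on round mm
    lo = np.floor((x.min() - 4.0 * h) / grid_resolution) * grid_resolution
    hi = np.ceil((x.max() + 4.0 * h) / grid_resolution) * grid_resolution
    grid = np.arange(lo, hi + 0.5 * grid_resolution, grid_resolution)
    est = kde_evaluate(x, h, grid)
    return SummaryStats(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        mode_kde=kde_mode(est),
        count=sample.n,
        min=float(x.min()),
        max=float(x.max()),
        bandwidth=h,
    )
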