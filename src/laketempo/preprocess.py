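"""Quality control, gap infilling, and series preparation.

Annual chlorophyll-a (CHL) records enter the pipeline as fixed-length series
(34 years for the 1985-2018 configuration) that may contain a small number of
missing years.  A record is usable when it has at most five missing years and
no two missing years are adjacent; accepted records are infilled by the
neighbor-mean rule and then prepared along two parallel paths:

* ``z_values`` -- within-lake z-scores (mean 0, SD 1), used by the temporal
  pattern analysis (clustering, anomalies, breakpoints).
* ``edm_values`` -- z-scored, linearly detrended, and re-standardized values,
  used by the empirical-dynamic-modeling and causality analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnualSeries",
    "PreparedSeries",
    "QCResult",
    "qc_filter",
    "infill",
    "prepare",
]

#: Maximum number of missing years an accepted record may contain.
MAX_MISSING = 5

#: Default series length (1985-2018 inclusive).
DEFAULT_N_YEARS = 34


@dataclass
class AnnualSeries:
    """One lake's annual CHL record.

    Missing years are NaN in ``values``; ``missing_mask`` mirrors them.
    """

    lake_id: str
    start_year: int
    values: np.ndarray
    missing_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        self.missing_mask = np.isnan(self.values)

    @property
    def n_years(self) -> int:
        return self.values.size

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)


@dataclass
class PreparedSeries:
    """The two preprocessing paths for one complete series.

    ``degenerate`` flags zero-variance input (or an EDM path that collapses
    to a constant after detrending); degenerate series are excluded from EDM
    and clustering and fall through to the "no pattern" class.
    """

    lake_id: str
    z_values: np.ndarray
    edm_values: np.ndarray
    degenerate: bool = False


@dataclass
class QCResult:
    lake_id: str
    accepted: bool
    reason: str
    n_missing: int


def qc_filter(raw: AnnualSeries, expected_length: int = DEFAULT_N_YEARS) -> QCResult:
    """Accept or reject a raw record.

    Rejection reasons: more than ``MAX_MISSING`` missing years, or any two
    missing years in consecutive positions.
    """
    if raw.n_years != expected_length:
        raise ValueError(
            f"series {raw.lake_id!r} has length {raw.n_years}, "
            f"expected {expected_length}"
        )
    miss = raw.missing_mask
    n_missing = int(miss.sum())
    if n_missing > MAX_MISSING:
        return QCResult(raw.lake_id, False, "too many missing", n_missing)
    if np.any(miss[:-1] & miss[1:]):
        return QCResult(raw.lake_id, False, "consecutive missing", n_missing)
    return QCResult(raw.lake_id, True, "", n_missing)


def infill(raw: AnnualSeries) -> AnnualSeries:
    """Fill missing years: interior gaps take the mean of the two adjacent
    years; a missing first or last year copies its single neighbor.

    Requires nonconsecutive gaps (guaranteed for records passing
    :func:`qc_filter`); consecutive gaps raise ``RuntimeError`` because they
    indicate a record that should have been rejected upstream.
    """
    miss = raw.missing_mask
    if np.any(miss[:-1] & miss[1:]):
        raise RuntimeError(
            f"series {raw.lake_id!r} has consecutive missing years; "
            "it should have been rejected by qc_filter"
        )
    if not miss.any():
        return AnnualSeries(raw.lake_id, raw.start_year, raw.values.copy())
    v = raw.values.copy()
    n = v.size
    for i in np.flatnonzero(miss):
        if i == 0:
            v[i] = v[1]
        elif i == n - 1:
            v[i] = v[n - 2]
        else:
            v[i] = 0.5 * (v[i - 1] + v[i + 1])
    return AnnualSeries(raw.lake_id, raw.start_year, v)


def zscore(x: np.ndarray) -> np.ndarray:
    """z-score with population SD (ddof=0); constant input maps to zeros."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def detrend_linear(x: np.ndarray) -> np.ndarray:
    """Residuals of an OLS fit of ``x`` on the time index."""
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size, dtype=float)
    t = t - t.mean()
    slope = (t @ (x - x.mean())) / (t @ t)
    return x - x.mean() - slope * t


def prepare(series: AnnualSeries) -> PreparedSeries:
    """Compute both preprocessing paths for a complete series.

    The z path is the plain within-lake z-score.  The EDM path is z-scored,
    linearly detrended against the time index, and re-standardized so that
    the S-map locality parameter is comparable across lakes.
    """
    v = series.values
    if np.isnan(v).any():
        raise ValueError(f"series {series.lake_id!r} has missing values; infill first")
    if v.std() == 0:
        return PreparedSeries(series.lake_id, np.zeros_like(v), np.zeros_like(v), True)
    z = zscore(v)
    resid = detrend_linear(z)
    if resid.std() < 1e-12:
        # a perfect linear ramp detrends to a constant
        return PreparedSeries(series.lake_id, z, np.zeros_like(v), True)
    return PreparedSeries(series.lake_id, z, zscore(resid), False)
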