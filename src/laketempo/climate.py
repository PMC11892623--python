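"""Annual climate metrics from monthly climate tables.

Four climate categories (air temperature, precipitation, drought index, ENSO
index) are aggregated over four intra-annual windows, yielding 16 annual
metric series per lake:

* ``water_year`` -- October of the preceding year through September
* ``spring``     -- February through April of the focal year
* ``summer``     -- May through September of the focal year
* ``winter``     -- November-December of the preceding year plus January

Temperature, drought, and ENSO are window means; precipitation is the window
total, matching the conventions of the source products the metrics emulate
(gridded monthly totals for precipitation, standardized indices otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "WINDOWS",
    "METRIC_NAMES",
    "ClimateMetricSet",
    "aggregate_climate",
    "standardize_metrics",
]

CATEGORIES = ("temp", "precip", "drought", "enso")
WINDOWS = ("water_year", "spring", "summer", "winter")
METRIC_NAMES = tuple(f"{c}_{w}" for c in CATEGORIES for w in WINDOWS)

# (year offset relative to the focal year, month) pairs per window
_WINDOW_MONTHS = {
    "water_year": [(-1, m) for m in (10, 11, 12)] + [(0, m) for m in range(1, 10)],
    "spring": [(0, m) for m in (2, 3, 4)],
    "summer": [(0, m) for m in (5, 6, 7, 8, 9)],
    "winter": [(-1, 11), (-1, 12), (0, 1)],
}

# aggregation statistic per category: precipitation accumulates, the rest average
_AGG = {"temp": "mean", "precip": "sum", "drought": "mean", "enso": "mean"}


@dataclass
class ClimateMetricSet:
    """The 16 annual climate metric series for one lake, aligned to its
    CHL years."""

    lake_id: str
    years: np.ndarray
    metrics: dict[str, np.ndarray]
    excluded: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if set(self.metrics) != set(METRIC_NAMES):
            missing = set(METRIC_NAMES) - set(self.metrics)
            extra = set(self.metrics) - set(METRIC_NAMES)
            raise ValueError(f"metric set mismatch: missing={missing} extra={extra}")
        for name, v in self.metrics.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.years.shape:
                raise ValueError(f"metric {name} length {v.size} != {self.years.size}")
            self.metrics[name] = v

    def testable_metrics(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.metrics.items() if k not in self.excluded}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, v in self.metrics.items():
            for y, val in zip(self.years, v):
                rows.append((self.lake_id, int(y), name, float(val)))
        return pd.DataFrame(rows, columns=["lake_id", "year", "metric_name", "value"])


def aggregate_climate(
    monthly: pd.DataFrame,
    years: np.ndarray | range,
    lake_id: str = "",
) -> ClimateMetricSet:
    """Build the 16 annual metric series from a monthly climate table.

    ``monthly`` needs columns year, month, temp, precip, drought, enso and
    must cover every month referenced by the windows (October of the year
    before the first target year onward).  Raises ``ValueError`` naming the
    missing (year, month) pairs if coverage is insufficient.
    """
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise ValueError("empty target year span")
    required_cols = {"year", "month", "temp", "precip", "drought", "enso"}
    if not required_cols.issubset(monthly.columns):
        raise ValueError(f"monthly table missing columns {required_cols - set(monthly.columns)}")

    lookup: dict[tuple[int, int], pd.Series] = {
        (int(r.year), int(r.month)): r for r in monthly.itertuples(index=False)
    }
    missing = [
        (int(y + dy), m)
        for y in years
        for w in WINDOWS
        for (dy, m) in _WINDOW_MONTHS[w]
        if (int(y + dy), m) not in lookup
    ]
    if missing:
        raise ValueError(f"monthly table lacks required months: {sorted(set(missing))}")

    metrics: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        for w in WINDOWS:
            vals = np.empty(years.size)
            for i, y in enumerate(years):
                window = [getattr(lookup[(int(y + dy), m)], cat) for dy, m in _WINDOW_MONTHS[w]]
                vals[i] = np.sum(window) if _AGG[cat] == "sum" else np.mean(window)
            metrics[f"{cat}_{w}"] = vals
    return ClimateMetricSet(lake_id=lake_id, years=years, metrics=metrics)


def standardize_metrics(cms: ClimateMetricSet) -> ClimateMetricSet:
    """z-score each metric series (mean 0, SD 1).

    Zero-variance metrics cannot be standardized; they are left as zeros and
    recorded in ``excluded`` so causality testing skips them.
    """
    out: dict[str, np.ndarray] = {}
    excluded = set(cms.excluded)
    for name, v in cms.metrics.items():
        sd = v.std()
        if sd == 0:
            out[name] = np.zeros_like(v)
            excluded.add(name)
        else:
            out[name] = (v - v.mean()) / sd
    return ClimateMetricSet(cms.lake_id, cms.years.copy(), out, excluded)
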