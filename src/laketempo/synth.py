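"""Synthetic lake/climate ensembles with ground-truth labels.

The generator emulates the statistical structure the analysis assumes:
annual chlorophyll series of length 34 drawn from four dynamical archetypes
-- white noise, AR(1), climate-coupled AR(1) (lag 0 or 1), and
climate-forced nonlinear (logistic-map) dynamics -- with optional planted
level shifts, single-year spikes, and monotonic trends, all in units of the
pre-overlay series SD so that downstream z-score-based detectors see effects
of known size.  Monthly climate tables carry a seasonal temperature cycle
with optional warming trend, non-negative precipitation, an autocorrelated
drought index, and a slow ENSO-like oscillation standardized to mean 0,
SD 1.

Every record carries TruthLabels (dynamics, causal metrics, base temporal
class, event years) for recovery tests; all randomness flows from explicit
seeds and regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate import ClimateMetricSet, aggregate_climate, standardize_metrics

__all__ = [
    "ClimateParams",
    "LakeSpec",
    "TruthLabels",
    "gen_monthly_climate",
    "simulate_lake",
    "gen_ensemble",
    "default_ensemble_config",
    "EnsembleConfig",
]

DYNAMICS = ("noise", "ar1", "ar1_driven", "nonlinear_driven")

#: logistic-map growth rate in the chaotic range, the standard CCM benchmark
LOGISTIC_R = 3.8


@dataclass
class ClimateParams:
    """Monthly climate generator settings (temperature in deg C,
    precipitation in mm/month)."""

    temp_mean: float = 10.0
    temp_seasonal_amp: float = 12.0
    temp_trend: float = 0.0  # deg C per year
    temp_noise_sd: float = 1.5
    precip_mean: float = 70.0
    precip_seasonal_amp: float = 20.0
    precip_noise_sd: float = 25.0
    drought_ar: float = 0.85  # monthly persistence of the drought index
    drought_noise_sd: float = 0.5
    enso_period_years: float = 4.5
    enso_noise_sd: float = 0.3


@dataclass
class LakeSpec:
    """Recipe for one synthetic lake series."""

    lake_id: str
    dynamics: str = "ar1"
    ar_coef: float = 0.5
    coupling: float = 0.0
    coupling_lag: int = 0
    driver_metric: str | None = None
    shift_year: int | None = None  # 1-based; shift applies from shift_year+1 on
    shift_size: float = 0.0  # in pre-overlay SD units
    spike_year: int | None = None  # 1-based
    spike_size: float = 0.0  # in pre-overlay SD units
    trend_slope: float = 0.0  # SD units per year
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dynamics not in DYNAMICS:
            raise ValueError(f"unknown dynamics {self.dynamics!r}")
        if not (-1.0 < self.ar_coef < 1.0):
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.coupling_lag not in (0, 1):
            raise ValueError("coupling_lag must be 0 or 1")
        if self.dynamics == "noise" and self.coupling != 0:
            raise ValueError("noise dynamics require coupling = 0")
        if self.coupling > 0 and self.driver_metric is None:
            raise ValueError("coupling > 0 requires a driver_metric")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class TruthLabels:
    lake_id: str
    true_dynamics: str
    true_causal_metrics: set[str] = field(default_factory=set)
    true_base_class: str = "no_pattern"
    true_event_years: list[int] = field(default_factory=list)


def gen_monthly_climate(
    n_years: int,
    seed: int,
    params: ClimateParams | None = None,
    start_year: int = 1984,
) -> pd.DataFrame:
    """Monthly climate table: one row per (year, month) with columns
    temp, precip, drought, enso.  Deterministic given the seed."""
    if n_years < 3:
        raise ValueError("n_years must be >= 3 (windows reach into the preceding year)")
    p = params or ClimateParams()
    rng = np.random.default_rng(seed)
    n = 12 * n_years
    month = np.tile(np.arange(1, 13), n_years)
    year_idx = np.repeat(np.arange(n_years), 12)
    year = start_year + year_idx

    # coldest in January, warmest in July; trend linear in the year index so
    # the OLS slope of annual means equals temp_trend exactly
    season = -np.cos(2.0 * np.pi * (month - 1) / 12.0)
    temp = (
        p.temp_mean
        + p.temp_seasonal_amp * season
        + p.temp_trend * year_idx
        + (rng.normal(0.0, p.temp_noise_sd, n) if p.temp_noise_sd > 0 else 0.0)
    )

    precip = (
        p.precip_mean
        + p.precip_seasonal_amp * np.sin(2.0 * np.pi * (month - 1) / 12.0)
        + (rng.normal(0.0, p.precip_noise_sd, n) if p.precip_noise_sd > 0 else 0.0)
    )
    precip = np.maximum(precip, 0.0)

    drought = np.zeros(n)
    eps = rng.normal(0.0, p.drought_noise_sd, n) if p.drought_noise_sd > 0 else np.zeros(n)
    for t in range(1, n):
        drought[t] = p.drought_ar * drought[t - 1] + eps[t]

    phase = rng.uniform(0.0, 2.0 * np.pi)
    t_months = np.arange(n)
    enso = np.sin(2.0 * np.pi * t_months / (12.0 * p.enso_period_years) + phase)
    if p.enso_noise_sd > 0:
        enso = enso + rng.normal(0.0, p.enso_noise_sd, n)
    sd = enso.std()
    enso = (enso - enso.mean()) / sd if sd > 0 else np.zeros(n)

    return pd.DataFrame(
        {"year": year, "month": month, "temp": temp, "precip": precip,
         "drought": drought, "enso": enso}
    )


def _driver_01(d: np.ndarray) -> np.ndarray:
    """Min-max map of a driver to [0, 1] for use inside the logistic map."""
    lo, hi = d.min(), d.max()
    if hi - lo < 1e-12:
        return np.full_like(d, 0.5)
    return (d - lo) / (hi - lo)


def simulate_lake(
    spec: LakeSpec,
    drivers: ClimateMetricSet | None = None,
    n_years: int = 34,
    start_year: int = 1985,
):
    """Simulate one lake's annual series from its spec.

    The dynamical core is generated first; trend, level shift, and spike
    overlays are then applied in that order, scaled by the pre-overlay SD so
    their sizes are in SD units.  Returns (AnnualSeries, TruthLabels).

    For coupled dynamics the driver series must cover the lake years; with
    ``coupling_lag=1`` one value before the first year is also needed, which
    is taken from the metric's own first year via the drivers' year span.
    """
    from .preprocess import AnnualSeries  # local import avoids cycle at import time

    rng = np.random.default_rng(spec.seed)
    d = None
    if spec.coupling > 0:
        if drivers is None:
            raise ValueError("coupled dynamics require a ClimateMetricSet")
        if spec.driver_metric not in drivers.metrics:
            raise ValueError(f"unknown driver metric {spec.driver_metric!r}")
        full = np.asarray(drivers.metrics[spec.driver_metric], dtype=float)
        years = drivers.years
        first = int(np.searchsorted(years, start_year))
        need_before = 1 if spec.coupling_lag == 1 else 0
        if first - need_before < 0 or first + n_years > years.size:
            raise ValueError("driver metrics do not cover the requested years")
        sd = full.std()
        full = (full - full.mean()) / sd if sd > 0 else np.zeros_like(full)
        # index i corresponds to year start_year + i; prepend the lag-1 value
        d = full[first - need_before : first + n_years]

    burn = 50
    if spec.dynamics == "noise":
        core = rng.normal(0.0, spec.noise_sd, n_years)
    elif spec.dynamics in ("ar1", "ar1_driven"):
        eps = rng.normal(0.0, spec.noise_sd, burn + n_years)
        x = np.zeros(burn + n_years)
        for t in range(1, burn + n_years):
            forcing = 0.0
            if spec.dynamics == "ar1_driven" and t >= burn:
                # d is offset so that d[i] is the driver value lag years
                # before year i of the series
                forcing = spec.coupling * d[t - burn]
            x[t] = spec.ar_coef * x[t - 1] + forcing + eps[t]
        core = x[burn:]
    else:  # nonlinear_driven: climate-forced logistic map
        d01 = _driver_01(d) if d is not None else None
        x = rng.uniform(0.2, 0.8)
        for _ in range(burn):  # settle onto the attractor, unforced
            x = x * (LOGISTIC_R - LOGISTIC_R * x)
        core = np.empty(n_years)
        for i in range(n_years):
            f = spec.coupling * d01[i] if d01 is not None else 0.0
            x = x * (LOGISTIC_R - LOGISTIC_R * x - f)
            x = min(max(x, 1e-6), 1.0 - 1e-6)
            core[i] = x
        if spec.noise_sd > 0:
            core = core + rng.normal(0.0, spec.noise_sd * core.std() * 0.1, n_years)

    scale = core.std()
    if scale == 0:
        scale = 1.0
    values = core.astype(float).copy()
    t_idx = np.arange(n_years, dtype=float)
    if spec.trend_slope != 0.0:
        values = values + spec.trend_slope * scale * t_idx
    if spec.shift_year is not None:
        if not (1 <= spec.shift_year < n_years):
            raise ValueError("shift_year must lie strictly inside the series")
        values[spec.shift_year :] = values[spec.shift_year :] + spec.shift_size * scale
    if spec.spike_year is not None:
        if not (1 <= spec.spike_year <= n_years):
            raise ValueError("spike_year must lie inside the series")
        values[spec.spike_year - 1] = values[spec.spike_year - 1] + spec.spike_size * scale

    has_shift = spec.shift_year is not None and spec.shift_size != 0
    has_spike = spec.spike_year is not None and spec.spike_size != 0
    if has_shift and has_spike:
        cls = "abrupt_mixed"
    elif has_shift:
        cls = "abrupt_persistent"
    elif has_spike:
        cls = "abrupt_temporary"
    elif spec.trend_slope > 0:
        cls = "monotonic_increasing"
    elif spec.trend_slope < 0:
        cls = "monotonic_decreasing"
    else:
        cls = "no_pattern"
    events = sorted(
        ([spec.shift_year] if has_shift else []) + ([spec.spike_year] if has_spike else [])
    )
    truth = TruthLabels(
        lake_id=spec.lake_id,
        true_dynamics=spec.dynamics,
        true_causal_metrics={spec.driver_metric} if spec.coupling > 0 else set(),
        true_base_class=cls,
        true_event_years=events,
    )
    return AnnualSeries(spec.lake_id, start_year, values), truth


@dataclass
class EnsembleConfig:
    """Counts per archetype plus shared generation settings."""

    counts: dict[str, int]
    n_years: int = 34
    start_year: int = 1985
    climate: ClimateParams = field(default_factory=ClimateParams)
    driver_metric: str = "enso_water_year"


def default_ensemble_config(n_per_archetype: int = 10) -> EnsembleConfig:
    """Six archetypes mirroring the base temporal classes; effect sizes are
    large enough to be unambiguous at 34 years (3.5 SD shift, 4.5 SD spike,
    0.15 SD/yr trend ~ 5 SD over the record)."""
    return EnsembleConfig(
        counts={
            "noise": n_per_archetype,
            "ar1_driven": n_per_archetype,
            "shift": n_per_archetype,
            "spike": n_per_archetype,
            "trend_inc": n_per_archetype,
            "trend_dec": n_per_archetype,
        }
    )


_ARCHETYPES = {
    "noise": dict(dynamics="noise", ar_coef=0.0),
    "ar1": dict(dynamics="ar1", ar_coef=0.5),
    "ar1_driven": dict(dynamics="ar1_driven", ar_coef=0.5, coupling=1.5, noise_sd=0.5),
    "nonlinear_driven": dict(dynamics="nonlinear_driven", ar_coef=0.0, coupling=0.3),
    "shift": dict(dynamics="ar1", ar_coef=0.2, shift_year=17, shift_size=3.5, noise_sd=0.4),
    "spike": dict(dynamics="ar1", ar_coef=0.2, spike_year=28, spike_size=4.5, noise_sd=0.4),
    "trend_inc": dict(dynamics="ar1", ar_coef=0.2, trend_slope=0.15, noise_sd=0.3),
    "trend_dec": dict(dynamics="ar1", ar_coef=0.2, trend_slope=-0.15, noise_sd=0.3),
}


def gen_ensemble(config: EnsembleConfig, seed: int):
    """Generate an ensemble of lakes with per-lake climate.

    Per-lake seeds are spawned deterministically from the master seed, so
    the same (config, seed) pair regenerates byte-identical output.
    Returns (series list, metric-set list, truth list).
    """
    unknown = set(config.counts) - set(_ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    seed_rng = np.random.default_rng(seed)
    series_list, metrics_list, truth_list = [], [], []
    for arch in sorted(config.counts):
        base = _ARCHETYPES[arch]
        for i in range(config.counts[arch]):
            lake_seed = int(seed_rng.integers(0, 2**31 - 1))
            clim_seed = int(seed_rng.integers(0, 2**31 - 1))
            lake_id = f"{arch}_{i:03d}"
            monthly = gen_monthly_climate(
                config.n_years + 2, clim_seed, config.climate,
                start_year=config.start_year - 1,
            )
            cms = aggregate_climate(
                monthly, range(config.start_year, config.start_year + config.n_years),
                lake_id=lake_id,
            )
            kwargs = dict(base)
            if kwargs.get("coupling", 0.0) > 0:
                kwargs["driver_metric"] = config.driver_metric
            spec = LakeSpec(lake_id=lake_id, seed=lake_seed, **kwargs)
            ser, truth = simulate_lake(
                spec, standardize_metrics(cms), n_years=config.n_years,
                start_year=config.start_year,
            )
            series_list.append(ser)
            metrics_list.append(cms)
            truth_list.append(truth)
    return series_list, metrics_list, truth_list


# ---------------------------------------------------------------------------
# CSV writers (long format; the pipeline's on-disk interchange)


def series_to_frame(series_list) -> pd.DataFrame:
    rows = []
    for s in series_list:
        for y, v in zip(s.years, s.values):
            rows.append((s.lake_id, int(y), float(v)))
    return pd.DataFrame(rows, columns=["lake_id", "year", "chl"])


def truth_to_frame(truth_list) -> pd.DataFrame:
    rows = [
        (
            t.lake_id,
            t.true_dynamics,
            ";".join(sorted(t.true_causal_metrics)),
            t.true_base_class,
            ";".join(map(str, t.true_event_years)),
        )
        for t in truth_list
    ]
    return pd.DataFrame(
        rows,
        columns=["lake_id", "true_dynamics", "true_causal_metrics",
                 "true_base_class", "true_event_years"],
    )
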