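"""Pipeline configuration.

All tunable thresholds of the analysis live here with their defaults; a run
records its full configuration (and master seed) in the output manifest so
results are reproducible bit-for-bit.  The significance threshold alpha is
applied uniformly across every stage (predictability, nonlinearity, CCM,
Granger/instantaneous, trend) with no multiple-testing correction, trading a
higher type-I rate for power on short series.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .edm import E_RANGE, THETA_GRID

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    start_year: int = 1985
    n_years: int = 34
    max_missing: int = 5
    alpha: float = 0.05
    e_range: tuple[int, ...] = E_RANGE
    theta_grid: tuple[float, ...] = THETA_GRID
    n_surrogates: int = 1000
    lib_sizes: tuple[int, int] = (20, 500)
    ccm_samples: int = 100
    min_seg_frac: float = 0.15
    anomaly_thresh: float = 1.0
    k_clusters: int = 16
    peak_window: int = 1
    a_classes: tuple[str, ...] = ()  # empty -> two largest abrupt classes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("n_years", "n_surrogates", "ccm_samples", "k_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_seg_frac <= 0 or self.anomaly_thresh <= 0:
            raise ValueError("min_seg_frac and anomaly_thresh must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in raw:
                v = raw[f]
                kwargs[f] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
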