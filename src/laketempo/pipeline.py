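"""End-to-end orchestration: qc -> prepare -> climate -> edm -> causality ->
pattern -> classify -> integrate, with every intermediate table written to
disk and a manifest recording the configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .causality import lake_causality
from .climate import ClimateMetricSet, aggregate_climate, standardize_metrics
from .config import PipelineConfig
from .edm import SeriesDiagnosis, diagnose_series
from .integrate import LakeRecord, assign_response_type, default_a_classes, summarize
from .pattern import base_class, cluster_series, compute_indicators, refine_classes
from .preprocess import AnnualSeries, infill, prepare, qc_filter
from .synth import TruthLabels

log = logging.getLogger("laketempo")

__all__ = ["run_all", "frame_to_series", "frame_to_metricsets"]


def frame_to_series(df: pd.DataFrame) -> list[AnnualSeries]:
    """Long-format (lake_id, year, chl) table -> AnnualSeries list.
    Years absent from a lake's rows become missing values."""
    out = []
    for lake_id, sub in df.groupby("lake_id", sort=True):
        sub = sub.sort_values("year")
        years = sub["year"].to_numpy()
        start, stop = int(years.min()), int(years.max())
        values = np.full(stop - start + 1, np.nan)
        values[years - start] = sub["chl"].to_numpy(dtype=float)
        out.append(AnnualSeries(str(lake_id), start, values))
    return out


def frame_to_metricsets(df: pd.DataFrame) -> dict[str, ClimateMetricSet]:
    """Long-format (lake_id, year, metric_name, value) -> per-lake sets."""
    out: dict[str, ClimateMetricSet] = {}
    for lake_id, sub in df.groupby("lake_id", sort=True):
        years = np.sort(sub["year"].unique())
        metrics = {}
        for name, msub in sub.groupby("metric_name"):
            msub = msub.set_index("year").reindex(years)
            metrics[str(name)] = msub["value"].to_numpy(dtype=float)
        out[str(lake_id)] = ClimateMetricSet(str(lake_id), years, metrics)
    return out


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                r = fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return r

        return wrapper

    return deco


def run_all(
    config: PipelineConfig,
    series_df: pd.DataFrame,
    monthly_df: pd.DataFrame | None,
    out_dir: str | Path,
    metrics_df: pd.DataFrame | None = None,
    truth_df: pd.DataFrame | None = None,
) -> dict:
    """Run the full pipeline and write all stage outputs under ``out_dir``.

    Climate input is either a monthly table (lake_id, year, month, temp,
    precip, drought, enso) to be aggregated here, or an already-built
    annual metric table.  Returns a dict with the in-memory records,
    summaries, and output paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- qc + prepare -----------------------------------------------------
    raw_series = frame_to_series(series_df)
    qc_rows, prepared = [], {}
    for s in raw_series:
        q = qc_filter(s, expected_length=config.n_years)
        qc_rows.append((s.lake_id, q.accepted, q.reason, q.n_missing))
        if q.accepted:
            prepared[s.lake_id] = prepare(infill(s))
    qc_df = pd.DataFrame(qc_rows, columns=["lake_id", "accepted", "reason", "n_infilled"])
    qc_df.to_csv(out / "qc_report.csv", index=False)
    if not prepared:
        raise RuntimeError("pipeline stage 'qc' failed: no series passed QC")

    prep_rows = []
    for lid, p in prepared.items():
        for i, (zv, ev) in enumerate(zip(p.z_values, p.edm_values)):
            prep_rows.append((lid, config.start_year + i, zv, ev, p.degenerate))
    pd.DataFrame(
        prep_rows, columns=["lake_id", "year", "z_value", "edm_value", "degenerate"]
    ).to_csv(out / "prepared.csv", index=False)

    # --- climate ----------------------------------------------------------
    years = range(config.start_year, config.start_year + config.n_years)
    if metrics_df is not None:
        metric_sets = frame_to_metricsets(metrics_df)
    elif monthly_df is not None:
        metric_sets = {}
        if "lake_id" in monthly_df.columns and monthly_df["lake_id"].nunique() > 1:
            for lid, sub in monthly_df.groupby("lake_id"):
                metric_sets[str(lid)] = aggregate_climate(sub, years, lake_id=str(lid))
        else:
            shared = aggregate_climate(monthly_df, years)
            for lid in prepared:
                metric_sets[lid] = ClimateMetricSet(
                    lid, shared.years.copy(), {k: v.copy() for k, v in shared.metrics.items()}
                )
    else:
        raise ValueError("either monthly_df or metrics_df is required")
    metric_sets = {lid: standardize_metrics(m) for lid, m in metric_sets.items()}
    pd.concat([m.to_frame() for m in metric_sets.values()]).to_csv(
        out / "climate_metrics.csv", index=False
    )

    # --- edm diagnosis ----------------------------------------------------
    diagnoses: dict[str, SeriesDiagnosis] = {}
    for lid, p in sorted(prepared.items()):
        if p.degenerate:
            diagnoses[lid] = SeriesDiagnosis(lid, False, np.nan, 1.0, 0, linearity="degenerate")
            continue
        diagnoses[lid] = diagnose_series(
            lid,
            p.edm_values,
            n_surrogates=config.n_surrogates,
            seed=int(rng.integers(0, 2**31 - 1)),
            alpha=config.alpha,
        )
    pd.DataFrame(
        [
            (
                d.lake_id, d.predictable, d.skill_rho, d.skill_p, d.best_E,
                d.delta_mae, d.delta_mae_p, d.linearity,
            )
            for d in diagnoses.values()
        ],
        columns=[
            "lake_id", "predictable", "skill_rho", "skill_p", "best_E",
            "delta_mae", "delta_mae_p", "linearity",
        ],
    ).to_csv(out / "diagnosis.csv", index=False)

    # --- causality ----------------------------------------------------------
    causal_rows, causal_results, climate_causal = [], {}, {}
    for lid, d in sorted(diagnoses.items()):
        results, any_causal = lake_causality(
            d,
            prepared[lid],
            metric_sets[lid],
            lib_sizes=config.lib_sizes,
            n_samples=config.ccm_samples,
            seed=int(rng.integers(0, 2**31 - 1)),
            alpha=config.alpha,
        )
        causal_results[lid], climate_causal[lid] = results, any_causal
        for r in results:
            causal_rows.append(
                (
                    r.lake_id, r.metric_name, r.method, r.causal, r.causal_mode,
                    r.ccm_rho_full, r.ccm_rho_min_lib, r.ccm_rho_max_lib, r.ccm_p,
                    r.granger_p, r.instantaneous_p,
                )
            )
    pd.DataFrame(
        causal_rows,
        columns=[
            "lake_id", "metric_name", "method", "causal", "causal_mode",
            "ccm_rho_full", "ccm_rho_min_lib", "ccm_rho_max_lib", "ccm_p",
            "granger_p", "instantaneous_p",
        ],
    ).to_csv(out / "causality.csv", index=False)

    # --- pattern ------------------------------------------------------------
    indicators = {
        lid: compute_indicators(
            lid,
            p.z_values,
            min_seg_frac=config.min_seg_frac,
            anomaly_thresh=config.anomaly_thresh,
            alpha=config.alpha,
        )
        for lid, p in sorted(prepared.items())
    }
    pd.DataFrame(
        [
            (
                i.lake_id,
                ";".join(map(str, i.breakpoint_years)),
                ";".join(map(str, i.anomaly_years)),
                i.mk_S, i.mk_tau, i.mk_p, i.trend, base_class(i),
            )
            for i in indicators.values()
        ],
        columns=[
            "lake_id", "breakpoint_years", "anomaly_years",
            "mk_S", "mk_tau", "mk_p", "trend", "base_class",
        ],
    ).to_csv(out / "indicators.csv", index=False)

    clusterable = [lid for lid, p in sorted(prepared.items()) if not p.degenerate]
    k = min(config.k_clusters, len(clusterable))
    model = cluster_series(
        np.array([prepared[lid].z_values for lid in clusterable]), clusterable, k=k
    )
    lake_class, registry = refine_classes(
        model,
        {lid: prepared[lid].z_values for lid in clusterable},
        peak_window=config.peak_window,
        min_seg_frac=config.min_seg_frac,
        alpha=config.alpha,
    )
    for lid, p in prepared.items():
        if p.degenerate:
            lake_class[lid] = "no_pattern"
    registry.to_csv(out / "class_registry.csv", index=False)
    pd.DataFrame(
        [(lid, model.labels.get(lid, -1), lake_class[lid]) for lid in sorted(prepared)],
        columns=["lake_id", "cluster", "ecological_class"],
    ).to_csv(out / "classes.csv", index=False)

    # --- integrate ------------------------------------------------------------
    truth_by_lake: dict[str, TruthLabels] = {}
    if truth_df is not None:
        for r in truth_df.itertuples(index=False):
            causal_metrics = set(str(r.true_causal_metrics).split(";")) - {"", "nan"}
            events = [
                int(float(v))
                for v in str(r.true_event_years).split(";")
                if v not in ("", "nan")
            ]
            truth_by_lake[str(r.lake_id)] = TruthLabels(
                str(r.lake_id), str(r.true_dynamics), causal_metrics,
                str(r.true_base_class), events,
            )
    records = [
        LakeRecord(
            lake_id=lid,
            diagnosis=diagnoses[lid],
            causal_results=causal_results[lid],
            climate_causal=climate_causal[lid],
            ecological_class=lake_class[lid],
            truth=truth_by_lake.get(lid),
        )
        for lid in sorted(prepared)
    ]
    a_classes = set(config.a_classes) or default_a_classes(records)
    for rec in records:
        rec.response_type = assign_response_type(rec, a_classes)
    pd.DataFrame(
        [
            (
                r.lake_id, r.diagnosis.linearity, r.climate_causal,
                ";".join(sorted(r.causal_metrics)), r.ecological_class,
                r.class_family, r.response_type,
            )
            for r in records
        ],
        columns=[
            "lake_id", "linearity", "climate_causal", "causal_metrics",
            "ecological_class", "class_family", "response_type",
        ],
    ).to_csv(out / "records.csv", index=False)

    summaries = summarize(records)
    for name, table in summaries.items():
        table.to_csv(out / f"summary_{name}.csv")

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_lakes_in": int(series_df["lake_id"].nunique()),
        "n_lakes_accepted": len(prepared),
        "a_classes": sorted(a_classes),
        "stages": [
            "qc_report", "prepared", "climate_metrics", "diagnosis",
            "causality", "indicators", "classes", "records",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {"records": records, "summaries": summaries, "out_dir": str(out)}
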