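"""Join the pattern and process streams and assign climate-response types.

Each lake's diagnosis (predictability, linearity), causal metric set, and
ecological temporal class combine into one of five climate-response types:

* ``A`` -- climate-causal, abrupt class in the configured A-set (climate
  effects likely and observable)
* ``B`` -- climate-causal, other abrupt class (present but variable)
* ``C`` -- climate-causal, nonabrupt class (present but constrained)
* ``D`` -- predictable but no climate metric was causal
* ``E`` -- unpredictable; causality could not be modeled
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .causality import CausalityResult
from .climate import CATEGORIES
from .edm import SeriesDiagnosis
from .synth import TruthLabels

__all__ = ["LakeRecord", "assign_response_type", "summarize"]

_ABRUPT_BASES = {"abrupt_temporary", "abrupt_persistent", "abrupt_mixed"}


def _class_family(label: str) -> str:
    base = label.split("@")[0]
    if base in _ABRUPT_BASES:
        return "abrupt"
    if base == "monotonic_increasing":
        return "trend_inc"
    if base == "monotonic_decreasing":
        return "trend_dec"
    return "no_trend"


@dataclass
class LakeRecord:
    lake_id: str
    diagnosis: SeriesDiagnosis
    causal_results: list[CausalityResult] = field(default_factory=list)
    climate_causal: bool = False
    ecological_class: str = ""
    response_type: str = ""
    truth: TruthLabels | None = None

    @property
    def causal_metrics(self) -> set[str]:
        return {r.metric_name for r in self.causal_results if r.causal}

    @property
    def class_family(self) -> str:
        return _class_family(self.ecological_class)


def assign_response_type(rec: LakeRecord, a_classes: set[str]) -> str:
    """Climate-response type from diagnosis, causality, and class.

    ``a_classes`` is the configured set of abrupt ecological classes whose
    climate-causal members are Type A (the A/B split is data-derived and so
    kept as configuration).
    """
    if rec.diagnosis.linearity in ("unpredictable", "degenerate"):
        return "E"
    if not rec.climate_causal:
        return "D"
    if not rec.ecological_class:
        raise ValueError(f"lake {rec.lake_id!r} lacks an ecological class")
    if rec.class_family == "abrupt":
        return "A" if rec.ecological_class in a_classes else "B"
    return "C"


def default_a_classes(records: list[LakeRecord]) -> set[str]:
    """Default A-set: the two largest abrupt ecological classes."""
    counts: dict[str, int] = {}
    for r in records:
        if _class_family(r.ecological_class) == "abrupt":
            counts[r.ecological_class] = counts.get(r.ecological_class, 0) + 1
    return set(sorted(counts, key=counts.get, reverse=True)[:2])


def summarize(records: list[LakeRecord]) -> dict[str, pd.DataFrame]:
    """Cross-tabulations of statistical properties, causality, and classes.

    Returns a dict of tables: ``properties`` (percent unpredictable /
    linear-stochastic / nonlinear, overall and per class), ``causal_by_class``
    (percent climate-causal per class), ``causal_by_category`` (causal lake
    counts per climate category), ``multi_metric`` (share of causal lakes
    with more than one causal metric), ``response_types`` (lake counts per
    type), and ``sankey`` (predictable -> linearity -> causal counts).
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    for r in records:
        lin = r.diagnosis.linearity
        if lin == "degenerate":
            lin = "unpredictable"
        rows.append(
            {
                "lake_id": r.lake_id,
                "linearity": lin,
                "climate_causal": r.climate_causal,
                "ecological_class": r.ecological_class,
                "response_type": r.response_type,
                "n_causal_metrics": len(r.causal_metrics),
            }
        )
    df = pd.DataFrame(rows)

    def pct_props(sub: pd.DataFrame) -> pd.Series:
        return (
            sub["linearity"].value_counts(normalize=True)
            .reindex(["unpredictable", "linear_stochastic", "nonlinear"], fill_value=0.0)
            * 100.0
        )

    props = pct_props(df).to_frame("overall").T
    per_class = df.groupby("ecological_class", group_keys=False)[df.columns].apply(pct_props)
    properties = pd.concat([props, per_class])

    causal_by_class = (
        df.groupby("ecological_class")["climate_causal"].mean().mul(100.0).to_frame("pct_causal")
    )

    cat_counts = {c: 0 for c in CATEGORIES}
    for r in records:
        cats = {m.split("_")[0] for m in r.causal_metrics}
        for c in cats:
            cat_counts[c] += 1
    causal_by_category = pd.DataFrame(
        {"category": list(cat_counts), "n_causal_lakes": list(cat_counts.values())}
    )

    causal = df[df["climate_causal"]]
    multi = float((causal["n_causal_metrics"] > 1).mean() * 100.0) if len(causal) else 0.0
    multi_metric = pd.DataFrame({"pct_causal_lakes_multi_metric": [multi]})

    response_types = (
        df["response_type"].value_counts().reindex(list("ABCDE"), fill_value=0).to_frame("n_lakes")
    )

    sankey = (
        df.assign(predictable=df["linearity"] != "unpredictable")
        .groupby(["predictable", "linearity", "climate_causal"])
        .size()
        .to_frame("n_lakes")
        .reset_index()
    )

    return {
        "properties": properties,
        "causal_by_class": causal_by_class,
        "causal_by_category": causal_by_category,
        "multi_metric": multi_metric,
        "response_types": response_types,
        "sankey": sankey,
    }
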