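"""Weighted water-quality index (WQI) and unweighted pollution index (PEI).

WQI per site is ``Σ_i W_i · (C_i/S_i · 100)`` with ``W_i = w_i/Σw_i``; PEI
is the weight-free ``Σ_i C_i/S_i``.  Both are ratio-based, so μg/L
concentrations are compared directly against μg/L guideline values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_GUIDELINES, DEFAULT_WEIGHTS, DEFAULT_WQI_BANDS
from .core_data import ConcentrationTable


@dataclass
class IndexStandards:
    """Guideline values S_i (μg/L) and significance weights w_i per metal."""

    guideline_ug_L: dict[str, float]
    weights: dict[str, float]

    def __post_init__(self) -> None:
        for metal, s in self.guideline_ug_L.items():
            if s <= 0:
                raise ValueError(f"guideline for {metal!r} must be > 0, got {s}")
        for metal, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"weight for {metal!r} must be > 0, got {w}")

    @classmethod
    def default(cls) -> "IndexStandards":
        return cls(dict(DEFAULT_GUIDELINES), dict(DEFAULT_WEIGHTS))

    @classmethod
    def from_config(cls, config: Mapping) -> "IndexStandards":
        std = config["standards"]
        return cls(dict(std["guideline_ug_L"]), dict(std["weights"]))


@dataclass
class WqiResult:
    site_ids: list[str]
    relative_weights: dict[str, float]
    ratings: pd.DataFrame       # q_i = C_i/S_i·100, sites × metals
    sub_indices: pd.DataFrame   # SI_i = W_i·q_i, sites × metals
    wqi: pd.Series              # per-site index
    classes: pd.Series          # per-site label
    contributions: pd.Series    # per-metal % of the mean index


@dataclass
class PeiResult:
    site_ids: list[str]
    ratios: pd.DataFrame        # Hc/Hmac, sites × metals
    pei: pd.Series
    classes: pd.Series
    contributions: pd.Series


def relative_weights(weights: Mapping[str, float]) -> dict[str, float]:
    """Normalize raw significance scores to relative weights summing to 1."""
    if not weights:
        raise ValueError("empty weight set")
    items = list(weights.items())
    total = float(sum(w for _, w in items))
    if total <= 0 or any(w <= 0 for _, w in items):
        raise ValueError("all weights must be > 0")
    return {metal: w / total for metal, w in items}


def classify_wqi(value: float) -> str:
    """Five-class banding: <50 excellent, <100 good, <200 poor, ≤300 very
    poor, >300 unfit for drinking (half-open edges so classes partition)."""
    for upper, label in DEFAULT_WQI_BANDS:
        if value < upper:
            return label
    return DEFAULT_WQI_BANDS[-1][1]


def classify_pei(value: float) -> str:
    """Three-class banding: <40 low, [40, 80] medium, >80 high."""
    if value < 40.0:
        return "low"
    if value <= 80.0:
        return "medium"
    return "high"


def _check_coverage(table: ConcentrationTable, available: Mapping, kind: str) -> None:
    missing = [m for m in table.metals if m not in available]
    if missing:
        raise KeyError(f"no {kind} value for metal(s): {', '.join(missing)}")


def wqi(table: ConcentrationTable, standards: IndexStandards) -> WqiResult:
    """Per-site weighted quality index with class labels and metal shares."""
    _check_coverage(table, standards.guideline_ug_L, "guideline")
    _check_coverage(table, standards.weights, "weight")
    rel = relative_weights({m: standards.weights[m] for m in table.metals})

    s_vec = np.array([standards.guideline_ug_L[m] for m in table.metals])
    w_vec = np.array([rel[m] for m in table.metals])
    ratings = table.values / s_vec * 100.0
    sub = ratings * w_vec
    totals = sub.sum(axis=1)

    idx = pd.Index(table.site_ids, name="site_id")
    ratings_df = pd.DataFrame(ratings, index=idx, columns=table.metals)
    sub_df = pd.DataFrame(sub, index=idx, columns=table.metals)
    wqi_s = pd.Series(totals, index=idx, name="wqi")
    classes = wqi_s.map(classify_wqi).rename("class")
    contrib = _mean_contributions(sub_df)
    return WqiResult(list(table.site_ids), rel, ratings_df, sub_df, wqi_s, classes, contrib)


def pei(table: ConcentrationTable, standards: IndexStandards) -> PeiResult:
    """Per-site unweighted pollution index (sum of guideline ratios)."""
    _check_coverage(table, standards.guideline_ug_L, "guideline")
    s_vec = np.array([standards.guideline_ug_L[m] for m in table.metals])
    ratios = table.values / s_vec
    totals = ratios.sum(axis=1)

    idx = pd.Index(table.site_ids, name="site_id")
    ratios_df = pd.DataFrame(ratios, index=idx, columns=table.metals)
    pei_s = pd.Series(totals, index=idx, name="pei")
    classes = pei_s.map(classify_pei).rename("class")
    contrib = _mean_contributions(ratios_df)
    return PeiResult(list(table.site_ids), ratios_df, pei_s, classes, contrib)


def _mean_contributions(sub_terms: pd.DataFrame) -> pd.Series:
    """Metal shares of the mean index: mean sub-term / mean index × 100."""
    col_means = sub_terms.mean(axis=0)
    total = col_means.sum()
    if total == 0:
        return pd.Series(np.nan, index=sub_terms.columns, name="contribution_percent")
    return (col_means / total * 100.0).rename("contribution_percent")


def index_contributions(result: WqiResult | PeiResult) -> pd.Series:
    """Per-metal percent contribution to the mean index (sums to 100)."""
    return result.contributions
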