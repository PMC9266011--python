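"""Attribute per-metal health risks to pollution sources.

Each metal's mean risk (HQ summed over routes, or ILCR) is multiplied by
that metal's per-source contribution fractions; summing over metals gives
the absolute risk attributed to each source, which is then percentaged per
population × risk type.  The residual (unapportioned) share of each metal
feeds an explicit remainder so totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .apportion import SourceContributions
from .health_risk import RiskResult
from .monte_carlo import McRiskSummary


@dataclass
class SourceRiskTable:
    population: str
    risk_type: str                  # "non_carcinogenic" | "carcinogenic"
    absolute: pd.Series             # per source (+ "unapportioned")
    percent: pd.Series              # per source, sums to 100
    per_metal: pd.DataFrame         # metals × sources, absolute attributed risk
    metal_risks: pd.Series          # the input per-metal risks
    total: float


def _metal_risks(risk, risk_type: str) -> pd.Series:
    """Per-metal mean risk values from a deterministic or MC result."""
    if isinstance(risk, RiskResult):
        return risk.hq_total if risk_type == "non_carcinogenic" else risk.ilcr
    if isinstance(risk, McRiskSummary):
        prefix = "HQ_" if risk_type == "non_carcinogenic" else "ILCR_"
        rows = {
            name[len(prefix):]: risk.summary.loc[name, "mean"]
            for name in risk.summary.index
            if name.startswith(prefix)
        }
        return pd.Series(rows, dtype=float)
    if isinstance(risk, Mapping):
        return pd.Series(dict(risk), dtype=float)
    raise TypeError(f"unsupported risk input {type(risk).__name__}")


def apportion_risk(
    risk,
    contribs: SourceContributions,
    risk_type: str = "non_carcinogenic",
    population: str = "population",
) -> SourceRiskTable:
    """Weight per-metal risks by per-metal source shares and aggregate."""
    risks = _metal_risks(risk, risk_type)
    shares = contribs.per_metal_percent
    missing = [m for m in risks.index if m not in shares.index]
    if missing:
        raise KeyError(
            f"no source contributions for metal(s): {', '.join(missing)}"
        )
    sources = contribs.source_names
    sub = shares.loc[list(risks.index), sources] / 100.0

    per_metal = sub.mul(risks, axis=0)                  # metals × sources
    absolute = per_metal.sum(axis=0)
    residual = float(risks.sum() - absolute.sum())      # unapportioned remainder
    absolute_full = pd.concat(
        [absolute, pd.Series({"unapportioned": residual})]
    ).rename("absolute")

    total_apportioned = absolute.sum()
    if total_apportioned > 0:
        percent = (absolute / total_apportioned * 100.0).rename("percent")
    else:
        percent = pd.Series(float("nan"), index=sources, name="percent")

    return SourceRiskTable(
        population=population,
        risk_type=risk_type,
        absolute=absolute_full,
        percent=percent,
        per_metal=per_metal,
        metal_risks=risks,
        total=float(risks.sum()),
    )


@dataclass
class PriorityRanking:
    metals_by_hq: pd.Series        # percent of HI, descending
    metals_by_ilcr: pd.Series      # percent of TCR, descending
    sources_by_risk: pd.Series     # total attributed risk percent, descending


def priority_ranking(
    noncarcinogenic: SourceRiskTable,
    carcinogenic: SourceRiskTable,
) -> PriorityRanking:
    """Rank metals by their share of HI and TCR, and sources by attributed risk."""
    hq = noncarcinogenic.metal_risks
    ilcr = carcinogenic.metal_risks
    hq_pct = (hq / hq.sum() * 100.0).sort_values(ascending=False)
    ilcr_pct = (ilcr / ilcr.sum() * 100.0).sort_values(ascending=False)

    combined = (
        noncarcinogenic.percent.fillna(0.0) + carcinogenic.percent.fillna(0.0)
    ) / 2.0
    return PriorityRanking(
        metals_by_hq=hq_pct.rename("percent_of_hi"),
        metals_by_ilcr=ilcr_pct.rename("percent_of_tcr"),
        sources_by_risk=combined.sort_values(ascending=False).rename("mean_percent"),
    )
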