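"""Deterministic exposure-dose and risk engine (ingestion + dermal routes).

Average daily dose, mg/(kg·day), with Cw in μg/L (the 10⁻³ factor converts
μg/L → mg/L):

    ADD_oral   = (Cw·10⁻³) · IR · EF · ED / (BW · AT)
    ADD_dermal = (Cw·10⁻³) · SA · PC · ET · EF · ED · CF / (BW · AT)

Non-carcinogenic: HQ = ADD/RfD per metal × route, HI = Σ HQ.
Carcinogenic: ILCR = ADD·CSF when ADD·CSF ≤ 0.01, else 1 − exp(−ADD·CSF);
TCR = Σ ILCR.  Carcinogenic doses use the lifetime averaging time,
non-carcinogenic doses the exposure-duration-based one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import config as cfg
from .core_data import ConcentrationTable

ROUTES = ("oral", "dermal")


@dataclass
class ExposureParameters:
    """Exposure factors for one population.

    Units: ir L/day; ef days/year; ed years; bw kg; sa cm²; et h/day;
    cf L/cm³; at_nc / at_ca days; pc cm/h per metal.
    """

    ir: float
    ef: float
    ed: float
    bw: float
    sa: float
    et: float
    at_nc: float
    at_ca: float
    cf: float = 1e-3
    pc: dict[str, float] = field(default_factory=lambda: dict(cfg.DEFAULT_PC))

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "sa", "et", "cf", "at_nc", "at_ca"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exposure parameter {name!r} must be > 0")
        if self.at_ca < self.at_nc:
            raise ValueError("carcinogenic AT must be ≥ non-carcinogenic AT")

    @classmethod
    def for_population(cls, population: str, config: Mapping | None = None) -> "ExposureParameters":
        tree = (config or cfg.default_config())["exposure"]
        if population not in tree:
            raise KeyError(f"unknown population {population!r}")
        block = dict(tree[population])
        pc = block.pop("pc", dict(cfg.DEFAULT_PC))
        return cls(pc=dict(pc), **block)


@dataclass
class ToxicityTable:
    """Reference doses, GI absorption fractions and cancer slope factors."""

    rfd_oral: dict[str, float]
    gi_abs: dict[str, float]
    csf: dict[str, float]
    carcinogens: tuple[str, ...] = cfg.CARCINOGENS

    def __post_init__(self) -> None:
        for metal, v in self.rfd_oral.items():
            if v <= 0:
                raise ValueError(f"RfD for {metal!r} must be > 0")
        for metal, v in self.csf.items():
            if v <= 0:
                raise ValueError(f"CSF for {metal!r} must be > 0")

    @classmethod
    def default(cls) -> "ToxicityTable":
        return cls(
            dict(cfg.DEFAULT_RFD_ORAL), dict(cfg.DEFAULT_GI_ABS), dict(cfg.DEFAULT_CSF)
        )

    @classmethod
    def from_config(cls, config: Mapping) -> "ToxicityTable":
        tox = config["toxicity"]
        return cls(
            dict(tox["rfd_oral"]),
            dict(tox["gi_abs"]),
            dict(tox["csf"]),
            tuple(tox.get("carcinogens", cfg.CARCINOGENS)),
        )

    def rfd(self, metal: str, route: str) -> float:
        """Route-indexed RfD: dermal RfD = oral RfD × GI absorption fraction."""
        if metal not in self.rfd_oral:
            raise KeyError(f"no RfD for metal {metal!r} (route {route})")
        if route == "oral":
            return self.rfd_oral[metal]
        if route == "dermal":
            return self.rfd_oral[metal] * self.gi_abs.get(metal, 1.0)
        raise KeyError(f"unknown route {route!r}")


def add_oral(cw_ug_L, params: ExposureParameters, carcinogenic: bool = False):
    """Ingestion average daily dose, mg/(kg·day); Cw in μg/L (scalar or array)."""
    at = params.at_ca if carcinogenic else params.at_nc
    return (
        np.asarray(cw_ug_L, dtype=float) * 1e-3
        * params.ir * params.ef * params.ed
        / (params.bw * at)
    )


def add_dermal(cw_ug_L, params: ExposureParameters, pc: float, carcinogenic: bool = False):
    """Dermal-contact average daily dose, mg/(kg·day).

    Dimensional bookkeeping: Cw·10⁻³ [mg/L] × SA [cm²] × PC [cm/h] × ET
    [h/day] × CF [L/cm³] → mg/day, divided by BW·AT/(EF·ED) days·kg.
    """
    at = params.at_ca if carcinogenic else params.at_nc
    return (
        np.asarray(cw_ug_L, dtype=float) * 1e-3
        * params.sa * pc * params.et * params.ef * params.ed * params.cf
        / (params.bw * at)
    )


def ilcr_from_dose(add, csf: float):
    """One-hit model: linear for ADD·CSF ≤ 0.01, 1 − exp(−ADD·CSF) above.

    Continuous and monotone across the switch; always ≤ 1.
    """
    r = np.asarray(add, dtype=float) * csf
    out = np.where(r <= 0.01, r, 1.0 - np.exp(-r))
    return out if out.ndim else float(out)


def hazard_index(hqs) -> float:
    """HI as the plain sum of hazard quotients."""
    return float(np.sum(list(hqs.values() if isinstance(hqs, Mapping) else hqs)))


def total_cancer_risk(ilcrs) -> float:
    """TCR as the plain sum of per-metal ILCRs."""
    return float(np.sum(list(ilcrs.values() if isinstance(ilcrs, Mapping) else ilcrs)))


def classify_hi(hi: float) -> str:
    return "severe" if hi > 1.0 else "safe"


def classify_tcr(tcr: float) -> str:
    if tcr > 1e-4:
        return "unacceptable"
    if tcr < 1e-6:
        return "negligible"
    return "acceptable"


@dataclass
class RiskResult:
    """Deterministic risk for one population at one concentration vector."""

    population: str
    add: pd.DataFrame            # metals × routes, non-carcinogenic AT
    hq: pd.DataFrame             # metals × routes
    hq_total: pd.Series          # per metal, summed over routes
    hi: float
    hi_class: str
    add_carcinogenic: pd.Series  # per carcinogen, both routes summed doses applied
    ilcr: pd.Series              # per carcinogen
    tcr: float
    tcr_class: str


def _mean_concentrations(source) -> dict[str, float]:
    if isinstance(source, ConcentrationTable):
        return {m: float(np.mean(source.column(m))) for m in source.metals}
    return {m: float(v) for m, v in dict(source).items()}


def assess(
    source,
    params: ExposureParameters,
    tox: ToxicityTable,
    population: str = "population",
) -> RiskResult:
    """Full deterministic assessment on mean concentrations.

    ``source`` is a :class:`ConcentrationTable` (column means are used) or a
    mapping metal → Cw in μg/L.
    """
    cw = _mean_concentrations(source)
    metals = list(cw)

    add_rows, hq_rows = {}, {}
    for metal in metals:
        if metal not in params.pc:
            raise KeyError(f"no dermal permeability coefficient for {metal!r}")
        a_or = float(add_oral(cw[metal], params))
        a_de = float(add_dermal(cw[metal], params, params.pc[metal]))
        add_rows[metal] = {"oral": a_or, "dermal": a_de}
        hq_rows[metal] = {
            "oral": a_or / tox.rfd(metal, "oral"),
            "dermal": a_de / tox.rfd(metal, "dermal"),
        }
    add_df = pd.DataFrame.from_dict(add_rows, orient="index")[list(ROUTES)]
    hq_df = pd.DataFrame.from_dict(hq_rows, orient="index")[list(ROUTES)]
    hq_total = hq_df.sum(axis=1).rename("hq")
    hi = hazard_index(hq_total.to_dict())

    carcinogens = [m for m in metals if m in tox.carcinogens]
    add_ca, ilcr = {}, {}
    for metal in carcinogens:
        if metal not in tox.csf:
            raise KeyError(f"no cancer slope factor for {metal!r}")
        dose = float(add_oral(cw[metal], params, carcinogenic=True)) + float(
            add_dermal(cw[metal], params, params.pc[metal], carcinogenic=True)
        )
        add_ca[metal] = dose
        ilcr[metal] = ilcr_from_dose(dose, tox.csf[metal])
    tcr = total_cancer_risk(ilcr)

    return RiskResult(
        population=population,
        add=add_df,
        hq=hq_df,
        hq_total=hq_total,
        hi=hi,
        hi_class=classify_hi(hi),
        add_carcinogenic=pd.Series(add_ca, dtype=float),
        ilcr=pd.Series(ilcr, dtype=float),
        tcr=tcr,
        tcr_class=classify_tcr(tcr),
    )


def hazard(source, params: ExposureParameters, tox: ToxicityTable, population: str = "population") -> RiskResult:
    """Non-carcinogenic view of :func:`assess` (HQ/HI populated)."""
    return assess(source, params, tox, population)


def cancer_risk(source, params: ExposureParameters, tox: ToxicityTable, population: str = "population") -> RiskResult:
    """Carcinogenic view of :func:`assess` (ILCR/TCR populated)."""
    return assess(source, params, tox, population)


def assess_per_site(
    table: ConcentrationTable,
    params: ExposureParameters,
    tox: ToxicityTable,
    population: str = "population",
) -> pd.DataFrame:
    """Per-site HI and TCR (rows = sites)."""
    rows = []
    for i, sid in enumerate(table.site_ids):
        cw = {m: table.values[i, j] for j, m in enumerate(table.metals)}
        res = assess(cw, params, tox, population)
        rows.append({"site_id": sid, "hi": res.hi, "tcr": res.tcr})
    return pd.DataFrame(rows).set_index("site_id")
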