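"""Probabilistic risk layer: input distributions, trial sampling, summaries.

Each run draws ``n_trials`` independent vectors of the random inputs (metal
concentrations first, in metal order, then IR, EF, ED, BW — one documented
draw order from a single seeded generator), evaluates the deterministic
dose/risk formulas per draw, and summarizes each output with mean, median,
SD, a confidence interval of the mean (normal approximation), 5th/95th
percentiles and exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import ConcentrationTable
from .health_risk import (
    ExposureParameters,
    ToxicityTable,
    add_dermal,
    add_oral,
    ilcr_from_dose,
)

_FAMILIES = ("point", "lognormal", "normal", "uniform", "triangular")


@dataclass
class DistributionSpec:
    """One random (or degenerate) input.

    Parameters by family: point → value; lognormal → mu, sigma (log scale);
    normal → mean, sd; uniform → low, high; triangular → low, mode, high.
    Optional truncation bounds are applied by rejection (with clipping as a
    guard after 100 rounds).
    """

    family: str
    params: dict[str, float]
    lower: float | None = None
    upper: float | None = None
    gof_ks: float | None = None
    gof_p: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValueError("truncation bounds out of order")
        p = self.params
        if self.family == "normal" and p["sd"] < 0:
            raise ValueError("sd must be ≥ 0")
        if self.family == "lognormal" and p["sigma"] < 0:
            raise ValueError("sigma must be ≥ 0")
        if self.family == "uniform" and p["low"] > p["high"]:
            raise ValueError("uniform bounds out of order")
        if self.family == "triangular" and not (p["low"] <= p["mode"] <= p["high"]):
            raise ValueError("triangular parameters out of order")

    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draw = self._draw(rng, size)
        if self.lower is None and self.upper is None:
            return draw
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        for _ in range(100):
            bad = (draw < lo) | (draw > hi)
            if not bad.any():
                return draw
            draw[bad] = self._draw(rng, int(bad.sum()))
        return np.clip(draw, lo, hi)

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(size, p["value"], dtype=float)
        if self.family == "lognormal":
            if p["sigma"] == 0:
                return np.full(size, np.exp(p["mu"]), dtype=float)
            return rng.lognormal(p["mu"], p["sigma"], size)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        return rng.triangular(p["low"], p["mode"], p["high"], size)

    def mean(self) -> float:
        """Analytic mean of the untruncated distribution."""
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "lognormal":
            return float(np.exp(p["mu"] + p["sigma"] ** 2 / 2.0))
        if self.family == "normal":
            return p["mean"]
        if self.family == "uniform":
            return (p["low"] + p["high"]) / 2.0
        return (p["low"] + p["mode"] + p["high"]) / 3.0


def fit_lognormal(values) -> DistributionSpec:
    """Maximum-likelihood lognormal fit with a KS goodness-of-fit statistic."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.any(x <= 0):
        raise ValueError("lognormal fit requires strictly positive values")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))  # MLE uses the biased sd
    if sigma > 0:
        ks = sps.kstest(x, "lognorm", args=(sigma, 0.0, np.exp(mu)))
        gof_ks, gof_p = float(ks.statistic), float(ks.pvalue)
    else:
        gof_ks = gof_p = None
    return DistributionSpec(
        "lognormal", {"mu": mu, "sigma": sigma}, gof_ks=gof_ks, gof_p=gof_p
    )


def concentration_specs(table: ConcentrationTable) -> dict[str, DistributionSpec]:
    """Fitted lognormal spec per metal column (zeros nudged to the smallest
    positive value in the column, as a censoring guard)."""
    out = {}
    for metal in table.metals:
        x = table.column(metal).copy()
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError(f"column {metal!r} has no positive values")
        x[x <= 0] = positive.min()
        out[metal] = fit_lognormal(x)
    return out


@dataclass
class McConfig:
    n_trials: int = 10000
    seed: int = 0
    confidence: float = 95.0
    random_inputs: tuple[str, ...] = ("cw", "ir", "ef", "ed", "bw")

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be ≥ 1")
        if not (0.0 < self.confidence < 100.0):
            raise ValueError("confidence must be in (0, 100)")


@dataclass
class McRiskSummary:
    population: str
    summary: pd.DataFrame              # quantities × statistics
    exceedance: pd.DataFrame           # standard thresholds
    draws: pd.DataFrame = field(repr=False, default=None)

    def quantity(self, name: str) -> pd.Series:
        return self.summary.loc[name]


def _summarize(draws: np.ndarray, confidence: float) -> dict[str, float]:
    n = draws.size
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1)) if n > 1 else 0.0
    z = sps.norm.ppf(0.5 + confidence / 200.0)
    half = z * sd / np.sqrt(n)
    return {
        "mean": mean,
        "median": float(np.median(draws)),
        "sd": sd,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "p5": float(np.percentile(draws, 5)),
        "p95": float(np.percentile(draws, 95)),
    }


def exposure_specs_from_config(
    params: ExposureParameters,
    mc_tree: Mapping | None = None,
    random_inputs: tuple[str, ...] = ("ir", "ef", "ed", "bw"),
) -> dict[str, DistributionSpec]:
    """Per-parameter distribution specs derived from a population's point
    values and the relative spreads in the config's monte_carlo block."""
    from .config import DEFAULT_MC

    tree = dict((mc_tree or DEFAULT_MC).get("exposure_distributions", {}))
    out = {}
    for name in ("ir", "ef", "ed", "bw"):
        value = getattr(params, name)
        if name not in random_inputs or name not in tree:
            out[name] = DistributionSpec.point(value)
            continue
        d = tree[name]
        if d["family"] == "triangular":
            out[name] = DistributionSpec(
                "triangular",
                {
                    "low": value * d["rel_low"],
                    "mode": value,
                    "high": value * d["rel_high"],
                },
                lower=0.0,
            )
        elif d["family"] == "uniform":
            out[name] = DistributionSpec(
                "uniform",
                {"low": value * d["rel_low"], "high": value * d["rel_high"]},
                lower=0.0,
            )
        elif d["family"] == "normal":
            out[name] = DistributionSpec(
                "normal", {"mean": value, "sd": value * d["rel_sd"]}, lower=0.0
            )
        else:
            out[name] = DistributionSpec.point(value)
    return out


def run_simulation(
    conc_specs: Mapping[str, DistributionSpec],
    params: ExposureParameters,
    tox: ToxicityTable,
    config: McConfig,
    exposure_specs: Mapping[str, DistributionSpec] | None = None,
    population: str = "population",
    keep_draws: bool = True,
) -> McRiskSummary:
    """Monte Carlo evaluation of the dose/risk formulas.

    ``conc_specs`` maps each metal to its concentration distribution (μg/L);
    ``exposure_specs`` optionally randomizes ir/ef/ed/bw (point values from
    ``params`` otherwise).  Metal sets of ``conc_specs`` and the toxicity
    table must be consistent.
    """
    metals = list(conc_specs)
    missing = [m for m in metals if m not in tox.rfd_oral]
    if missing:
        raise ValueError(f"no toxicity data for metal(s): {', '.join(missing)}")
    for m in metals:
        if m not in params.pc:
            raise ValueError(f"no permeability coefficient for metal {m!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_trials

    # documented draw order: Cw per metal (given order), then ir, ef, ed, bw
    cw = {m: conc_specs[m].sample(rng, n) for m in metals}
    exp_specs = dict(exposure_specs or {})
    vecs = {}
    for name in ("ir", "ef", "ed", "bw"):
        spec = exp_specs.get(name)
        if spec is None or name not in config.random_inputs:
            vecs[name] = np.full(n, getattr(params, name))
        else:
            vecs[name] = spec.sample(rng, n)

    draws = {}
    hi = np.zeros(n)
    tcr = np.zeros(n)
    for m in metals:
        hq_m = np.zeros(n)
        for route in ("oral", "dermal"):
            add = _vector_add(cw[m], m, vecs, params, route, carcinogenic=False)
            hq_m += add / tox.rfd(m, route)
        draws[f"HQ_{m}"] = hq_m
        hi += hq_m
        if m in tox.carcinogens:
            if m not in tox.csf:
                raise ValueError(f"no cancer slope factor for {m!r}")
            dose = _vector_add(
                cw[m], m, vecs, params, "oral", carcinogenic=True
            ) + _vector_add(cw[m], m, vecs, params, "dermal", carcinogenic=True)
            ilcr = ilcr_from_dose(dose, tox.csf[m])
            draws[f"ILCR_{m}"] = ilcr
            tcr += ilcr
    draws["HI"] = hi
    draws["TCR"] = tcr

    summary = pd.DataFrame.from_dict(
        {k: _summarize(v, config.confidence) for k, v in draws.items()},
        orient="index",
    )
    summary.index.name = "quantity"

    exceed_rows = {}
    for k, v in draws.items():
        if k.startswith("HQ") or k == "HI":
            exceed_rows[k] = {"threshold": 1.0, "probability": float(np.mean(v > 1.0))}
        else:
            thr = 1e-4 if k == "TCR" else 1e-6
            exceed_rows[k] = {"threshold": thr, "probability": float(np.mean(v > thr))}
    exceedance = pd.DataFrame.from_dict(exceed_rows, orient="index")
    exceedance.index.name = "quantity"

    return McRiskSummary(
        population=population,
        summary=summary,
        exceedance=exceedance,
        draws=pd.DataFrame(draws) if keep_draws else None,
    )


def _vector_add(cw, metal, vecs, params: ExposureParameters, route, carcinogenic):
    """Per-draw ADD with the randomized ir/ef/ed/bw substituted in."""
    p = replace(
        params, ir=1.0, ef=1.0, ed=1.0, bw=1.0
    )  # unit factors; apply vectors manually
    if route == "oral":
        base = add_oral(cw, p, carcinogenic=carcinogenic)
        base = base * vecs["ir"]
    else:
        base = add_dermal(cw, p, params.pc[metal], carcinogenic=carcinogenic)
    return base * vecs["ef"] * vecs["ed"] / vecs["bw"]


def exceedance(draws, threshold: float) -> float:
    """Fraction of draws strictly above ``threshold``."""
    x = np.asarray(draws, dtype=float)
    return float(np.mean(x > threshold))
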