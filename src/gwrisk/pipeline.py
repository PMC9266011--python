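"""End-to-end orchestration: simulate/read → indices → apportionment → risk
→ Monte Carlo → source-risk, with file-based stage outputs and a manifest.

Stages communicate through CSV/YAML files under one output directory, so
each stage is independently rerunnable; the manifest records the config
hash, seeds, package version and every emitted file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import config as cfg
from .apportion import (
    apcs,
    bartlett_sphericity,
    fit_mlr,
    fit_pca_varimax,
    kmo_statistic,
    metal_source_contributions,
    overall_source_contributions,
    pearson_matrix,
)
from .core_data import (
    ConcentrationTable,
    descriptive_stats,
    read_concentration_table,
    write_concentration_table,
)
from .health_risk import ExposureParameters, ToxicityTable, assess
from .monte_carlo import (
    McConfig,
    concentration_specs,
    exposure_specs_from_config,
    run_simulation,
)
from .source_risk import apportion_risk
from .synthetic import generate, three_source_spec, write_truth
from .water_quality import IndexStandards, pei, wqi

log = logging.getLogger("gwrisk")

POPULATIONS = ("adult_male", "adult_female", "child")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    created: str
    stages: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def record(self, stage: str, inputs: list[str], outputs: list[str]) -> None:
        self.stages[stage] = {
            "inputs": [str(p) for p in inputs],
            "outputs": [str(p) for p in outputs],
        }

    def write(self, path) -> None:
        payload = {
            "schema_version": cfg.SCHEMA_VERSION,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "created": self.created,
            "stages": self.stages,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @property
    def output_files(self) -> list[str]:
        return [f for s in self.stages.values() for f in s["outputs"]]


def _hash_config(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _require(config: dict, section: str) -> dict:
    if section not in config or config[section] is None:
        raise PipelineError(f"config is missing required section {section!r}")
    return config[section]


def run_pipeline(config: dict | str | Path, outdir, seed: int = 0) -> RunManifest:
    """Execute every stage and return the run manifest.

    ``config`` is a config tree or a YAML path (overlaid on defaults).
    Deterministic given ``seed`` and the config.
    """
    if not isinstance(config, dict):
        config = cfg.load_config(config)
    for section in ("standards", "toxicity", "exposure", "monte_carlo"):
        _require(config, section)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_hash_config(config),
        seed=seed,
        version=__version__,
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    # --- stage: input table -------------------------------------------------
    stage = "input"
    try:
        input_cfg = config.get("input", {})
        extra_outputs: list = []
        if input_cfg.get("table"):
            table = read_concentration_table(
                input_cfg["table"],
                unit=input_cfg.get("unit", "ug/L"),
                substitution=input_cfg.get("substitution", "half"),
            )
            table_path = str(input_cfg["table"])
            inputs = [table_path]
        else:
            spec = three_source_spec(
                seed=seed,
                noise_cv=input_cfg.get("noise_cv", 0.1),
            )
            table, truth = generate(spec)
            table_path = outdir / "concentrations.csv"
            write_concentration_table(table, table_path)
            truth_path = outdir / "truth.yaml"
            write_truth(truth, truth_path)
            inputs = []
            extra_outputs = [table_path, truth_path]
        stats = descriptive_stats(table)
        stats_path = outdir / "descriptive_stats.csv"
        stats.table.to_csv(stats_path)
        outputs = [stats_path] + (extra_outputs if not inputs else [])
        manifest.record(stage, inputs, outputs)
        log.info("input: %d sites × %d metals", table.n_sites, table.n_metals)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: indices -----------------------------------------------------
    stage = "indices"
    try:
        standards = IndexStandards.from_config(config)
        w = wqi(table, standards)
        p = pei(table, standards)
        wqi_path = outdir / "wqi.csv"
        pei_path = outdir / "pei.csv"
        pd.concat([w.wqi, w.classes], axis=1).to_csv(wqi_path)
        pd.concat([p.pei, p.classes], axis=1).to_csv(pei_path)
        manifest.record(stage, [str(table_path)], [wqi_path, pei_path])
        log.info("indices: mean WQI %.2f, mean PEI %.2f", w.wqi.mean(), p.pei.mean())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: apportionment ----------------------------------------------
    stage = "apportionment"
    try:
        app_cfg = config.get("apportionment", cfg.DEFAULT_APPORTION)
        corr = pearson_matrix(table)
        kmo = kmo_statistic(corr)
        chi2, dof, pval = bartlett_sphericity(corr, table.n_sites)
        model = fit_pca_varimax(table, retention=app_cfg.get("retention", "kaiser"))
        scores = apcs(model, table)
        reg = fit_mlr(scores, table)
        contribs = metal_source_contributions(
            reg, scores, negative_policy=app_cfg.get("negative_policy", "truncate")
        )
        overall = overall_source_contributions(
            contribs,
            aggregation=app_cfg.get("aggregation", "equal"),
            mean_concentrations=pd.Series(
                table.values.mean(axis=0), index=table.metals
            ),
        )
        loadings_path = outdir / "loadings.csv"
        apcs_path = outdir / "apcs.csv"
        contrib_path = outdir / "source_contributions.csv"
        overall_path = outdir / "overall_shares.yaml"
        model.loadings.to_csv(loadings_path)
        scores.scores.to_csv(apcs_path)
        contribs.per_metal_percent.to_csv(contrib_path)
        with open(overall_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "schema_version": cfg.SCHEMA_VERSION,
                    "kmo": float(kmo),
                    "bartlett": {"chi2": float(chi2), "dof": dof, "p": float(pval)},
                    "n_components": model.n_components,
                    "cumulative_percent": float(model.cumulative_percent),
                    "overall_percent": {k: float(v) for k, v in overall.items()},
                },
                fh,
                sort_keys=False,
            )
        manifest.record(
            stage,
            [str(table_path)],
            [loadings_path, apcs_path, contrib_path, overall_path],
        )
        log.info(
            "apportionment: %d components, KMO %.3f, overall %s",
            model.n_components, kmo,
            {k: round(float(v), 1) for k, v in overall.items()},
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: deterministic risk -----------------------------------------
    stage = "risk"
    try:
        tox = ToxicityTable.from_config(config)
        det_results = {}
        rows = []
        for pop in POPULATIONS:
            pars = ExposureParameters.for_population(pop, config)
            res = assess(table, pars, tox, population=pop)
            det_results[pop] = (pars, res)
            for metal in res.hq_total.index:
                rows.append(
                    {
                        "population": pop,
                        "metal": metal,
                        "hq": res.hq_total[metal],
                        "ilcr": res.ilcr.get(metal, float("nan")),
                    }
                )
            rows.append(
                {"population": pop, "metal": "TOTAL", "hq": res.hi, "ilcr": res.tcr}
            )
        risk_path = outdir / "risk_deterministic.csv"
        pd.DataFrame(rows).to_csv(risk_path, index=False)
        manifest.record(stage, [str(table_path)], [risk_path])
        log.info("risk: HI per population %s",
                 {p: round(r.hi, 4) for p, (_, r) in det_results.items()})
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: Monte Carlo -------------------------------------------------
    stage = "monte_carlo"
    try:
        mc_tree = config["monte_carlo"]
        mc_results = {}
        summaries = []
        conc = concentration_specs(table)
        for i, pop in enumerate(POPULATIONS):
            pars, _ = det_results[pop]
            mc_cfg = McConfig(
                n_trials=int(mc_tree.get("n_trials", 10000)),
                seed=seed + i,
                confidence=float(mc_tree.get("confidence", 95.0)),
                random_inputs=tuple(mc_tree.get("random_inputs", ("cw", "ir", "ef", "ed", "bw"))),
            )
            exp_specs = exposure_specs_from_config(pars, mc_tree)
            mc = run_simulation(
                conc, pars, tox, mc_cfg, exposure_specs=exp_specs,
                population=pop, keep_draws=False,
            )
            mc_results[pop] = mc
            s = mc.summary.copy()
            s.insert(0, "population", pop)
            summaries.append(s)
        mc_path = outdir / "mc_summary.csv"
        pd.concat(summaries).to_csv(mc_path)
        manifest.record(stage, [str(table_path)], [mc_path])
        log.info("monte_carlo: %d trials × %d populations",
                 mc_cfg.n_trials, len(POPULATIONS))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: source risk -------------------------------------------------
    stage = "source_risk"
    try:
        rows = []
        for pop in POPULATIONS:
            mc = mc_results[pop]
            for risk_type in ("non_carcinogenic", "carcinogenic"):
                tbl = apportion_risk(mc, contribs, risk_type=risk_type, population=pop)
                for source in tbl.absolute.index:
                    rows.append(
                        {
                            "population": pop,
                            "risk_type": risk_type,
                            "source": source,
                            "absolute": tbl.absolute[source],
                            "percent": tbl.percent.get(source, float("nan")),
                        }
                    )
        sr_path = outdir / "source_risk.csv"
        pd.DataFrame(rows).to_csv(sr_path, index=False)
        manifest.record(stage, [str(mc_path), str(contrib_path)], [sr_path])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.yaml"
    manifest.write(manifest_path)
    log.info("pipeline complete: %d files under %s", len(manifest.output_files), outdir)
    return manifest
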