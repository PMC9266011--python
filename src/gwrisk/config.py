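"""Shipped default configuration and YAML config handling.

Every number here is an overridable default, not a hidden constant: the
CLI and pipeline read a YAML config whose sections mirror this module, and
analysis functions take the resulting objects explicitly.

Guideline values are grade-III groundwater limits (GB/T 14848-2017 style),
weights follow a health-significance scoring convention, and the toxicity /
exposure blocks are USEPA RAGS-consistent literature values.
"""

from __future__ import annotations

import copy

import yaml

SCHEMA_VERSION = 1

#: Grade-III guideline concentrations, μg/L.
DEFAULT_GUIDELINES = {
    "Cr": 50.0,
    "Mn": 100.0,
    "Fe": 300.0,
    "Cu": 1000.0,
    "Zn": 1000.0,
    "Cd": 5.0,
    "Pb": 100.0,
}

#: Integer significance scores w_i used by the weighted index.
DEFAULT_WEIGHTS = {
    "Cr": 5,
    "Mn": 4,
    "Fe": 1,
    "Cu": 2,
    "Zn": 2,
    "Cd": 5,
    "Pb": 5,
}

#: Oral reference doses, mg/(kg·day).
DEFAULT_RFD_ORAL = {
    "Cr": 0.003,
    "Mn": 0.14,
    "Fe": 0.7,
    "Cu": 0.04,
    "Zn": 0.3,
    "Cd": 0.0005,
    "Pb": 0.0014,
}

#: Gastrointestinal absorption fractions; dermal RfD = oral RfD × fraction.
DEFAULT_GI_ABS = {
    "Cr": 0.025,
    "Mn": 0.04,
    "Fe": 1.0,
    "Cu": 1.0,
    "Zn": 1.0,
    "Cd": 0.05,
    "Pb": 1.0,
}

#: Cancer slope factors, (mg/(kg·day))⁻¹, for the carcinogen set.
DEFAULT_CSF = {
    "Cr": 0.5,
    "Cd": 6.1,
    "Pb": 0.0085,
}

CARCINOGENS = ("Cr", "Cd", "Pb")

#: Dermal permeability coefficients, cm/h.
DEFAULT_PC = {
    "Cr": 0.002,
    "Mn": 0.001,
    "Fe": 0.001,
    "Cu": 0.001,
    "Zn": 0.0006,
    "Cd": 0.001,
    "Pb": 0.0001,
}

#: Exposure parameters per population.  AT in days; carcinogenic AT is the
#: 70-year lifetime convention, non-carcinogenic AT = ED × 365.
DEFAULT_EXPOSURE = {
    "adult_male": {
        "ir": 2.0,        # L/day
        "ef": 365.0,      # days/year
        "ed": 30.0,       # years
        "bw": 70.0,       # kg
        "sa": 18000.0,    # cm²
        "et": 0.58,       # h/day
        "cf": 1e-3,       # L/cm³
        "at_nc": 30.0 * 365.0,
        "at_ca": 70.0 * 365.0,
    },
    "adult_female": {
        "ir": 1.8,
        "ef": 365.0,
        "ed": 30.0,
        "bw": 55.0,
        "sa": 16000.0,
        "et": 0.58,
        "cf": 1e-3,
        "at_nc": 30.0 * 365.0,
        "at_ca": 70.0 * 365.0,
    },
    "child": {
        "ir": 1.0,
        "ef": 365.0,
        "ed": 6.0,
        "bw": 15.0,
        "sa": 6600.0,
        "et": 1.0,
        "cf": 1e-3,
        "at_nc": 6.0 * 365.0,
        "at_ca": 70.0 * 365.0,
    },
}

#: Monte Carlo defaults: which exposure inputs are random and their families.
#: Families/parameters are literature-conventional placeholders, replaceable
#: per run; concentrations are fitted lognormals by default.
DEFAULT_MC = {
    "n_trials": 10000,
    "confidence": 95.0,
    "random_inputs": ["cw", "ir", "ef", "ed", "bw"],
    "exposure_distributions": {
        # relative spreads applied around each population's point value
        "ir": {"family": "triangular", "rel_low": 0.5, "rel_high": 1.5},
        "ef": {"family": "triangular", "rel_low": 0.85, "rel_high": 1.0},
        "ed": {"family": "uniform", "rel_low": 0.5, "rel_high": 1.5},
        "bw": {"family": "normal", "rel_sd": 0.15},
    },
}

DEFAULT_APPORTION = {
    "retention": "kaiser",        # "kaiser" (eigenvalue > 1) or integer count
    "negative_policy": "truncate",  # or "absolute"
    "aggregation": "equal",         # or "concentration"
}

DEFAULT_WQI_BANDS = [
    (50.0, "excellent"),
    (100.0, "good"),
    (200.0, "poor"),
    (300.0, "very poor"),
    (float("inf"), "unfit for drinking"),
]

DEFAULT_PEI_BANDS = [
    (40.0, "low"),
    (80.0, "medium"),
    (float("inf"), "high"),
]


def default_config() -> dict:
    """Full default configuration tree (deep copy; mutate freely)."""
    return copy.deepcopy(
        {
            "schema_version": SCHEMA_VERSION,
            "standards": {
                "guideline_ug_L": DEFAULT_GUIDELINES,
                "weights": DEFAULT_WEIGHTS,
            },
            "toxicity": {
                "rfd_oral": DEFAULT_RFD_ORAL,
                "gi_abs": DEFAULT_GI_ABS,
                "csf": DEFAULT_CSF,
                "carcinogens": list(CARCINOGENS),
                "pc": DEFAULT_PC,
            },
            "exposure": DEFAULT_EXPOSURE,
            "monte_carlo": DEFAULT_MC,
            "apportionment": DEFAULT_APPORTION,
        }
    )


def load_config(path) -> dict:
    """Load a YAML config, overlaying it onto the shipped defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    base = default_config()
    _deep_update(base, user)
    return base


def save_config(config: dict, path) -> None:
    config = dict(config)
    config.setdefault("schema_version", SCHEMA_VERSION)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _deep_update(base: dict, overlay: dict) -> dict:
    for key, value in overlay.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base
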