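"""Concentration tables: validated data model, CSV I/O and summary statistics.

The canonical internal concentration unit is μg/L.  Readers accept mg/L and
convert on ingest; every downstream formula documents its own conversion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Fixed reporting order for the seven metals.
METALS: tuple[str, ...] = ("Cr", "Mn", "Fe", "Cu", "Zn", "Cd", "Pb")

SCHEMA_VERSION = 1

_SITE_COLUMNS = {"site_id", "site", "id", "sample", "sample_id"}
_COORD_COLUMNS = {"lat", "lon", "latitude", "longitude", "x", "y"}

_CENSOR_RE = re.compile(r"^\s*<\s*(\S+)\s*$")


class ValidationError(ValueError):
    """Raised when a concentration table violates its invariants."""


@dataclass
class ConcentrationTable:
    """Sites × metals concentration matrix in μg/L.

    Parameters
    ----------
    site_ids
        One identifier per row.
    metals
        Ordered metal names, one per column; must be unique.
    values
        2-D float array, shape ``(n_sites, n_metals)``, all entries ≥ 0.
    censored
        Optional boolean matrix flagging below-detection entries that were
        substituted on ingest.
    """

    site_ids: list[str]
    metals: list[str]
    values: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n_sites, n_metals = self.values.shape
        if len(self.site_ids) != n_sites:
            raise ValidationError(
                f"{len(self.site_ids)} site ids for {n_sites} rows"
            )
        if len(self.metals) != n_metals:
            raise ValidationError(
                f"{len(self.metals)} metal names for {n_metals} columns"
            )
        if len(set(self.metals)) != len(self.metals):
            raise ValidationError("metal names must be unique")
        bad = np.argwhere(np.asarray(self.values) < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"negative concentration at row {self.site_ids[i]!r}, "
                f"column {self.metals[j]!r}: {self.values[i, j]}"
            )
        for j, m in enumerate(self.metals):
            if np.all(np.isnan(self.values[:, j])):
                raise ValidationError(f"column {m!r} is entirely missing")
        if self.censored is not None:
            self.censored = np.asarray(self.censored, dtype=bool)
            if self.censored.shape != self.values.shape:
                raise ValidationError("censored mask shape mismatch")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def n_metals(self) -> int:
        return self.values.shape[1]

    def column(self, metal: str) -> np.ndarray:
        try:
            j = self.metals.index(metal)
        except ValueError:
            raise KeyError(f"metal {metal!r} not in table") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.site_ids, name="site_id"),
            columns=list(self.metals),
        )


def _parse_cell(raw: object, substitution: str) -> tuple[float, bool]:
    """Parse one CSV cell; returns (value μg/L pre-conversion, censored)."""
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        return float(raw), False
    text = str(raw).strip()
    m = _CENSOR_RE.match(text)
    if m:
        dl = float(m.group(1))
        factor = {"zero": 0.0, "half": 0.5, "full": 1.0}[substitution]
        return dl * factor, True
    return float(text), False


def read_concentration_table(
    path,
    unit: str = "ug/L",
    substitution: str = "half",
) -> ConcentrationTable:
    """Read a sites × metals CSV into a validated :class:`ConcentrationTable`.

    The file must carry a header row naming the metals; an optional leading
    ``site_id`` column (or ``site``/``id``/…) supplies row identifiers, and
    coordinate columns (``lat``/``lon``/…) are ignored.  Below-detection
    tokens like ``<0.01`` are substituted according to ``substitution``
    (``zero`` | ``half`` | ``full`` of the stated detection limit) and
    flagged in the censored mask.

    ``unit`` may be ``"ug/L"`` (native) or ``"mg/L"``; mg/L values are
    multiplied by exactly 1000.
    """
    unit_norm = unit.replace("μ", "u").replace("µ", "u").lower()
    if unit_norm not in {"ug/l", "mg/l"}:
        raise ValidationError(f"unsupported unit {unit!r}")
    if substitution not in {"zero", "half", "full"}:
        raise ValidationError(f"unknown substitution policy {substitution!r}")

    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    if df.empty:
        raise ValidationError(f"no data rows in {path}")

    cols = list(df.columns)
    site_col = next((c for c in cols if c.strip().lower() in _SITE_COLUMNS), None)
    metal_cols = [
        c for c in cols
        if c != site_col and c.strip().lower() not in _COORD_COLUMNS
    ]
    if not metal_cols:
        raise ValidationError("no metal columns found in header")

    site_ids = (
        [str(s) for s in df[site_col]]
        if site_col is not None
        else [f"S{i + 1}" for i in range(len(df))]
    )

    values = np.empty((len(df), len(metal_cols)))
    censored = np.zeros_like(values, dtype=bool)
    for j, col in enumerate(metal_cols):
        for i, raw in enumerate(df[col]):
            try:
                v, c = _parse_cell(raw, substitution)
            except (ValueError, TypeError):
                raise ValidationError(
                    f"unparseable cell {raw!r} at row {site_ids[i]!r}, "
                    f"column {col!r}"
                ) from None
            values[i, j] = v
            censored[i, j] = c

    if unit_norm == "mg/l":
        values = values * 1000.0

    return ConcentrationTable(
        site_ids=site_ids,
        metals=[c.strip() for c in metal_cols],
        values=values,
        censored=censored if censored.any() else None,
    )


def write_concentration_table(table: ConcentrationTable, path) -> None:
    """Write a table as RFC-4180 CSV (μg/L) with a schema-version comment."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# schema_version: {SCHEMA_VERSION}\n")
        fh.write("site_id," + ",".join(table.metals) + "\n")
        for i, sid in enumerate(table.site_ids):
            cells = [repr(float(v)) for v in table.values[i]]
            fh.write(str(sid) + "," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Descriptive statistics


@dataclass
class DescriptiveStats:
    """Per-metal summary statistics (μg/L; cv in percent).

    ``skewness``/``kurtosis`` use the adjusted Fisher–Pearson (sample-size
    corrected) estimators, with the excess-kurtosis convention (normal → 0).
    Undefined entries (constant columns) are reported as NaN, never raised.
    """

    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("min", "max", "mean", "sd", "cv_percent", "skewness", "kurtosis")

    def __getitem__(self, metal: str) -> pd.Series:
        return self.table.loc[metal]

    @property
    def metals(self) -> list[str]:
        return list(self.table.index)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation in percent, ``100·sd/mean`` (NaN if mean ≤ 0)."""
    if mean <= 0:
        return float("nan") if sd != 0 else 0.0
    return 100.0 * sd / mean


def max_mean_ratio(maximum: float, mean: float) -> float:
    """Ratio of a column maximum to its mean (NaN when mean is 0)."""
    if mean == 0:
        return float("nan")
    return maximum / mean


def descriptive_stats(table: ConcentrationTable) -> DescriptiveStats:
    """Eight summary statistics per metal (two or more sites required)."""
    if table.n_sites < 2:
        raise ValidationError("descriptive statistics need at least 2 sites")
    rows = {}
    for metal in table.metals:
        x = table.column(metal)
        x = x[~np.isnan(x)]
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            skew = kurt = float("nan")
            cv = 0.0
        else:
            skew = float(sps.skew(x, bias=False))
            kurt = float(sps.kurtosis(x, fisher=True, bias=False))
            cv = cv_percent(mean, sd)
        rows[metal] = {
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "mean": mean,
            "sd": sd,
            "cv_percent": cv,
            "skewness": skew,
            "kurtosis": kurt,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[
        list(DescriptiveStats.COLUMNS)
    ]
    frame.index.name = "metal"
    return DescriptiveStats(table=frame)


def max_mean_ratios(stats: DescriptiveStats) -> pd.Series:
    """Per-metal max/mean ratio from a computed summary."""
    out = {
        m: max_mean_ratio(stats.table.loc[m, "max"], stats.table.loc[m, "mean"])
        for m in stats.metals
    }
    return pd.Series(out, name="max_mean_ratio")
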