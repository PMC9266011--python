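"""Receptor modelling: correlation screening, adequacy tests, varimax-rotated
PCA, absolute principal component scores (APCS) and per-metal regression.

Pipeline: z-score the concentration matrix, eigendecompose its correlation
matrix, retain components (eigenvalue > 1 or a fixed count), varimax-rotate,
score sites with regression-method score coefficients, subtract the score of
an artificial zero-concentration sample to obtain APCS, then regress each
raw concentration on the APCS columns.  Mean ``coef × APCS`` terms give
per-source contributions to each metal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_data import ConcentrationTable


class ApportionmentError(ValueError):
    """Raised for ill-posed receptor-model inputs (singular/degenerate)."""


# ---------------------------------------------------------------------------
# Correlation screening and adequacy tests


@dataclass
class CorrelationSummary:
    r: pd.DataFrame
    p: pd.DataFrame

    @property
    def metals(self) -> list[str]:
        return list(self.r.index)


def pearson_matrix(table: ConcentrationTable) -> CorrelationSummary:
    """Pairwise Pearson r with two-sided t-distribution p-values.

    Constant columns yield NaN in their row/column rather than an error.
    """
    n = table.n_sites
    if n < 3:
        raise ApportionmentError("need at least 3 sites for correlations")
    m = table.n_metals
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    sds = table.values.std(axis=0, ddof=1)
    for i in range(m):
        for j in range(i, m):
            if sds[i] == 0 or sds[j] == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            res = sps.pearsonr(table.values[:, i], table.values[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(table.metals, name="metal")
    return CorrelationSummary(
        r=pd.DataFrame(r, index=idx, columns=table.metals),
        p=pd.DataFrame(p, index=idx, columns=table.metals),
    )


def _corr_array(corr: CorrelationSummary | pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(corr, CorrelationSummary):
        return corr.r.to_numpy()
    if isinstance(corr, pd.DataFrame):
        return corr.to_numpy()
    return np.asarray(corr, dtype=float)


def kmo_statistic(corr) -> float:
    """Kaiser–Meyer–Olkin sampling adequacy.

    ``KMO = Σ_{i≠j} r²_ij / (Σ_{i≠j} r²_ij + Σ_{i≠j} q²_ij)`` where the
    partial correlations ``q_ij = −inv(R)_ij / √(inv(R)_ii · inv(R)_jj)``.
    """
    R = _corr_array(corr)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ApportionmentError("correlation matrix is singular") from None
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(corr, n_sites: int) -> tuple[float, int, float]:
    """Bartlett's sphericity test: χ² = −(n−1−(2m+5)/6)·ln det R, dof m(m−1)/2."""
    R = _corr_array(corr)
    m = R.shape[0]
    if n_sites <= m:
        raise ApportionmentError("need more sites than metals for the test")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ApportionmentError("correlation matrix is not positive definite")
    chi2 = -(n_sites - 1 - (2 * m + 5) / 6.0) * logdet
    dof = m * (m - 1) // 2
    p = float(sps.chi2.sf(chi2, dof))
    return float(chi2), int(dof), p


# ---------------------------------------------------------------------------
# PCA with varimax rotation


@dataclass
class PcaModel:
    metals: list[str]
    n_components: int
    loadings: pd.DataFrame            # rotated, metals × components
    eigenvalues: np.ndarray           # all m eigenvalues, descending
    explained_percent: np.ndarray     # per retained component, post-rotation
    cumulative_percent: float
    score_coefficients: pd.DataFrame  # metals × components (regression method)
    means: np.ndarray                 # per-metal standardization mean
    sds: np.ndarray                   # per-metal standardization sd (ddof=1)
    unrotated_loadings: pd.DataFrame = field(repr=False, default=None)

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)


def varimax(loadings: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Kaiser-normalized varimax rotation.

    Iterates the SVD form of the orthogonal varimax update until the relative
    change in the criterion drops below ``tol``.  Returns (rotated loadings,
    rotation matrix); orthogonality of the rotation preserves per-row
    communalities exactly.
    """
    L = np.asarray(loadings, dtype=float)
    m, k = L.shape
    if k < 2:
        return L.copy(), np.eye(k)
    h = np.sqrt(np.sum(L**2, axis=1))
    h[h == 0] = 1.0
    Ln = L / h[:, None]
    R = np.eye(k)
    prev = 0.0
    for _ in range(max_iter):
        Lr = Ln @ R
        grad = Ln.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / m)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        crit = float(np.sum(s))
        if crit <= prev * (1.0 + tol):
            break
        prev = crit
    rotated = (Ln @ R) * h[:, None]
    return rotated, R


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Make each component's largest-|loading| entry positive (reproducible)."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = np.argmax(np.abs(out[:, j]))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def fit_pca_varimax(
    table: ConcentrationTable,
    retention: str | int = "kaiser",
) -> PcaModel:
    """Varimax-rotated PCA of the z-scored concentration matrix.

    ``retention`` is ``"kaiser"`` (eigenvalue > 1) or an explicit component
    count.  Explained-variance percentages are recomputed from the rotated
    loadings (sum of squared loadings per component / number of metals).
    """
    X = table.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [m for m, s in zip(table.metals, sds) if s == 0]
        raise ApportionmentError(f"constant column(s): {', '.join(bad)}")
    Z = (X - means) / sds

    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    if retention == "kaiser":
        p = int(np.sum(eigvals > 1.0))
    else:
        p = int(retention)
    if p < 1:
        raise ApportionmentError("retention rule kept no components")
    if p > table.n_metals:
        raise ApportionmentError("cannot retain more components than metals")

    unrotated = eigvecs[:, :p] * np.sqrt(np.clip(eigvals[:p], 0, None))
    if p >= 2:
        rotated, _ = varimax(unrotated)
    else:
        rotated = unrotated.copy()
    rotated = _fix_signs(rotated)

    ss = np.sum(rotated**2, axis=0)
    order2 = np.argsort(ss)[::-1]   # keep components in descending variance
    rotated = rotated[:, order2]
    ss = ss[order2]
    explained = ss / table.n_metals * 100.0

    # regression-method factor score coefficients: W = R⁻¹ Λ
    # (pseudo-inverse so rank-deficient R — e.g. duplicated columns — still
    # yields the minimum-norm coefficients)
    W = np.linalg.pinv(R) @ rotated

    names = [f"PC{i + 1}" for i in range(p)]
    idx = pd.Index(table.metals, name="metal")
    return PcaModel(
        metals=list(table.metals),
        n_components=p,
        loadings=pd.DataFrame(rotated, index=idx, columns=names),
        eigenvalues=eigvals,
        explained_percent=explained,
        cumulative_percent=float(np.sum(explained)),
        score_coefficients=pd.DataFrame(W, index=idx, columns=names),
        means=means,
        sds=sds,
        unrotated_loadings=pd.DataFrame(unrotated, index=idx, columns=[f"U{i+1}" for i in range(p)]),
    )


# ---------------------------------------------------------------------------
# APCS and the per-metal regressions


@dataclass
class ApcsMatrix:
    scores: pd.DataFrame       # sites × components
    zero_scores: np.ndarray    # factor scores of the artificial zero sample

    @property
    def component_names(self) -> list[str]:
        return list(self.scores.columns)


def apcs(model: PcaModel, table: ConcentrationTable) -> ApcsMatrix:
    """Absolute principal component scores.

    Factor scores are ``Z · W``; the artificial zero-concentration sample has
    z-scores ``−mean/sd``, and its factor score is subtracted from every
    site's score so that a true-zero sample maps exactly to the origin.
    """
    if list(table.metals) != model.metals:
        raise ApportionmentError("table metals do not match the fitted model")
    Z = (table.values - model.means) / model.sds
    W = model.score_coefficients.to_numpy()
    scores = Z @ W
    z0 = -model.means / model.sds
    zero_scores = z0 @ W
    out = scores - zero_scores
    return ApcsMatrix(
        scores=pd.DataFrame(
            out, index=pd.Index(table.site_ids, name="site_id"),
            columns=model.component_names,
        ),
        zero_scores=zero_scores,
    )


@dataclass
class SourceRegression:
    metals: list[str]
    intercepts: pd.Series              # ξ0 per metal
    coefficients: pd.DataFrame         # metals × components, ξk
    predicted: pd.DataFrame            # sites × metals
    r_squared: pd.Series
    predicted_measured_ratio: pd.Series


def fit_mlr(apcs_matrix: ApcsMatrix, table: ConcentrationTable) -> SourceRegression:
    """Per-metal OLS of raw concentration on the APCS columns."""
    A = apcs_matrix.scores.to_numpy()
    n, p = A.shape
    if table.n_sites != n:
        raise ApportionmentError("site count mismatch between APCS and table")
    if n < p + 2:
        raise ApportionmentError("need at least n_components + 2 sites")
    X = np.column_stack([np.ones(n), A])
    if np.linalg.matrix_rank(X) < p + 1:
        raise ApportionmentError("collinear APCS columns")

    beta, *_ = np.linalg.lstsq(X, table.values, rcond=None)
    pred = X @ beta
    resid = table.values - pred
    sst = np.sum((table.values - table.values.mean(axis=0)) ** 2, axis=0)
    ssr = np.sum(resid**2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sst > 0, 1.0 - ssr / sst, np.nan)
        ratio = np.where(
            table.values.mean(axis=0) != 0,
            pred.mean(axis=0) / table.values.mean(axis=0),
            np.nan,
        )

    midx = pd.Index(table.metals, name="metal")
    return SourceRegression(
        metals=list(table.metals),
        intercepts=pd.Series(beta[0], index=midx, name="intercept"),
        coefficients=pd.DataFrame(
            beta[1:].T, index=midx, columns=apcs_matrix.component_names
        ),
        predicted=pd.DataFrame(
            pred, index=apcs_matrix.scores.index, columns=table.metals
        ),
        r_squared=pd.Series(r2, index=midx, name="r_squared"),
        predicted_measured_ratio=pd.Series(ratio, index=midx, name="pred_meas_ratio"),
    )


@dataclass
class SourceContributions:
    per_metal_percent: pd.DataFrame    # metals × components (+ "residual")
    raw_mean_terms: pd.DataFrame       # signed mean ξk·APCS_k, with intercept
    overall_percent: pd.Series | None = None

    @property
    def source_names(self) -> list[str]:
        return [c for c in self.per_metal_percent.columns if c != "residual"]


def metal_source_contributions(
    reg: SourceRegression,
    apcs_matrix: ApcsMatrix,
    negative_policy: str = "truncate",
) -> SourceContributions:
    """Per-metal percent contribution of each source.

    Source k's raw term for metal n is the site-mean of ``ξk·APCS_k``.
    Under the default ``truncate`` policy, negative mean terms are floored
    at 0 before percentaging (the raw signed values stay available); the
    ``absolute`` policy uses |term| instead.  The denominator adds the
    intercept when positive, and that intercept share plus any truncation
    loss is reported as the ``residual`` (unapportioned) column.
    """
    if negative_policy not in {"truncate", "absolute"}:
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    mean_apcs = apcs_matrix.scores.mean(axis=0).to_numpy()
    terms = reg.coefficients.to_numpy() * mean_apcs  # metals × components
    intercept = reg.intercepts.to_numpy()

    if negative_policy == "truncate":
        adj = np.clip(terms, 0.0, None)
    else:
        adj = np.abs(terms)
    denom = adj.sum(axis=1) + np.clip(intercept, 0.0, None)
    if np.all(denom == 0):
        pct = np.full_like(adj, np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(denom[:, None] > 0, adj / denom[:, None] * 100.0, np.nan)

    comp_names = reg.coefficients.columns
    midx = reg.coefficients.index
    per_metal = pd.DataFrame(pct, index=midx, columns=comp_names)
    per_metal["residual"] = 100.0 - per_metal[comp_names].sum(axis=1)

    raw = pd.DataFrame(terms, index=midx, columns=comp_names)
    raw["intercept"] = intercept
    return SourceContributions(per_metal_percent=per_metal, raw_mean_terms=raw)


def overall_source_contributions(
    contribs: SourceContributions,
    aggregation: str = "equal",
    mean_concentrations: pd.Series | None = None,
) -> pd.Series:
    """Overall per-source shares, renormalized over the sources to 100.

    ``equal`` averages each source's per-metal percentage with equal metal
    weight; ``concentration`` weights metals by their mean concentration
    (``mean_concentrations`` required).
    """
    sources = contribs.source_names
    shares = contribs.per_metal_percent[sources]
    if aggregation == "equal":
        agg = shares.mean(axis=0)
    elif aggregation == "concentration":
        if mean_concentrations is None:
            raise ValueError("concentration weighting needs mean_concentrations")
        w = mean_concentrations.reindex(shares.index)
        agg = (shares.mul(w, axis=0)).sum(axis=0) / w.sum()
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    total = agg.sum()
    if total == 0:
        return pd.Series(np.nan, index=sources, name="overall_percent")
    out = (agg / total * 100.0).rename("overall_percent")
    contribs.overall_percent = out
    return out
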