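"""Group-level inference for dynamic-network metrics.

The primary comparison is an ANCOVA of a per-subject metric on group,
adjusting for age, sex, education, mean framewise displacement (head
motion) and acquisition site (fixed-effect dummies, reference = first
site lexicographically).  Metrics defined on a sparsity grid are compared
through the between-subject effect of a repeated-measures model, which
for a complete balanced within-subject factor equals the ANCOVA on each
subject's sparsity mean; per-sparsity ANCOVAs are reported alongside.
Clinical associations use partial Spearman correlations (covariate
residualized ranks) and multiple testing is controlled with the
Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GroupTestResult",
    "CorrelationResult",
    "ancova_group_effect",
    "sparsity_profile_group_effect",
    "partial_spearman",
    "bh_fdr",
    "fdr_annotate",
    "subgroup_contrasts",
    "check_phenotype",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("age", "sex", "education", "mean_fd")

PHENOTYPE_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "mean_fd",
    "site",
)


@dataclass(frozen=True)
class GroupTestResult:
    metric_name: str
    sparsity: object  # float, "averaged", or None
    F: float
    df1: int
    df2: int
    p: float
    p_fdr: float
    direction: int  # sign of the covariate-adjusted (case - control) difference
    contrast: str | None = None
    n: int = 0


@dataclass(frozen=True)
class CorrelationResult:
    metric_name: str
    variable: str
    rho: float
    p: float
    p_fdr: float
    n_used: int


def check_phenotype(pheno: pd.DataFrame, require=PHENOTYPE_COLUMNS) -> None:
    """Validate the phenotype table: required columns and unique subject ids."""
    missing = [c for c in require if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if pheno["subject_id"].duplicated().any():
        raise ValueError("phenotype table has duplicated subject ids")


def _covariate_design(
    pheno: pd.DataFrame, covariates, site_col: str | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; categoricals become treatment dummies
    with the lexicographically first level as reference."""
    n = len(pheno)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cats = list(covariates)
    if site_col is not None and site_col in pheno.columns:
        if pheno[site_col].nunique() > 1:
            cats = cats + [site_col]
    for c in cats:
        col = pheno[c]
        if col.isna().any():
            raise ValueError(f"missing values in covariate '{c}'")
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            cols.append(col.to_numpy(dtype=float))
            names.append(c)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # identify dependent columns via pivoted QR
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = sorted(names[piv[i]] for i in range(len(names)) if i >= (diag > tol).sum())
    raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _check_site_identifiable(pheno, group_col, site_col) -> None:
    if site_col is None or site_col not in pheno.columns:
        return
    if pheno[site_col].nunique() < 2:
        return
    tab = pd.crosstab(pheno[site_col], pheno[group_col])
    lacking = tab.index[(tab > 0).sum(axis=1) < 2].tolist()
    if lacking:
        raise ValueError(
            f"group effect not identified: site(s) {lacking} contain only one group"
        )


def ancova_group_effect(
    y,
    pheno: pd.DataFrame,
    *,
    group_col: str = "group",
    groups: tuple[str, str] = ("MDD", "HC"),
    covariates=DEFAULT_COVARIATES,
    site_col: str | None = "site",
    metric_name: str = "",
    sparsity=None,
    contrast: str | None = None,
) -> GroupTestResult:
    """Partial F-test for the group term in y ~ group + covariates + site.

    Fits the full and the group-free linear model by least squares and
    returns the extra-sum-of-squares F (1 numerator df), its p-value, and
    the sign of the adjusted (``groups[0]`` minus ``groups[1]``) mean
    difference.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(pheno):
        raise ValueError("y length must match phenotype rows")
    if not np.isfinite(y).all():
        raise ValueError("y contains missing/non-finite values")
    labels = pheno[group_col].astype(str)
    extra = set(labels) - set(map(str, groups))
    if extra:
        raise ValueError(f"unexpected group labels: {sorted(extra)}")
    if labels.nunique() < 2:
        raise ValueError("both groups must be present for a group contrast")
    _check_site_identifiable(pheno, group_col, site_col)

    Z, znames = _covariate_design(pheno, covariates, site_col)
    g = (labels == str(groups[0])).to_numpy(dtype=float)
    X = np.column_stack([Z, g])
    names = znames + [f"{group_col}[{groups[0]}]"]
    _check_full_rank(X, names)

    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, Z).fit()
    df2 = int(round(full.df_resid))
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    num = max(float(reduced.ssr - full.ssr), 0.0)
    scale = max(float(reduced.ssr), float(np.var(y) * len(y)), 1.0)
    if num <= 1e-12 * scale:
        F, p = 0.0, 1.0
    elif full.ssr <= 1e-12 * scale:
        F, p = np.inf, 0.0
    else:
        F = num / (full.ssr / df2)
        p = float(scipy.stats.f.sf(F, 1, df2))
    direction = int(np.sign(full.params[-1])) if num > 0 else 0
    return GroupTestResult(
        metric_name=metric_name,
        sparsity=sparsity,
        F=float(F),
        df1=1,
        df2=df2,
        p=p,
        p_fdr=np.nan,
        direction=direction,
        contrast=contrast,
        n=len(pheno),
    )


def sparsity_profile_group_effect(
    y_by_sparsity: pd.DataFrame, pheno: pd.DataFrame, **kwargs
) -> tuple[GroupTestResult, list[GroupTestResult]]:
    """Group effect for a metric defined on the full sparsity grid.

    The between-subject group main effect of the repeated-measures design
    (sparsity as within-subject factor) equals the ANCOVA on each
    subject's sparsity mean when the grid is complete; that equivalence is
    exploited here.  Per-sparsity ANCOVAs are returned alongside.  The
    group x sparsity interaction is deliberately not computed.
    """
    if y_by_sparsity.isna().any().any():
        raise ValueError("missing sparsity cells; the grid must be complete")
    if len(y_by_sparsity) != len(pheno):
        raise ValueError("metric table and phenotype must align row-wise")
    averaged = ancova_group_effect(
        y_by_sparsity.mean(axis=1).to_numpy(), pheno, sparsity="averaged", **kwargs
    )
    per_sparsity = [
        ancova_group_effect(
            y_by_sparsity[c].to_numpy(), pheno, sparsity=float(c), **kwargs
        )
        for c in y_by_sparsity.columns
    ]
    return averaged, per_sparsity


def partial_spearman(
    x,
    y,
    covariates: pd.DataFrame | None = None,
    *,
    metric_name: str = "",
    variable: str = "",
    min_n: int = 10,
) -> CorrelationResult:
    """Partial Spearman rank correlation of x and y given covariates.

    All variables — x, y and every covariate column — are rank-transformed
    (average ranks for ties; for 0/1 dummies this is an affine map and
    changes nothing), the x and y ranks are residualized on the covariate
    rank design (with intercept) by least squares, and the Pearson
    correlation of the residuals is reported with a t-approximation
    p-value on n - 2 - q degrees of freedom (q = number of covariate
    columns).  Ranking the covariates keeps strong monotone confounding
    linear on the rank scale, so it is removed rather than partially
    left in the residuals.  Rows with a missing x or y are dropped
    listwise first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    if covariates is not None:
        if len(covariates) != len(x):
            raise ValueError("covariates must align with x and y")
        Z = covariates.to_numpy(dtype=float)
        keep &= np.isfinite(Z).all(axis=1)
    n = int(keep.sum())
    if n < min_n:
        raise ValueError(f"only {n} complete cases; need at least {min_n}")
    xr = scipy.stats.rankdata(x[keep])
    yr = scipy.stats.rankdata(y[keep])
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("constant variable after listwise deletion")
    design = np.ones((n, 1))
    q = 0
    if covariates is not None:
        Zk = covariates.to_numpy(dtype=float)[keep]
        Zr = np.column_stack([scipy.stats.rankdata(c) for c in Zk.T])
        design = np.column_stack([design, Zr])
        q = Zr.shape[1]
    beta_x, *_ = np.linalg.lstsq(design, xr, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, yr, rcond=None)
    rx = xr - design @ beta_x
    ry = yr - design @ beta_y
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise ValueError("degenerate residuals; correlation undefined")
    rho = float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))
    df = n - 2 - q
    if df <= 0:
        raise ValueError("not enough cases for the requested covariate set")
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return CorrelationResult(
        metric_name=metric_name, variable=variable, rho=rho, p=p,
        p_fdr=np.nan, n_used=n,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fdr_annotate(results):
    """Fill ``p_fdr`` across one family of GroupTestResult/CorrelationResult."""
    adj = bh_fdr([r.p for r in results])
    return [replace(r, p_fdr=float(a)) for r, a in zip(results, adj)]


def subgroup_contrasts(
    metrics: pd.DataFrame,
    pheno: pd.DataFrame,
    *,
    status_col: str = "fedn_status",
    pairs=(("FEDN", "nonFEDN"), ("FEDN", "HC"), ("nonFEDN", "HC")),
    **kwargs,
) -> list[GroupTestResult]:
    """Pairwise ANCOVAs among FEDN patients, non-FEDN patients and controls.

    Each metric column is compared within every subgroup pair; the FDR is
    applied across the full family (metrics x contrasts).  Sites lacking
    both levels of a contrast are dropped from that contrast with a
    logged warning.
    """
    if len(metrics) != len(pheno):
        raise ValueError("metric table and phenotype must align row-wise")
    labels = np.where(
        pheno["group"].astype(str) == "HC", "HC", pheno[status_col].astype(str)
    )
    work = pheno.copy()
    work["_subgroup"] = labels
    results = []
    for a, b in pairs:
        mask = work["_subgroup"].isin([a, b]).to_numpy()
        sub = work.loc[mask]
        if "site" in sub.columns and sub["site"].nunique() > 1:
            tab = pd.crosstab(sub["site"], sub["_subgroup"])
            bad_sites = tab.index[(tab > 0).sum(axis=1) < 2].tolist()
            if bad_sites:
                logger.warning(
                    "contrast %s vs %s: dropping site(s) %s lacking both levels",
                    a, b, bad_sites,
                )
                keep_sites = ~sub["site"].isin(bad_sites)
                sub = sub.loc[keep_sites]
                mask = mask.copy()
                mask[mask] = keep_sites.to_numpy()
        for col in metrics.columns:
            results.append(
                ancova_group_effect(
                    metrics.loc[mask, col].to_numpy(),
                    sub,
                    group_col="_subgroup",
                    groups=(a, b),
                    metric_name=str(col),
                    contrast=f"{a}_vs_{b}",
                    **kwargs,
                )
            )
    return fdr_annotate(results)
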