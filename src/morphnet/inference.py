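"""Hub detection, covariate-adjusted group tests, BH-FDR, partial correlation.

The group comparison is a least-squares linear model with a two-level group
factor and dummy-coded covariates; with no covariates its group t-statistic
is algebraically the pooled-variance two-sample t.  FDR families are one per
(metric, sparsity), matching per-level corrected reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import stress

__all__ = [
    "StatResult",
    "detect_hubs",
    "build_design_matrix",
    "group_effect_lm",
    "hub_ttests",
    "bh_fdr",
    "partial_correlation",
]


@dataclass
class StatResult:
    term: str
    estimate: float
    statistic: float
    df: float
    p: float
    p_corr: Optional[float] = None
    family: str = ""
    extra: dict = field(default_factory=dict)


def detect_hubs(
    nodal_values: np.ndarray, groups: Sequence[str], sd_factor: float = 2.0
) -> np.ndarray:
    """Union over groups of nodes whose group-mean value is > mean + 2 SD.

    ``nodal_values`` is (n_subjects, n_nodes); for each group the nodal means
    are computed, and a node is a hub in that group when its mean exceeds the
    across-node mean by ``sd_factor`` across-node standard deviations (sample
    SD).  Zero variance across nodes yields no hubs for that group.
    """
    vals = np.asarray(nodal_values, dtype=float)
    if vals.ndim != 2 or vals.shape[1] < 2:
        raise ValueError("nodal_values must be (n_subjects, n_nodes) with >= 2 nodes")
    groups = np.asarray(groups)
    hubs: set[int] = set()
    for g in np.unique(groups):
        node_means = vals[groups == g].mean(axis=0)
        sd = node_means.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        cut = node_means.mean() + sd_factor * sd
        hubs.update(np.flatnonzero(node_means > cut).tolist())
    return np.array(sorted(hubs), dtype=int)


def build_design_matrix(
    cohort: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns; categoricals dummy-coded, first level reference."""
    n = len(cohort)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for cov in covariates:
        if cov not in cohort.columns:
            raise ValueError(f"covariate {cov!r} not in cohort table")
        col = cohort[cov]
        if col.isna().any():
            raise ValueError(f"covariate {cov!r} has missing values among analyzed rows")
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    return np.column_stack(cols), names


def _check_full_rank(x: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify offending columns via pivoted QR diagonal
        _, r, piv = _qr_pivot(x)
        bad = [names[piv[i]] for i in range(rank, x.shape[1])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _qr_pivot(x: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(x, mode="economic", pivoting=True)
    return q, r, piv


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Returns (beta, se, sigma2, df_resid)."""
    n, p = x.shape
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - p
    if df <= 0:
        raise ValueError("not enough observations for the model")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    return beta, se, sigma2, df


def group_effect_lm(
    y: Sequence[float],
    cohort: pd.DataFrame,
    covariates: Sequence[str] = (),
    group_col: str = "stress_group",
    family: str = "",
) -> StatResult:
    """Group effect (High minus Low) from y ~ intercept + group + covariates.

    Equivalent to a two-level ANCOVA: the group t is the signed square root
    of the ANCOVA F.  With no covariates it reproduces the pooled two-sample
    t exactly.
    """
    y = np.asarray(y, dtype=float)
    grp = cohort[group_col].astype(str)
    if not set(grp) <= {stress.LOW, stress.HIGH}:
        raise ValueError("cohort rows must be restricted to Low/High groups before modeling")
    for g in (stress.LOW, stress.HIGH):
        if (grp == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    indicator = (grp == stress.HIGH).to_numpy(dtype=float)
    x_cov, names = build_design_matrix(cohort, covariates)
    x = np.column_stack([x_cov[:, :1], indicator, x_cov[:, 1:]])
    names = ["intercept", "group[High]"] + names[1:]
    _check_full_rank(x, names)
    beta, se, sigma2, df = _ols(y, x)
    extra = {"covariates": list(covariates)}
    y_scale = max(1.0, float(np.abs(y).max()))
    if se[1] == 0 or not np.isfinite(se[1]) or np.sqrt(sigma2) < 1e-10 * y_scale:
        # zero residual variance (e.g. a measure that is constant by
        # construction, like mean degree under proportional thresholding)
        extra["degenerate"] = True
        t = 0.0
        p = 1.0
    else:
        t = float(beta[1] / se[1])
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return StatResult(
        term="group[High]",
        estimate=float(beta[1]),
        statistic=t,
        df=df,
        p=p,
        family=family,
        extra=extra,
    )


def hub_ttests(
    nodal_values: np.ndarray,
    groups: Sequence[str],
    nodes: Sequence[int],
    node_ids: Sequence | None = None,
    family: str = "",
    q: float = 0.05,
) -> list[StatResult]:
    """Two-tailed pooled two-sample t-tests (Low vs High) at the given nodes.

    The tested nodes form one FDR family; BH-adjusted p-values are filled in.
    """
    vals = np.asarray(nodal_values, dtype=float)
    groups = np.asarray(groups)
    hi = vals[groups == stress.HIGH]
    lo = vals[groups == stress.LOW]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("each group needs at least 2 subjects")
    nodes = list(nodes)
    if not nodes:
        return []
    n1, n2 = len(lo), len(hi)
    df = n1 + n2 - 2
    results = []
    for node in nodes:
        # "Low vs High" orientation: an increase in the High group gives t < 0
        a, b = lo[:, node], hi[:, node]
        diff = float(a.mean() - b.mean())
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        if denom == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            t = float(diff / denom)
            p = 2.0 * float(stats.t.sf(abs(t), df))
        label = node_ids[node] if node_ids is not None else node
        results.append(
            StatResult(
                term=f"node[{label}]",
                estimate=diff,
                statistic=t,
                df=df,
                p=p,
                family=family,
                extra={"node": int(node)},
            )
        )
    adjusted, _ = bh_fdr([r.p for r in results], q=q)
    for r, pc in zip(results, adjusted):
        r.p_corr = float(pc)
    return results


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection mask at q).

    adjusted p_(i) = min over j >= i of min(1, m * p_(j) / j) on the sorted
    scale, mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= q


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    z: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates Z.

    Both variables are residualized on [intercept, Z] by least squares; the
    correlation of the residuals is returned with a two-sided p-value from a
    t-distribution with n - |Z| - 2 degrees of freedom.  With Z empty this is
    the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if z is None:
        zm = np.empty((n, 0))
    elif isinstance(z, pd.DataFrame):
        zm, _ = build_design_matrix(z, list(z.columns))
        zm = zm[:, 1:]
    else:
        zm = np.asarray(z, dtype=float)
        if zm.ndim == 1:
            zm = zm[:, None]
    k = zm.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > |Z| + 2 observations, got n={n}, |Z|={k}")
    design = np.column_stack([np.ones(n), zm])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix Z is rank deficient")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a residual that is zero up to round-off (variable exactly explained by Z)
    # yields r_partial = 0, not round-off noise
    tol_x = 1e-10 * max(1.0, float(np.linalg.norm(x - x.mean())))
    tol_y = 1e-10 * max(1.0, float(np.linalg.norm(y - y.mean())))
    if np.linalg.norm(rx) < tol_x or np.linalg.norm(ry) < tol_y:
        return 0.0, 1.0
    denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 0.0, 1.0
    r = float(rx @ ry) / denom
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return r, p
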