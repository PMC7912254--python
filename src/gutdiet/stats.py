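"""Statistical toolkit shared by every screen in the pipeline.

Partial Spearman correlation (rank, residualize on covariates, Pearson on
residuals), Benjamini-Hochberg FDR, single-factor PERMANOVA,
Wilcoxon-Mann-Whitney, and covariate-adjusted group F-tests (GLM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as ss
import skbio
from statsmodels.stats.multitest import multipletests


@dataclass
class AssociationResult:
    left: str
    right: str
    coefficient: float
    p_value: float
    n: int
    q_value: float | None = None
    extra: dict = field(default_factory=dict)


def expand_covariates(covariates: pd.DataFrame | None) -> np.ndarray | None:
    """Indicator-expand categorical covariate columns; numeric pass through."""
    if covariates is None or covariates.shape[1] == 0:
        return None
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            cols.append(dummies.to_numpy(dtype=float))
    return np.hstack(cols)


def _residualize(Y: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of Y on [1, Z] by least squares."""
    n = Y.shape[0]
    design = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


def partial_spearman(
    x, y, covariates: pd.DataFrame | np.ndarray | None = None
) -> AssociationResult:
    """Partial Spearman correlation of x and y given covariates.

    Ranks x, y and every (indicator-expanded) covariate column with midranks,
    residualizes the ranked x and y on the ranked covariates plus intercept,
    and takes the Pearson correlation of the residuals.  Two-sided p from a t
    statistic on n - 2 - c degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        Z = expand_covariates(covariates)
    else:
        Z = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z is not None and Z.shape[0] != len(x):
            Z = Z.T
    c = 0 if Z is None else Z.shape[1]
    n = len(x)
    if n <= c + 3:
        raise ValueError(f"n = {n} too small for {c} covariate columns")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rz = None if Z is None else np.apply_along_axis(ss.rankdata, 0, Z)
    ex = _residualize(rx[:, None], rz)[:, 0]
    ey = _residualize(ry[:, None], rz)[:, 0]
    r = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    df = n - 2 - c
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2 * ss.t.sf(abs(t), df))
    return AssociationResult("x", "y", r, max(p, np.finfo(float).tiny), n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def permanova(
    dm: skbio.DistanceMatrix,
    factor,
    n_perm: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Single-factor PERMANOVA pseudo-F with a label-permutation p-value.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within is the analogous per-group sum;
    F = (SS_between / (a-1)) / (SS_within / (n-a)).  The p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm), never 0.
    """
    labels = pd.Series(np.asarray(factor), index=list(dm.ids))
    levels, codes = np.unique(labels.to_numpy(), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least two factor levels")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        raise ValueError("every level needs at least two samples")
    D2 = dm.data**2
    n = len(codes)
    a = len(levels)
    ss_total = D2.sum() / (2.0 * n)

    def ss_within(code_matrix: np.ndarray) -> np.ndarray:
        # code_matrix: (reps, n) integer labels; returns SS_within per rep
        out = np.zeros(code_matrix.shape[0])
        for g in range(a):
            mask = (code_matrix == g).astype(float)
            ng = mask.sum(axis=1)
            quad = np.einsum("ri,ij,rj->r", mask, D2, mask)
            out += quad / (2.0 * ng)
        return out

    sw = ss_within(codes[None, :])[0]
    f_obs = ((ss_total - sw) / (a - 1)) / (sw / (n - a))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    sw_perm = ss_within(perms)
    f_perm = ((ss_total - sw_perm) / (a - 1)) / (sw_perm / (n - a))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return AssociationResult(
        "distance", "factor", float(f_obs), float(p), n, extra={"n_perm": n_perm}
    )


def mann_whitney(x_a, x_b) -> AssociationResult:
    """Two-sided Wilcoxon-Mann-Whitney test with midrank ties.

    Exact enumeration when the pooled size is at most 12 and tie-free;
    normal approximation with tie and continuity correction otherwise.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if len(x_a) == 0 or len(x_b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x_a, x_b])
    exact = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    res = ss.mannwhitneyu(
        x_a, x_b, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return AssociationResult(
        "group_a", "group_b", float(res.statistic), float(res.pvalue),
        len(pooled), extra={"exact": exact},
    )


def glm_group_test(
    y, group, covariates: pd.DataFrame | None = None
) -> AssociationResult:
    """Covariate-adjusted group contrast by partial F-test.

    OLS of y on intercept + covariates + group indicators, compared against
    the covariate-only model.  Also reports covariate-adjusted group means
    (group effects evaluated with covariates held at their sample means).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    codes, levels = pd.factorize(np.asarray(group))
    a = len(levels)
    if a < 2:
        raise ValueError("group factor needs at least two levels")
    Z = expand_covariates(covariates)
    base = np.ones((n, 1)) if Z is None else np.column_stack([np.ones(n), Z])
    G = np.zeros((n, a - 1))
    for g in range(1, a):
        G[codes == g, g - 1] = 1.0
    full = np.column_stack([base, G])
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("design matrix rank deficient (aliased columns)")
    beta_full, *_ = np.linalg.lstsq(full, y, rcond=None)
    beta_base, *_ = np.linalg.lstsq(base, y, rcond=None)
    rss_full = float(((y - full @ beta_full) ** 2).sum())
    rss_base = float(((y - base @ beta_base) ** 2).sum())
    df1 = a - 1
    df2 = n - full.shape[1]
    f = ((rss_base - rss_full) / df1) / (rss_full / df2)
    p = float(ss.f.sf(f, df1, df2))
    # adjusted means: prediction per group at the covariate sample means
    base_mean = base.mean(axis=0)
    adj = {}
    for g in range(a):
        gvec = np.zeros(a - 1)
        if g > 0:
            gvec[g - 1] = 1.0
        adj[levels[g]] = float(np.concatenate([base_mean, gvec]) @ beta_full)
    return AssociationResult(
        "y", "group", float(f), max(p, np.finfo(float).tiny), n,
        extra={"adjusted_means": adj, "df": (df1, df2)},
    )


def correlation_screen(
    left: pd.DataFrame,
    right: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    fdr_scope: str = "per_left",
) -> pd.DataFrame:
    """Partial Spearman correlations for every left x right variable pair.

    BH-FDR is applied within each declared scope: ``per_left`` corrects each
    left variable's family separately; ``global`` corrects over all pairs.
    Returns a long-format table (left, right, coefficient, p, q, n).
    """
    if fdr_scope not in ("per_left", "global"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    n = left.shape[0]
    Z = expand_covariates(covariates)
    c = 0 if Z is None else Z.shape[1]
    rz = None if Z is None else np.apply_along_axis(ss.rankdata, 0, Z)
    RL = np.apply_along_axis(ss.rankdata, 0, left.to_numpy(dtype=float))
    RR = np.apply_along_axis(ss.rankdata, 0, right.to_numpy(dtype=float))
    EL = _residualize(RL, rz)
    ER = _residualize(RR, rz)
    EL = EL / np.sqrt((EL**2).sum(axis=0, keepdims=True))
    ER = ER / np.sqrt((ER**2).sum(axis=0, keepdims=True))
    R = np.clip(EL.T @ ER, -1.0, 1.0)
    df = n - 2 - c
    r_safe = np.clip(R, -1 + 1e-15, 1 - 1e-15)
    t = r_safe * np.sqrt(df / (1 - r_safe**2))
    P = 2 * ss.t.sf(np.abs(t), df)
    rows = []
    for i, lname in enumerate(left.columns):
        for j, rname in enumerate(right.columns):
            rows.append((lname, rname, R[i, j], P[i, j]))
    out = pd.DataFrame(rows, columns=["left", "right", "coefficient", "p_value"])
    out["n"] = n
    if fdr_scope == "global":
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["q_value"] = out.groupby("left", sort=False)["p_value"].transform(
            lambda p: bh_fdr(p.to_numpy())
        )
    return out
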