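"""Reduced rank regression dietary patterns.

With a single response variable the first RRR factor reduces exactly to the
fitted direction of ordinary least squares on column-standardized predictors:
the score is the standardized fitted value, loadings are food-score Pearson
correlations, and the fraction of response variance explained is the squared
score-response correlation.  Here the response is a (log) alpha-diversity
index and the predictors are the 25 energy-adjusted log food-group intakes,
yielding the "high alpha-diversity dietary pattern" (HiaDP) score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CompositionMatrix
from .stats import correlation_screen


@dataclass
class RRRResult:
    """First-factor reduced-rank-regression fit for one response.

    ``weights`` are coefficients on the standardized foods, ``loadings`` the
    food-score correlations, ``scores`` the per-sample pattern values
    (mean 0, variance 1, oriented so corr(score, response) >= 0) and
    ``response_r2`` the fraction of response variance the score explains.
    """

    food_groups: list[str]
    weights: pd.Series
    loadings: pd.Series
    scores: pd.Series
    response_r2: float


def fit_rrr(X: pd.DataFrame, y) -> RRRResult:
    """Derive the dietary pattern maximizing explained response variance.

    ``X`` is the sample x food matrix (already log-transformed and
    energy-adjusted upstream); ``y`` the response (log alpha-diversity).
    """
    y = np.asarray(y, dtype=float)
    n, g = X.shape
    if n < g + 2:
        raise ValueError(f"need n >= {g + 2} samples for {g} foods, got {n}")
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=1)
    if (sd == 0).any():
        dead = [c for c, s in zip(X.columns, sd) if s == 0]
        raise ValueError(f"constant food columns: {dead}")
    Xs = (Xv - Xv.mean(axis=0)) / sd
    if np.linalg.matrix_rank(Xs) < g:
        corr = np.corrcoef(Xs, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear food columns (e.g. {X.columns[i]!r} ~ {X.columns[j]!r})"
        )
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), Xs]), y, rcond=None)
    w = beta[1:]
    raw = Xs @ w
    score = (raw - raw.mean()) / raw.std(ddof=1)
    r = float(np.corrcoef(score, y)[0, 1])
    if r < 0:
        score, w, r = -score, -w, -r
    loadings = Xs.T @ score / ((n - 1) * 1.0)  # Pearson corr: both standardized
    return RRRResult(
        food_groups=list(X.columns),
        weights=pd.Series(w, index=X.columns),
        loadings=pd.Series(loadings, index=X.columns),
        scores=pd.Series(score, index=X.index),
        response_r2=r**2,
    )


def main_contributors(result: RRRResult, threshold: float = 0.3) -> dict[str, list[str]]:
    """Food groups with |loading| above the threshold, split by sign and
    sorted by |loading| descending (the pattern's 'main contributing' foods)."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    big = result.loadings[result.loadings.abs() > threshold]
    big = big.reindex(big.abs().sort_values(ascending=False).index)
    return {
        "positive": [f for f, v in big.items() if v > 0],
        "negative": [f for f, v in big.items() if v < 0],
    }


def pattern_taxa_screen(
    scores: pd.Series,
    clr_taxa: CompositionMatrix,
    covariates: pd.DataFrame | None = None,
    fdr_scope: str = "global",
) -> pd.DataFrame:
    """Partial Spearman screen of the pattern score against clr abundances.

    Returns a long-format table (taxon, coefficient, p_value, q_value, n);
    BH-FDR is applied over the screened taxon family.
    """
    if clr_taxa.stage != "clr":
        raise ValueError("pattern_taxa_screen expects clr-stage abundances")
    left = pd.DataFrame({"pattern_score": scores})
    out = correlation_screen(left, clr_taxa.values, covariates, fdr_scope=fdr_scope)
    out = out.rename(columns={"right": "taxon"}).drop(columns="left")
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
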