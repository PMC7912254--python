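"""Transformations applied before any statistics.

Order of operations for the microbiome side: rarefy counts once to a common
depth, aggregate to the rank of interest, convert to proportions, replace
zeros by the geometric Bayesian-multiplicative rule, then centre log-ratio
(clr) transform.  For diet: log-transform intakes and remove total-energy
dependence by the residual method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RANKS, UNCLASSIFIED, DietTable, FeatureTable

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    pass


@dataclass
class CompositionMatrix:
    """Sample x part relative-abundance matrix with an explicit pipeline stage.

    ``stage`` is one of ``proportions`` (rows on the simplex),
    ``zero_replaced`` (simplex, strictly positive) or ``clr`` (rows sum to 0).
    ``totals`` carries each sample's original count total, needed by the
    Bayesian-multiplicative zero replacement.
    """

    values: pd.DataFrame
    stage: str
    totals: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def part_ids(self) -> list[str]:
        return list(self.values.columns)


def rarefy(table: FeatureTable, depth: int | None = None, seed: int = 0) -> FeatureTable:
    """Subsample every sample's counts without replacement to a common depth.

    Samples with fewer than ``depth`` total reads are dropped (logged).  The
    default depth is the minimum sample total, mirroring standardisation to
    the shallowest library.  A single draw is taken under ``seed``.
    """
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.info("rarefy: dropped %d samples below depth %d", len(dropped), depth)
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.counts.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = table.counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=keep, columns=table.counts.columns)
    return FeatureTable(counts=counts, lineages=table.lineages.copy())


def aggregate(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum counts over taxa sharing a name at ``rank``; unassigned pool into
    ``unclassified``.  Per-sample totals are conserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    names = table.lineages[rank].fillna(UNCLASSIFIED).replace("", UNCLASSIFIED)
    grouped = table.counts.T.groupby(names.to_numpy()).sum().T
    lineages = pd.DataFrame(UNCLASSIFIED, index=grouped.columns, columns=list(RANKS))
    lineages[rank] = grouped.columns
    return FeatureTable(counts=grouped, lineages=lineages)


def to_proportions(table: FeatureTable) -> CompositionMatrix:
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateInputError(f"all-zero samples: {list(zero.index)}")
    props = table.counts.div(totals, axis=0).astype(float)
    return CompositionMatrix(values=props, stage="proportions", totals=totals.astype(float))


def replace_zeros(cm: CompositionMatrix, prior_strength: float = 0.5) -> CompositionMatrix:
    """Geometric Bayesian-multiplicative zero replacement.

    For sample i with original count total N_i and a uniform per-part prior
    s_j = ``prior_strength`` (S = sum_j s_j), each zero part becomes
    delta_ij = s_j / (N_i + S) and the non-zero parts are shrunk by the factor
    (1 - sum of imputed mass) so the row stays on the simplex.  Ratios between
    non-zero parts are preserved exactly.
    """
    if cm.stage != "proportions":
        raise ValueError(f"replace_zeros expects stage 'proportions', got {cm.stage!r}")
    if prior_strength <= 0:
        raise ValueError("prior_strength must be positive")
    if cm.totals is None:
        raise ValueError("replace_zeros needs original count totals")
    X = cm.values.to_numpy(dtype=float)
    n, d = X.shape
    S = prior_strength * d
    N = cm.totals.to_numpy(dtype=float)
    delta = prior_strength / (N + S)  # per-sample imputed value for each zero part
    zeros = X == 0
    imputed_mass = zeros.sum(axis=1) * delta
    out = X * (1.0 - imputed_mass)[:, None]
    out[zeros] = np.broadcast_to(delta[:, None], X.shape)[zeros]
    return CompositionMatrix(
        values=pd.DataFrame(out, index=cm.values.index, columns=cm.values.columns),
        stage="zero_replaced",
        totals=cm.totals,
    )


def clr(cm: CompositionMatrix) -> CompositionMatrix:
    """Centre log-ratio: ln x minus the sample's mean log part; rows sum to 0."""
    if cm.stage not in ("zero_replaced", "proportions"):
        raise ValueError(f"clr expects zero-replaced proportions, got stage {cm.stage!r}")
    X = cm.values.to_numpy(dtype=float)
    if (X <= 0).any():
        raise ValueError("clr requires strictly positive entries; replace zeros first")
    logX = np.log(X)
    out = logX - logX.mean(axis=1, keepdims=True)
    return CompositionMatrix(
        values=pd.DataFrame(out, index=cm.values.index, columns=cm.values.columns),
        stage="clr",
        totals=cm.totals,
    )


def clr_log_ratio(cm_clr: CompositionMatrix, part_a: str, part_b: str) -> pd.Series:
    """clr_a - clr_b, identically ln(x_a / x_b) (e.g. the Firmicutes/Bacteroidetes
    log ratio when the parts are those phyla)."""
    if cm_clr.stage != "clr":
        raise ValueError("clr_log_ratio expects a clr-stage matrix")
    for part in (part_a, part_b):
        if part not in cm_clr.values.columns:
            raise ValueError(f"part {part!r} not present")
    return cm_clr.values[part_a] - cm_clr.values[part_b]


def log_energy_adjust(diet: DietTable) -> pd.DataFrame:
    """Energy adjustment of log intakes by the residual method.

    Each food group's log intake is regressed on log total energy (OLS with
    intercept); the adjusted value is the residual plus the fitted value at
    the sample-mean log energy, so columns keep their original location while
    becoming uncorrelated with energy.  Zero intakes are offset by half the
    smallest positive value in their column before the log.
    """
    loge = np.log(diet.total_energy.to_numpy(dtype=float))
    if np.ptp(loge) == 0:
        raise DegenerateInputError("total energy constant across samples")
    X = diet.intakes.to_numpy(dtype=float).copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        if (col == 0).any():
            pos = col[col > 0]
            if len(pos) == 0:
                raise DegenerateInputError(
                    f"food group {diet.intakes.columns[j]!r} has no positive intakes"
                )
            col[col == 0] = pos.min() / 2.0
    logX = np.log(X)
    centered = loge - loge.mean()
    denom = (centered**2).sum()
    slopes = centered @ (logX - logX.mean(axis=0)) / denom
    fitted_at_mean = logX.mean(axis=0)  # intercept + slope * mean(loge)
    resid = logX - logX.mean(axis=0) - np.outer(centered, slopes)
    adjusted = resid + fitted_at_mean
    return pd.DataFrame(adjusted, index=diet.intakes.index, columns=diet.intakes.columns)
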