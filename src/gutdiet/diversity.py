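"""Alpha-diversity indices and beta-diversity distance matrices.

Alpha indices (Chao1, Shannon, Faith's PD) are computed on rarefied counts.
Beta matrices (Bray-Curtis, unweighted and weighted UniFrac) are computed on
the same standardized table.  UniFrac and Faith PD work from an explicit
branch incidence decomposition of the rooted tree: every branch contributes
its length according to which samples have observed leaves below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .io import FeatureTable
from .preprocess import CompositionMatrix, DegenerateInputError


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1 and F2 are the singleton and doubleton counts; the bias-corrected
    form is used throughout so samples without doubletons are defined.
    """
    counts = np.asarray(counts)
    if not (counts > 0).any():
        raise DegenerateInputError("all-zero sample")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy -sum p ln p over non-zero proportions (natural log by
    default; ``base`` rescales)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclass
class BranchMatrix:
    """Per-branch leaf incidence of a rooted tree.

    ``incidence[b, l]`` is True when leaf ``l`` descends from branch ``b``
    (the edge above each non-root node); ``lengths[b]`` is that branch's
    length.  The root carries no branch.
    """

    incidence: np.ndarray  # (n_branches, n_leaves) bool
    lengths: np.ndarray  # (n_branches,)
    leaf_names: list[str]

    @classmethod
    def from_tree(cls, tree: skbio.TreeNode) -> "BranchMatrix":
        leaves = [t.name for t in tree.tips()]
        pos = {name: i for i, name in enumerate(leaves)}
        rows, lengths = [], []
        for node in tree.postorder(include_self=False):
            mask = np.zeros(len(leaves), dtype=bool)
            for tip in node.tips(include_self=True):
                mask[pos[tip.name]] = True
            rows.append(mask)
            lengths.append(float(node.length or 0.0))
        return cls(np.array(rows), np.array(lengths), leaves)


def _observed_matrix(table: FeatureTable, bm: BranchMatrix) -> np.ndarray:
    """Counts reordered to the tree's leaf order; errors on taxa off the tree."""
    observed = table.counts.loc[:, (table.counts > 0).any(axis=0)]
    missing = [t for t in observed.columns if t not in set(bm.leaf_names)]
    if missing:
        raise ValueError(f"observed taxa missing from tree: {missing}")
    full = pd.DataFrame(
        0.0, index=table.counts.index, columns=bm.leaf_names, dtype=float
    )
    shared = [t for t in table.taxon_ids if t in set(bm.leaf_names)]
    full.loc[:, shared] = table.counts[shared].to_numpy(dtype=float)
    return full.to_numpy()


def faith_pd(counts: np.ndarray, tree: skbio.TreeNode, leaf_names: list[str] | None = None) -> float:
    """Faith's phylogenetic diversity: total branch length on the union of
    root-to-leaf paths over the observed leaves."""
    bm = tree if isinstance(tree, BranchMatrix) else BranchMatrix.from_tree(tree)
    counts = np.asarray(counts, dtype=float)
    if leaf_names is not None:
        extra = [n for n, c in zip(leaf_names, counts)
                 if c > 0 and n not in set(bm.leaf_names)]
        if extra:
            raise ValueError(f"observed taxa missing from tree: {extra}")
        order = pd.Series(counts, index=leaf_names).reindex(bm.leaf_names).fillna(0.0)
        counts = order.to_numpy()
    present = counts > 0
    if not present.any():
        raise DegenerateInputError("all-zero sample")
    covered = bm.incidence @ present > 0
    return float(bm.lengths[covered].sum())


def alpha_diversity(table: FeatureTable, tree: skbio.TreeNode) -> pd.DataFrame:
    """Chao1, Shannon and Faith PD per sample, as a DataFrame."""
    bm = BranchMatrix.from_tree(tree)
    obs = _observed_matrix(table, bm)
    rows = {
        "chao1": [chao1(r) for r in table.counts.to_numpy()],
        "shannon": [shannon(r) for r in table.counts.to_numpy()],
        "faith_pd": [faith_pd(r, bm) for r in obs],
    }
    return pd.DataFrame(rows, index=table.counts.index)


def bray_curtis(cm: CompositionMatrix) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances: in [0, 1], 0 for
    identical rows, 1 for disjoint supports."""
    if cm.stage != "proportions":
        raise ValueError("bray_curtis expects a proportions-stage matrix")
    d = squareform(pdist(cm.values.to_numpy(dtype=float), metric="braycurtis"))
    return skbio.DistanceMatrix(d, ids=cm.sample_ids)


def unweighted_unifrac(table: FeatureTable, tree: skbio.TreeNode) -> skbio.DistanceMatrix:
    """Unweighted UniFrac: branch length unique to one sample's leaf set over
    branch length present in either, per pair."""
    bm = BranchMatrix.from_tree(tree)
    present = (_observed_matrix(table, bm) > 0)
    # A[i, b]: branch b has an observed leaf of sample i below it
    A = (present @ bm.incidence.T > 0).astype(float)
    shared = (A * bm.lengths) @ A.T  # sum of lengths where both present
    row = (A * bm.lengths).sum(axis=1)
    either = row[:, None] + row[None, :] - shared
    unique = either - shared
    with np.errstate(invalid="ignore"):
        d = np.where(either > 0, unique / np.where(either > 0, either, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return skbio.DistanceMatrix(d, ids=table.sample_ids)


def weighted_unifrac(
    table: FeatureTable, tree: skbio.TreeNode, normalized: bool = False
) -> skbio.DistanceMatrix:
    """Weighted UniFrac: sum_b l_b |P_A(b) - P_B(b)| with P_X(b) the fraction
    of sample X's reads descending from branch b; the normalized form divides
    by sum_b l_b (P_A(b) + P_B(b)).  Default raw (unnormalized)."""
    bm = BranchMatrix.from_tree(tree)
    obs = _observed_matrix(table, bm)
    totals = obs.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise DegenerateInputError("all-zero sample")
    P = (obs / totals) @ bm.incidence.T  # (n_samples, n_branches)
    W = P * bm.lengths
    raw = squareform(pdist(W, metric="cityblock"))
    if not normalized:
        d = raw
    else:
        row = W.sum(axis=1)
        denom = row[:, None] + row[None, :]
        with np.errstate(invalid="ignore"):
            d = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(d, 0.0)
    return skbio.DistanceMatrix((d + d.T) / 2.0, ids=table.sample_ids)


BETA_METRICS = ("bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def beta_diversity(
    table: FeatureTable, tree: skbio.TreeNode | None, metric: str
) -> skbio.DistanceMatrix:
    """Dispatch to one beta-diversity metric by name."""
    if metric == "bray_curtis":
        from .preprocess import to_proportions

        return bray_curtis(to_proportions(table))
    if metric == "unweighted_unifrac":
        return unweighted_unifrac(table, tree)
    if metric == "weighted_unifrac":
        return weighted_unifrac(table, tree)
    raise ValueError(f"unknown beta metric {metric!r}; expected one of {BETA_METRICS}")
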