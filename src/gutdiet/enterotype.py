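"""Enterotype discovery on beta-diversity matrices.

Classical PCoA (metric multidimensional scaling) projects the distance
matrix onto principal coordinates; k-means on the first two coordinates
partitions the cohort; three criteria (elbow on within-cluster sum of
squares, mean silhouette width, and the gap statistic against a uniform
reference) inform the choice of k; each cluster is named by its most
discriminating genus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .preprocess import CompositionMatrix
from .stats import AssociationResult, glm_group_test


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n, m)
    eigenvalues: np.ndarray  # (m,), descending
    negative_eigenvalue_mass: float


@dataclass
class EnterotypeResult:
    labels: pd.Series  # sample -> cluster id in 0..k-1
    k: int
    diagnostics: pd.DataFrame
    dominant_genus: dict[int, str] = field(default_factory=dict)
    pcoa: PCoAResult | None = None


def pcoa(dm: skbio.DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical scaling: double-centre -D^2/2, eigendecompose, scale
    eigenvectors by sqrt(eigenvalue).  Negative eigenvalues are excluded and
    their absolute mass reported."""
    D2 = dm.data.astype(float) ** 2
    n = D2.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12
    pos = vals > tol
    neg_mass = float(np.abs(vals[vals < -tol]).sum())
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; truncating from {n_axes}",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = vecs[:, :n_axes] * np.sqrt(vals[:n_axes])
    return PCoAResult(list(dm.ids), coords, vals[:n_axes], neg_mass)


def kmeans_cluster(
    coordinates: np.ndarray, k: int, seed: int = 0, n_init: int = 50
) -> np.ndarray:
    """k-means with k-means++ starts, best of ``n_init`` restarts, seeded."""
    coordinates = np.asarray(coordinates, dtype=float)
    if k < 1 or k > coordinates.shape[0]:
        raise ValueError(f"k = {k} out of range for n = {coordinates.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31))
    return km.fit_predict(coordinates)


def _wss(coordinates: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in np.unique(labels):
        pts = coordinates[labels == g]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def choose_k(
    coordinates: np.ndarray, k_max: int = 8, B: int = 50, seed: int = 0, n_init: int = 10
) -> pd.DataFrame:
    """Diagnostics over k = 1..k_max: elbow (WSS), mean silhouette, gap.

    Gap statistic: mean over B uniform reference sets drawn on the bounding
    box of the coordinates of log W*_k, minus log W_k, with its standard
    error (the sd inflated by sqrt(1 + 1/B)).  Suggested k per criterion:
    elbow = max second difference of WSS, silhouette = argmax, gap = smallest
    k with gap(k) >= gap(k+1) - se(k+1).  The final k remains a user choice.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 2:
        raise ValueError("B must be >= 2")
    coordinates = np.asarray(coordinates, dtype=float)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, k_max + 1)
    wss = np.empty(len(ks))
    sil = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        labels = kmeans_cluster(coordinates, k, seed=seed + i, n_init=n_init)
        wss[i] = _wss(coordinates, labels)
        if k >= 2 and len(np.unique(labels)) > 1:
            sil[i] = silhouette_score(coordinates, labels)
    lo, hi = coordinates.min(axis=0), coordinates.max(axis=0)
    log_wstar = np.empty((B, len(ks)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=coordinates.shape)
        for i, k in enumerate(ks):
            labels = kmeans_cluster(ref, k, seed=seed + 1000 + b * k_max + i, n_init=n_init)
            log_wstar[b, i] = np.log(_wss(ref, labels))
    gap = log_wstar.mean(axis=0) - np.log(wss)
    se = log_wstar.std(axis=0, ddof=1) * np.sqrt(1.0 + 1.0 / B)
    diag = pd.DataFrame(
        {"k": ks, "wss": wss, "mean_silhouette": sil, "gap": gap, "gap_se": se}
    ).set_index("k")
    second_diff = np.full(len(ks), np.nan)
    if len(ks) >= 3:
        second_diff[1:-1] = wss[:-2] - 2 * wss[1:-1] + wss[2:]
    diag["wss_second_diff"] = second_diff
    gap_k = None
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - se[i + 1]:
            gap_k = int(ks[i])
            break
    if gap_k is None:
        gap_k = int(ks[-1])
    diag.attrs["suggested"] = {
        "elbow": int(ks[np.nanargmax(second_diff)]) if len(ks) >= 3 else None,
        "silhouette": int(ks[np.nanargmax(sil)]),
        "gap": gap_k,
    }
    return diag


def label_enterotypes(
    labels, genus_proportions: CompositionMatrix
) -> dict[int, str]:
    """Name each cluster by its most discriminating genus.

    The score of genus g for cluster c is mean proportion within c minus the
    mean over all other clusters; ties break by within-cluster mean, then
    lexicographically.  The cluster-to-genus map is injective: a lower-scoring
    cluster whose best genus is taken falls back to its next best.
    """
    if genus_proportions.stage != "proportions":
        raise ValueError("label_enterotypes expects genus proportions")
    labels = pd.Series(np.asarray(labels), index=genus_proportions.values.index)
    vals = genus_proportions.values
    clusters = [int(c) for c in sorted(labels.unique())]
    if len(clusters) == 1:
        return {clusters[0]: vals.mean(axis=0).idxmax()}
    scores = {}
    for c in clusters:
        inside = vals[labels == c].mean(axis=0)
        outside = vals[labels != c].mean(axis=0)
        diff = inside - outside
        ranking = sorted(
            vals.columns,
            key=lambda g: (-diff[g], -inside[g], g),
        )
        scores[c] = (diff, ranking)
    # assign greedily by descending best-genus score, keeping the map injective
    order = sorted(clusters, key=lambda c: -scores[c][0][scores[c][1][0]])
    taken: set[str] = set()
    out: dict[int, str] = {}
    for c in order:
        for g in scores[c][1]:
            if g not in taken:
                out[c] = g
                taken.add(g)
                break
    return out


def discover_enterotypes(
    dm: skbio.DistanceMatrix,
    genus_proportions: CompositionMatrix | None = None,
    k: int = 3,
    k_max: int = 8,
    B: int = 50,
    seed: int = 0,
    n_axes: int = 2,
) -> EnterotypeResult:
    """PCoA -> k-means on the first ``n_axes`` coordinates -> diagnostics and
    dominant-genus names.  ``k`` defaults to the three canonical enterotypes."""
    pc = pcoa(dm, n_axes=n_axes)
    labels = kmeans_cluster(pc.coordinates, k, seed=seed)
    diag = choose_k(pc.coordinates, k_max=k_max, B=B, seed=seed)
    result = EnterotypeResult(
        labels=pd.Series(labels, index=pc.sample_ids), k=k, diagnostics=diag, pcoa=pc
    )
    if genus_proportions is not None:
        aligned = genus_proportions.values.loc[pc.sample_ids]
        cm = CompositionMatrix(values=aligned, stage="proportions")
        result.dominant_genus = label_enterotypes(labels, cm)
    return result


def enterotype_contrasts(
    result: EnterotypeResult,
    variables: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted enterotype contrasts for each variable.

    Per variable: a partial F-test of the enterotype factor (GLM adjusted for
    covariates) plus per-enterotype means and interquartile ranges of the raw
    variable.  Returns one row per variable.
    """
    labels = result.labels.loc[variables.index]
    rows = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        res: AssociationResult = glm_group_test(y, labels.to_numpy(), covariates)
        row: dict[str, object] = {"variable": name, "F": res.coefficient, "p_value": res.p_value}
        for c in sorted(labels.unique()):
            grp = variables.loc[labels == c, name]
            genus = result.dominant_genus.get(c, str(c))
            row[f"mean_{genus}"] = grp.mean()
            row[f"iqr_{genus}"] = f"{grp.quantile(0.25):.3g}-{grp.quantile(0.75):.3g}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
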