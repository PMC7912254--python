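"""Synthetic diet-microbiome study generator with known ground truth.

Emulates a 222-subject cross-sectional cohort: a rooted phylogeny over ~200
taxa spanning the four dominant gut phyla (Bacteroidetes, Firmicutes,
Proteobacteria, Actinobacteria), Dirichlet-multinomial count tables with
three planted enterotype communities (Prevotella / Bacteroides / Ruminococcus
dominated), 25 energy-correlated log-normal food-group intakes, and a planted
food-pattern -> community-evenness effect.  Every draw flows from one root
seed through named sub-streams, so adding a component never perturbs
another's randomness.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import skbio

from .io import (
    CovariateTable,
    DietTable,
    FeatureTable,
    write_covariates,
    write_diet,
    write_feature_table,
    write_tree,
)

# genus roster per phylum; leaf budgets follow the cohort's phylum dominance
PHYLA = {
    "Bacteroidetes": ["Bacteroides", "Prevotella", "Tannerella", "Coenonia",
                      "Alistipes", "Parabacteroides"],
    "Firmicutes": ["Ruminococcus", "Lactobacillus", "Eubacterium",
                   "Faecalibacterium", "Roseburia", "Blautia", "Clostridium",
                   "Streptococcus", "Dorea", "Oscillibacter"],
    "Proteobacteria": ["Escherichia", "Sutterella", "Bilophila"],
    "Actinobacteria": ["Bifidobacterium", "Collinsella"],
}
PHYLUM_LEAF_SHARE = {"Bacteroidetes": 0.30, "Firmicutes": 0.50,
                     "Proteobacteria": 0.12, "Actinobacteria": 0.08}
# median relative abundance of the four phyla (percent scale 54.2/37.6/3.8/0.4,
# renormalized to a simplex)
PHYLUM_MASS = {"Bacteroidetes": 0.5646, "Firmicutes": 0.3917,
               "Proteobacteria": 0.0396, "Actinobacteria": 0.0042}

FOOD_GROUPS = [
    "potatoes", "vegetables", "fermented_vegetables", "seaweeds", "legumes",
    "fermented_legumes", "fruit_fruit_juice", "nuts_seeds", "dairy",
    "refined_grains", "multi_whole_grains", "other_cereal_products", "meats",
    "processed_meats", "fish_seashells", "eggs", "vegetable_oils",
    "other_fats", "sugar_confectionery", "cakes_sweets", "coffee", "tea",
    "non_alcoholic_beverages", "pizza_burgers", "salty_snacks",
]
FOOD_MEANS = [30, 150, 90, 1.5, 45, 3.8, 200, 3.0, 140, 440, 4.0, 78, 107,
              7.0, 35, 24, 1.9, 0.6, 3.6, 17, 3.0, 25, 90, 18, 7.6]
# planted high-diversity pattern direction: plant/fermented foods up,
# sweet beverages and noodle products down
PATTERN_WEIGHTS = {
    "fermented_legumes": 0.8, "vegetables": 0.7, "potatoes": 0.6,
    "seaweeds": 0.6, "nuts_seeds": 0.5, "tea": 0.4,
    "non_alcoholic_beverages": -0.7, "other_cereal_products": -0.4,
}


@dataclass
class StudyConfig:
    """Parameters of the synthetic study; defaults emulate the cohort shape."""

    n_samples: int = 222
    n_taxa: int = 200
    n_food_groups: int = 25
    enterotype_proportions: tuple = (0.288, 0.365, 0.347)
    dominant_taxa: tuple = ("Prevotella", "Bacteroides", "Ruminococcus")
    concentration: float = 250.0
    dominant_boost: float = 6.0
    diversity_scale: float = 0.8
    diet_effect: float = 0.5
    depth_range: tuple = (8000, 45000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_taxa < 2:
            raise ValueError("n_samples >= 1 and n_taxa >= 2 required")
        if abs(sum(self.enterotype_proportions) - 1.0) > 1e-12:
            raise ValueError("enterotype_proportions must sum to 1")
        if len(self.dominant_taxa) != len(self.enterotype_proportions):
            raise ValueError("one dominant taxon per enterotype required")
        if len(set(self.dominant_taxa)) != len(self.dominant_taxa):
            raise ValueError("dominant taxa must be distinct")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.depth_range[0] > self.depth_range[1] or self.depth_range[0] < 1:
            raise ValueError("invalid depth_range")

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("enterotype_proportions", "dominant_taxa", "depth_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    enterotype_labels: pd.Series  # per-sample int in 0..k-1
    pattern_weights: pd.Series  # per-food planted direction
    latent_diversity: pd.Series  # per-sample evenness latent


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


def _lineage_rows(n_taxa: int) -> pd.DataFrame:
    """Deterministic leaf taxonomy: taxon ids T0001.. with phylum/genus by clade."""
    roster_size = sum(len(g) for g in PHYLA.values())
    if n_taxa < roster_size:
        # tiny trees: fill genera round-robin across phyla, one leaf each
        interleaved = []
        for i in range(max(len(g) for g in PHYLA.values())):
            for p, genera in PHYLA.items():
                if i < len(genera):
                    interleaved.append((p, genera[i]))
        rows = [
            {"taxon_id": f"T{i + 1:04d}", "phylum": p, "class": f"{p}_c",
             "order": f"{p}_o", "family": f"{g}_f", "genus": g}
            for i, (p, g) in enumerate(interleaved[:n_taxa])
        ]
        return pd.DataFrame(rows).set_index("taxon_id")
    budgets = {}
    acc = 0
    phyla = list(PHYLA)
    for i, p in enumerate(phyla):
        budgets[p] = (
            n_taxa - acc if i == len(phyla) - 1
            else max(len(PHYLA[p]), round(PHYLUM_LEAF_SHARE[p] * n_taxa))
        )
        acc += budgets[p]
    if acc - budgets[phyla[-1]] >= n_taxa:
        raise ValueError(f"n_taxa = {n_taxa} too small for the genus roster")
    rows = []
    idx = 1
    for p in phyla:
        genera = PHYLA[p]
        per = np.full(len(genera), budgets[p] // len(genera))
        per[: budgets[p] % len(genera)] += 1
        for g, m in zip(genera, per):
            for _ in range(int(m)):
                rows.append(
                    {"taxon_id": f"T{idx:04d}", "phylum": p,
                     "class": f"{p}_c", "order": f"{p}_o",
                     "family": f"{g}_f", "genus": g}
                )
                idx += 1
    return pd.DataFrame(rows).set_index("taxon_id")


def _random_join(nodes: list[skbio.TreeNode], rng: np.random.Generator,
                 mean_len: float) -> skbio.TreeNode:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = skbio.TreeNode(children=[left, right])
        for child in (left, right):
            if child.length is None:
                child.length = float(rng.exponential(mean_len))
        nodes.append(parent)
    return nodes[0]


def generate_tree(n_taxa: int = 200, seed: int = 0) -> tuple[skbio.TreeNode, pd.DataFrame]:
    """Rooted binary tree over ``n_taxa`` leaves with exponential branch
    lengths, clade structure nested genus-within-phylum; returns the tree and
    the per-leaf lineage table."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be at least 2")
    lineages = _lineage_rows(n_taxa)
    rng = _substream(seed, "tree")
    phylum_trees = []
    for p in PHYLA:
        genus_trees = []
        for g in PHYLA[p]:
            leaves = [skbio.TreeNode(name=t, length=float(rng.exponential(0.05)))
                      for t in lineages.index[lineages["genus"] == g]]
            if not leaves:
                continue
            sub = leaves[0] if len(leaves) == 1 else _random_join(leaves, rng, 0.05)
            # genus stem: genera are well-separated clades, as in 16S trees
            stem = float(rng.exponential(0.2))
            sub.length = stem if sub.length is None else sub.length + stem
            genus_trees.append(sub)
        if not genus_trees:
            continue
        sub = genus_trees[0] if len(genus_trees) == 1 else _random_join(genus_trees, rng, 0.35)
        if sub.length is None:
            sub.length = float(rng.exponential(0.3))
        phylum_trees.append(sub)
    root = phylum_trees[0] if len(phylum_trees) == 1 else _random_join(phylum_trees, rng, 0.3)
    for child in root.children:
        if child.length is None:
            child.length = float(rng.exponential(0.3))
    root.length = None
    return root, lineages


def _enterotype_means(config: StudyConfig, lineages: pd.DataFrame,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-enterotype Dirichlet mean compositions over the leaves."""
    taxa = lineages.index
    base = np.empty(len(taxa))
    for p, mass in PHYLUM_MASS.items():
        idx = (lineages["phylum"] == p).to_numpy()
        w = rng.lognormal(0.0, 1.0, size=idx.sum())
        base[idx] = mass * w / w.sum()
    base /= base.sum()
    genus_of = lineages["genus"]
    means = []
    for taxon in config.dominant_taxa:
        if taxon in set(genus_of):
            genus = taxon
        elif taxon in set(taxa):
            genus = genus_of[taxon]
        else:
            raise ValueError(f"dominant taxon {taxon!r} not in the tree")
        m = base.copy()
        m[(genus_of == genus).to_numpy()] *= config.dominant_boost
        means.append(m / m.sum())
    return np.array(means)


def generate_counts(
    config: StudyConfig, tree: skbio.TreeNode, lineages: pd.DataFrame | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """Dirichlet-multinomial counts with planted enterotypes and a latent
    per-sample evenness variable.

    Each sample draws an enterotype label, then a composition from a
    Dirichlet centred on that enterotype's mean; the Dirichlet precision is
    ``concentration * exp(diversity_scale * u)`` for a standard-normal latent
    ``u``, so higher ``u`` means more even communities (higher true
    diversity).  Counts are multinomial at a uniform random depth.
    """
    leaf_names = [t.name for t in tree.tips()]
    if lineages is None:
        lineages = _lineage_rows(len(leaf_names)).reindex(leaf_names)
    if set(leaf_names) != set(lineages.index):
        raise ValueError("tree leaves and lineage table disagree")
    lineages = lineages.loc[leaf_names]
    rng = _substream(config.seed, "counts")
    means = _enterotype_means(config, lineages, rng)
    n, k = config.n_samples, len(means)
    labels = rng.choice(k, size=n, p=np.asarray(config.enterotype_proportions))
    u = rng.standard_normal(n)
    depths = rng.integers(config.depth_range[0], config.depth_range[1] + 1, size=n)
    counts = np.empty((n, len(leaf_names)), dtype=np.int64)
    for i in range(n):
        conc = config.concentration * np.exp(config.diversity_scale * u[i])
        p = rng.dirichlet(conc * means[labels[i]])
        counts[i] = rng.multinomial(depths[i], p)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    table = FeatureTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=leaf_names),
        lineages=lineages,
    )
    weights = pd.Series(
        [PATTERN_WEIGHTS.get(f, 0.0) for f in FOOD_GROUPS[: config.n_food_groups]],
        index=FOOD_GROUPS[: config.n_food_groups],
    )
    truth = GroundTruth(
        enterotype_labels=pd.Series(labels, index=sample_ids),
        pattern_weights=weights,
        latent_diversity=pd.Series(u, index=sample_ids),
    )
    return table, truth


def generate_diet(
    config: StudyConfig, ground_truth: GroundTruth
) -> tuple[DietTable, CovariateTable]:
    """Log-normal intakes with an energy slope and the planted pattern effect.

    log intake = log mean + slope * (log energy - mean log energy)
    + diet_effect * weight * latent_diversity + noise.  Covariates are drawn
    independently except a planted sex -> alcohol effect (a confounding
    fixture for partial-correlation checks).
    """
    n = len(ground_truth.latent_diversity)
    sample_ids = list(ground_truth.latent_diversity.index)
    u = ground_truth.latent_diversity.to_numpy()
    rng = _substream(config.seed, "diet")
    loge = rng.normal(np.log(2000.0), 0.2, size=n)
    energy = np.exp(loge)
    foods = FOOD_GROUPS[: config.n_food_groups]
    means = np.array(FOOD_MEANS[: config.n_food_groups], dtype=float)
    slopes = rng.uniform(0.5, 1.0, size=len(foods))
    w = ground_truth.pattern_weights.reindex(foods).to_numpy()
    eps = rng.normal(0.0, 0.4, size=(n, len(foods)))
    logx = (
        np.log(means)[None, :]
        + np.outer(loge - loge.mean(), slopes)
        + config.diet_effect * np.outer(u, w)
        + eps
    )
    intakes = pd.DataFrame(np.exp(logx), index=sample_ids, columns=foods)

    crng = _substream(config.seed, "covariates")
    sex = np.where(crng.random(n) < 0.49, "M", "F")
    age = np.clip(np.round(crng.normal(30, 9, size=n)), 18, 58).astype(int)
    bmi = np.round(np.clip(crng.normal(22.9, 2.5, size=n), 18.5, 29.9), 1)
    supplement = np.where(crng.random(n) < 0.35, "yes", "no")
    activity = np.where(crng.random(n) < 0.41, "yes", "no")
    smoking = np.where(crng.random(n) < 0.24, "ever", "never")
    batch = crng.integers(1, 9, size=n)
    alcohol = np.exp(crng.normal(1.2 + 0.9 * (sex == "M"), 0.8, size=n))
    covariates = CovariateTable(
        pd.DataFrame(
            {"sex": sex, "age": age, "bmi": bmi, "supplement_use": supplement,
             "physical_activity": activity, "smoking_status": smoking,
             "batch": batch},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    diet = DietTable(
        intakes=intakes,
        total_energy=pd.Series(energy, index=sample_ids),
        alcohol=pd.Series(alcohol, index=sample_ids),
    )
    return diet, covariates


def generate_study(config: StudyConfig):
    """Full synthetic study: (tree, feature table, diet, covariates, truth)."""
    tree, lineages = generate_tree(config.n_taxa, seed=config.seed)
    table, truth = generate_counts(config, tree, lineages)
    diet, covariates = generate_diet(config, truth)
    return tree, table, diet, covariates, truth


def write_study(config: StudyConfig, outdir) -> dict[str, str]:
    """Serialize the four pipeline inputs plus the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, table, diet, covariates, truth = generate_study(config)
    paths = {
        "feature_table": outdir / "feature_table.tsv",
        "tree": outdir / "tree.nwk",
        "diet": outdir / "diet.csv",
        "covariates": outdir / "covariates.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_feature_table(table, paths["feature_table"])
    write_tree(tree, paths["tree"])
    write_diet(diet, paths["diet"])
    write_covariates(covariates, paths["covariates"])
    payload = {
        "enterotype_labels": truth.enterotype_labels.to_dict(),
        "pattern_weights": truth.pattern_weights.to_dict(),
        "latent_diversity": truth.latent_diversity.to_dict(),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
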