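"""End-to-end orchestration of the diet-microbiome analysis graph.

Stages: ingest -> rarefy -> aggregate (phylum, genus) -> proportions ->
zero-replace -> clr -> alpha indices -> beta matrices -> diet log/energy
adjustment -> phylum-diet correlation screen -> RRR dietary pattern and
pattern-taxa screen -> enterotypes per beta metric with diet contrasts.
Every stage writes a TSV plus a JSON provenance record; all randomness flows
from one root seed via named sub-streams.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diversity, enterotype, io, pattern, preprocess, stats
from .simulate import StudyConfig, write_study

COVARIATE_COLUMNS = ["sex", "age", "bmi", "supplement_use", "physical_activity",
                     "smoking_status", "batch"]


@dataclass
class PipelineConfig:
    """Everything `run_all` needs; defaults follow the study's analysis plan."""

    feature_table: str | None = None
    tree: str | None = None
    diet: str | None = None
    covariates: str | None = None
    synthetic: StudyConfig | None = None
    output_dir: str = "results"
    rarefaction_depth: int | None = None  # None: cohort minimum
    screen_ranks: tuple = ("phylum", "genus")
    alpha_response: str = "shannon"
    beta_metrics: tuple = ("weighted_unifrac", "bray_curtis")
    k: int = 3
    k_max: int = 8
    gap_b: int = 50
    loading_threshold: float = 0.3
    prior_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.loading_threshold < 1):
            raise ValueError("loading threshold must lie in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.alpha_response not in ("chao1", "shannon", "faith_pd"):
            raise ValueError(f"unknown alpha response {self.alpha_response!r}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            for key in ("enterotype_proportions", "dominant_taxa", "depth_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            raw["synthetic"] = StudyConfig(**syn)
        for key in ("screen_ranks", "beta_metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(root: int, name: str) -> int:
    return int((int(root) % 2**31) ^ zlib.crc32(name.encode()) % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis graph; returns a report of output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "gutdiet_version": __version__,
        "seed": config.seed,
        "parameters": {
            "rarefaction_depth": config.rarefaction_depth,
            "alpha_response": config.alpha_response,
            "beta_metrics": list(config.beta_metrics),
            "k": config.k,
            "loading_threshold": config.loading_threshold,
            "prior_strength": config.prior_strength,
        },
        "stages": [],
    }

    # --- ingest -----------------------------------------------------------
    if config.synthetic is not None:
        simdir = out / "synthetic_inputs"
        paths = write_study(config.synthetic, simdir)
        config = PipelineConfig(**{
            **{f.name: getattr(config, f.name) for f in
               config.__dataclass_fields__.values()},
            "feature_table": paths["feature_table"], "tree": paths["tree"],
            "diet": paths["diet"], "covariates": paths["covariates"],
            "synthetic": None,
        })
    inputs = ("feature_table", "tree", "diet", "covariates")
    missing = [name for name in inputs if getattr(config, name) is None]
    if missing:
        raise io.JoinError(f"pipeline stage 'ingest': missing inputs {missing}")
    for name in inputs:
        p = getattr(config, name)
        provenance[f"input_{name}"] = {"path": str(p), "sha256": _sha256(Path(p))}
    table = io.read_feature_table(config.feature_table)
    tree = io.read_tree(config.tree)
    diet = io.read_diet(config.diet)
    covariates = io.read_covariates(config.covariates)

    shared = io.align_samples(table, diet, covariates)
    table = io.FeatureTable(counts=table.counts.loc[shared], lineages=table.lineages)
    diet = io.DietTable(
        intakes=diet.intakes.loc[shared],
        total_energy=diet.total_energy.loc[shared],
        alcohol=diet.alcohol.loc[shared],
    )
    cov_df = covariates.data.loc[shared, COVARIATE_COLUMNS]
    # batch is a label, not a quantity: force indicator expansion downstream
    cov_df = cov_df.assign(batch=cov_df["batch"].astype(str))

    def save(df: pd.DataFrame, name: str, stage: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t")
        provenance["stages"].append({"stage": stage, "output": name})

    # --- standardize ------------------------------------------------------
    rare = preprocess.rarefy(table, config.rarefaction_depth,
                             seed=_stage_seed(config.seed, "rarefy"))
    shared = rare.sample_ids
    diet_int = diet.intakes.loc[shared]
    cov_df = cov_df.loc[shared]
    save(rare.counts, "rarefied_counts.tsv", "rarefy")

    by_rank = {r: preprocess.aggregate(rare, r) for r in config.screen_ranks}
    clr_by_rank = {
        r: preprocess.clr(preprocess.replace_zeros(
            preprocess.to_proportions(t), prior_strength=config.prior_strength))
        for r, t in by_rank.items()
    }
    for r, cm in clr_by_rank.items():
        save(cm.values, f"clr_{r}.tsv", f"clr[{r}]")

    # --- alpha / beta -----------------------------------------------------
    alpha = diversity.alpha_diversity(rare, tree)
    save(alpha, "alpha_diversity.tsv", "alpha")
    beta = {m: diversity.beta_diversity(rare, tree, m) for m in config.beta_metrics}
    for m, dm in beta.items():
        io.write_distance_matrix(dm, out / f"beta_{m}.tsv")
        provenance["stages"].append({"stage": f"beta[{m}]", "output": f"beta_{m}.tsv"})

    # --- diet adjustment + phylum screen ----------------------------------
    adj = preprocess.log_energy_adjust(io.DietTable(
        intakes=diet_int, total_energy=diet.total_energy.loc[shared],
        alcohol=diet.alcohol.loc[shared]))
    save(adj, "diet_adjusted.tsv", "adjust-diet")

    phylum_clr = clr_by_rank.get("phylum")
    screen_left = phylum_clr.values.copy()
    if {"Firmicutes", "Bacteroidetes"} <= set(screen_left.columns):
        screen_left["FB_log_ratio"] = preprocess.clr_log_ratio(
            phylum_clr, "Firmicutes", "Bacteroidetes")
    diet_screen = stats.correlation_screen(screen_left, adj, cov_df,
                                           fdr_scope="per_left")
    save(diet_screen.set_index(["left", "right"]),
         "phylum_diet_screen.tsv", "screen[phylum-diet]")

    # --- dietary pattern --------------------------------------------------
    response = np.log(alpha.loc[shared, config.alpha_response])
    rrr = pattern.fit_rrr(adj, response)
    save(pd.DataFrame({"weight": rrr.weights, "loading": rrr.loadings}),
         "pattern_loadings.tsv", "derive-pattern")
    save(rrr.scores.to_frame("pattern_score"), "pattern_scores.tsv",
         "derive-pattern")
    contributors = pattern.main_contributors(rrr, config.loading_threshold)
    genus_clr = clr_by_rank.get("genus", phylum_clr)
    taxa_screen = pattern.pattern_taxa_screen(rrr.scores, genus_clr, cov_df)
    save(taxa_screen.set_index("taxon"), "pattern_taxa_screen.tsv",
         "screen[pattern-taxa]")

    # --- enterotypes ------------------------------------------------------
    genus_props = preprocess.to_proportions(by_rank.get("genus", by_rank["phylum"]))
    labels_by_metric = {}
    for m, dm in beta.items():
        ent = enterotype.discover_enterotypes(
            dm, genus_props, k=config.k, k_max=config.k_max, B=config.gap_b,
            seed=_stage_seed(config.seed, f"enterotype[{m}]"))
        labels_by_metric[m] = ent
        named = ent.labels.map(ent.dominant_genus)
        save(pd.DataFrame({"cluster": ent.labels, "enterotype": named}),
             f"enterotype_labels_{m}.tsv", f"enterotype[{m}]")
        save(ent.diagnostics, f"enterotype_diagnostics_{m}.tsv",
             f"enterotype[{m}]")
        coords = pd.DataFrame(ent.pcoa.coordinates, index=ent.pcoa.sample_ids,
                              columns=[f"PCo{i+1}" for i in
                                       range(ent.pcoa.coordinates.shape[1])])
        save(coords, f"pcoa_{m}.tsv", f"enterotype[{m}]")
        variables = adj.copy()
        variables.insert(0, "pattern_score", rrr.scores)
        contrasts = enterotype.enterotype_contrasts(ent, variables, cov_df)
        save(contrasts, f"enterotype_contrasts_{m}.tsv", f"contrasts[{m}]")

    report = {
        "n_samples": len(shared),
        "rarefaction_depth": int(rare.sample_totals().iloc[0]),
        "pattern_response_r2": rrr.response_r2,
        "main_contributors": contributors,
        "dominant_genera": {m: e.dominant_genus for m, e in labels_by_metric.items()},
        "outputs": sorted(s["output"] for s in provenance["stages"]),
    }
    provenance["report"] = report
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True, default=str)
    return report
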