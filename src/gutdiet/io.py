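"""Readers, writers and validated in-memory containers for every on-disk artifact.

Canonical formats are all plain text: feature table and distance matrix as TSV,
phylogeny as Newick, diet and covariates as CSV with a ``sample_id`` key column.
Every writer produces a file its reader accepts (round-trip contract).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

RANKS = ("phylum", "class", "order", "family", "genus")
RANK_PREFIXES = {"p": "phylum", "c": "class", "o": "order", "f": "family", "g": "genus"}
UNCLASSIFIED = "unclassified"

COVARIATE_SCHEMA = {
    "sex": {"M", "F"},
    "supplement_use": {"yes", "no"},
    "physical_activity": {"yes", "no"},
    "smoking_status": {"ever", "never"},
}


class FormatError(ValueError):
    """A file violates its declared schema."""


class JoinError(ValueError):
    """Sample identifiers do not line up across tables."""


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class FeatureTable:
    """Sample x taxon count table with per-taxon taxonomic lineages.

    ``counts`` is an integer DataFrame indexed by sample id with taxon-id
    columns; ``lineages`` maps each taxon to a name at each rank in
    :data:`RANKS` (``"unclassified"`` where unassigned).
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "sample id")
        _check_unique(self.counts.columns, "taxon id")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"taxon {self.counts.columns[j]!r}"
            )
        missing = self.counts.columns.difference(self.lineages.index)
        if len(missing):
            raise FormatError(f"taxa without lineage: {missing.tolist()}")
        self.lineages = self.lineages.reindex(self.counts.columns).fillna(UNCLASSIFIED)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class DietTable:
    """Sample x food-group intakes in g/day plus total energy and alcohol."""

    intakes: pd.DataFrame
    total_energy: pd.Series
    alcohol: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.intakes.index, "sample id")
        if (self.intakes.to_numpy() < 0).any():
            raise FormatError("negative intake")
        if (self.total_energy <= 0).any():
            raise FormatError("non-positive total energy")
        if (self.alcohol < 0).any():
            raise FormatError("negative alcohol intake")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intakes.index)

    @property
    def food_groups(self) -> list[str]:
        return list(self.intakes.columns)


@dataclass
class CovariateTable:
    """Per-sample covariates: sex, age, BMI, supplement use, activity, smoking, batch."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample id")
        for col, levels in COVARIATE_SCHEMA.items():
            if col in self.data.columns:
                bad = set(self.data[col].astype(str)) - levels
                if bad:
                    raise FormatError(f"covariate {col!r}: invalid levels {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def align_samples(*indexed) -> list:
    """Intersect sample ids across tables, preserving the first table's order.

    Imperfect overlap is resolved by intersection with a logged count of
    dropped samples; an empty intersection is a :class:`JoinError`.
    """
    ids = [pd.Index(getattr(t, "sample_ids", t)) for t in indexed]
    common = ids[0]
    for other in ids[1:]:
        common = common.intersection(other)
    common = [s for s in ids[0] if s in set(common)]
    if not common:
        offenders = [list(i[:5]) for i in ids]
        raise JoinError(f"no samples shared across tables; leading ids per table: {offenders}")
    dropped = sum(len(i) - len(common) for i in ids)
    if dropped:
        logger.info("align_samples: dropped %d non-shared sample rows", dropped)
    return common


# ---------------------------------------------------------------------------
# feature table TSV: rows = taxa, columns = samples, plus a 'lineage' column
# with Greengenes-style prefixes p__;c__;o__;f__;g__ ('r__' when unassigned).


def format_lineage(lineage: pd.Series) -> str:
    parts = []
    for prefix, rank in RANK_PREFIXES.items():
        name = lineage.get(rank, UNCLASSIFIED)
        parts.append(f"{prefix}__{'' if name == UNCLASSIFIED else name}")
    return ";".join(parts)


def parse_lineage(text: str) -> dict[str, str]:
    out = dict.fromkeys(RANKS, UNCLASSIFIED)
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        if "__" not in token:
            raise FormatError(f"lineage token {token!r} lacks a rank prefix")
        prefix, name = token.split("__", 1)
        rank = RANK_PREFIXES.get(prefix)
        if rank is None:
            raise FormatError(f"unknown rank prefix {prefix!r} in {text!r}")
        out[rank] = name or UNCLASSIFIED
    return out


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.counts.T.copy()
    df.insert(0, "lineage", [format_lineage(table.lineages.loc[t]) for t in df.index])
    df.to_csv(path, sep="\t", index_label="taxon_id")


def read_feature_table(path, samples_as_rows: bool = False) -> FeatureTable:
    """Read a TSV feature table (rows = taxa by convention; flag flips it)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    lineage_col = df.pop("lineage") if "lineage" in df.columns else None
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise FormatError(f"non-numeric count at row {num.index[i]!r}, column {num.columns[j]!r}")
    vals = num.to_numpy()
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise FormatError(f"negative count at row {num.index[i]!r}, column {num.columns[j]!r}")
    if not np.allclose(vals, np.round(vals)):
        i, j = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise FormatError(f"non-integer count at row {num.index[i]!r}, column {num.columns[j]!r}")
    counts = num.astype(np.int64)
    if not samples_as_rows:
        # file convention: rows are taxa, columns are samples
        counts = counts.T
    taxa = counts.columns
    if lineage_col is not None:
        lineages = pd.DataFrame([parse_lineage(lineage_col.get(t, "")) for t in taxa], index=taxa)
    else:
        lineages = pd.DataFrame(UNCLASSIFIED, index=taxa, columns=list(RANKS))
    counts.index.name = counts.columns.name = None
    lineages.index.name = None
    return FeatureTable(counts=counts, lineages=lineages)


# ---------------------------------------------------------------------------
# tree, diet, covariates, distance matrix


def read_tree(path) -> skbio.TreeNode:
    tree = skbio.TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    _check_unique(names, "leaf name")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(f"missing branch length above node {node.name!r}")
        if node.length < 0:
            raise FormatError(f"negative branch length above node {node.name!r}")
    return tree


def write_tree(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_diet(path) -> DietTable:
    df = pd.read_csv(path, index_col="sample_id")
    for col in ("total_energy", "alcohol"):
        if col not in df.columns:
            raise FormatError(f"diet table missing required column {col!r}")
    energy = df.pop("total_energy").astype(float)
    alcohol = df.pop("alcohol").astype(float)
    df.index.name = energy.index.name = alcohol.index.name = None
    return DietTable(intakes=df.astype(float), total_energy=energy, alcohol=alcohol)


def write_diet(diet: DietTable, path) -> None:
    df = diet.intakes.copy()
    df["total_energy"] = diet.total_energy
    df["alcohol"] = diet.alcohol
    df.to_csv(path, index_label="sample_id")


def read_covariates(path) -> CovariateTable:
    return CovariateTable(pd.read_csv(path, index_col="sample_id"))


def write_covariates(cov: CovariateTable, path) -> None:
    cov.data.to_csv(path, index_label="sample_id")


def read_distance_matrix(path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row and column ids differ")
    vals = df.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise FormatError("distance matrix not symmetric within 1e-10")
    if (vals < 0).any():
        raise FormatError("negative distance")
    return skbio.DistanceMatrix((vals + vals.T) / 2.0, ids=list(df.index))


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def validate_inputs(feature_path=None, tree_path=None, diet_path=None, covariate_path=None) -> dict:
    """Load each provided input, collecting a schema report per file."""
    report: dict[str, str] = {}
    loaders = {
        "feature_table": (feature_path, read_feature_table),
        "tree": (tree_path, read_tree),
        "diet": (diet_path, read_diet),
        "covariates": (covariate_path, read_covariates),
    }
    objs: dict[str, object] = {}
    for name, (path, loader) in loaders.items():
        if path is None:
            continue
        try:
            objs[name] = loader(path)
            report[name] = "ok"
        except (FormatError, JoinError, ValueError) as exc:
            report[name] = f"ERROR: {exc}"
    tabular = [o for k, o in objs.items() if k != "tree"]
    if len(tabular) > 1 and all(v == "ok" for v in report.values()):
        try:
            shared = align_samples(*tabular)
            report["join"] = f"ok ({len(shared)} shared samples)"
        except JoinError as exc:
            report["join"] = f"ERROR: {exc}"
    return report
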