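import numpy as np
import pandas as pd
import pytest
import skbio

from gutdiet.io import RANKS, FeatureTable


def make_table(counts, sample_ids=None, taxon_ids=None, lineages=None) -> FeatureTable:
    counts = np.asarray(counts)
    n, d = counts.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    taxon_ids = taxon_ids or [f"T{j}" for j in range(d)]
    df = pd.DataFrame(counts, index=sample_ids, columns=taxon_ids)
    if lineages is None:
        lin = pd.DataFrame("unclassified", index=taxon_ids, columns=list(RANKS))
    else:
        lin = pd.DataFrame(lineages).T.reindex(columns=list(RANKS)).fillna("unclassified")
    return FeatureTable(counts=df, lineages=lin)


def random_tree(leaf_names, rng) -> skbio.TreeNode:
    """Random rooted binary tree with uniform(0.1, 1) branch lengths."""
    nodes = [skbio.TreeNode(name=n, length=float(rng.uniform(0.1, 1.0)))
             for n in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = skbio.TreeNode(children=[a, b],
                                length=float(rng.uniform(0.1, 1.0)))
        nodes.append(parent)
    nodes[0].length = None
    return nodes[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
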