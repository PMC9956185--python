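import dendropy
import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import OTUTable, SampleMetadata
from ecoassembly.matrices import PairwiseMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    return OTUTable(
        ["OTU_1", "OTU_2", "OTU_3"],
        ["s1", "s2"],
        np.array([[5.0, 0.0], [3.0, 2.0], [0.0, 8.0]]),
    )


def random_table(rng, n_taxa=20, n_samples=6, depth=200) -> OTUTable:
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.column_stack([rng.multinomial(depth, p) for _ in range(n_samples)]).astype(float)
    counts[0, :] += 1  # no all-zero column
    return OTUTable(
        [f"OTU_{i + 1}" for i in range(n_taxa)],
        [f"s{j + 1}" for j in range(n_samples)],
        counts,
    )


def patchy_table(rng, n_taxa=12, n_samples=5, depth=200, present_frac=0.6, taxa=None) -> OTUTable:
    """Counts table where each sample occupies a random subset of taxa, so
    community supports differ between samples (needed for non-degenerate
    nearest-taxon statistics)."""
    taxa = taxa or [f"T{i + 1}" for i in range(n_taxa)]
    counts = np.zeros((n_taxa, n_samples))
    for j in range(n_samples):
        k = max(2, int(round(present_frac * n_taxa)))
        idx = rng.choice(n_taxa, size=k, replace=False)
        counts[idx, j] = rng.multinomial(depth, rng.dirichlet(np.ones(k)))
        if counts[:, j].sum() == 0:
            counts[idx[0], j] = 1
    return OTUTable(taxa, [f"s{j + 1}" for j in range(n_samples)], counts)


@pytest.fixture
def meta_df():
    rows = []
    for i in range(6):
        rows.append(
            {
                "sample_id": f"s{i + 1}",
                "site_id": f"site{i // 2 + 1}",
                "layer": "surface" if i % 2 == 0 else "bottom",
                "latitude": 22.0 + 0.1 * i,
                "longitude": 113.0 + 0.2 * i,
                "DO": [6.5, 1.4, 0.23, 2.0, 7.8, 3.1][i],
                "salinity": 2.0 + 5.0 * i,
                "turbidity": 4.0 + i,
                "TALK": 100.0 + 3 * i,
                "depth": 0.5 if i % 2 == 0 else 10.0 + i,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def meta(meta_df):
    return SampleMetadata(meta_df)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture
def four_tip_tree():
    # ((A:1,B:2):0.5,(C:0.75,D:0.25):1.5)
    return tree_from_newick("((A:1.0,B:2.0):0.5,(C:0.75,D:0.25):1.5);")


@pytest.fixture
def four_tip_distances(four_tip_tree):
    from ecoassembly.assembly import patristic_distances

    return patristic_distances(four_tip_tree, ["A", "B", "C", "D"])


def random_ultrametric_tree(rng, n_tips: int, height: float = 1.0) -> dendropy.Tree:
    """Pure-birth coalescent-like ultrametric tree built by random joins."""
    import io as _io

    nodes = [(f"T{i + 1}", 0.0) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        h = max(ha, hb) + float(rng.uniform(0.05, 0.3))
        merged = (f"({na}:{h - ha},{nb}:{h - hb})", h)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    newick, h = nodes[0]
    scale = height / h
    tree = tree_from_newick(newick + ";")
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return tree


def pairwise_from_points(points: np.ndarray, labels=None) -> PairwiseMatrix:
    from scipy.spatial.distance import pdist, squareform

    n = len(points)
    labels = labels or [f"p{i}" for i in range(n)]
    return PairwiseMatrix(labels, squareform(pdist(points)), "geographic_km")
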