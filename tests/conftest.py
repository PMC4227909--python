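"""Shared fixtures and independent oracles.

The oracles here recompute quantities by brute force (path enumeration,
exhaustive subset enumeration) so the implementation under test is checked
against an independent route, not against itself.
"""

from __future__ import annotations

from itertools import combinations
from math import sqrt

import numpy as np
import pytest

import commphylo as cp

# ((A,B),(C,D)) with unit branches: d(A,B)=2, d(A,C)=4
BALANCED4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def balanced4():
    return cp.read_newick(BALANCED4)


@pytest.fixture
def balanced4_D(balanced4):
    return cp.patristic_matrix(balanced4)


@pytest.fixture
def yule50():
    return cp.simulate_yule(50, seed=424242)


def brute_patristic(phy: cp.Phylogeny, a: str, b: str) -> float:
    """Path-sum distance via explicit root paths (independent of the
    distance-matrix implementation)."""

    def root_path(label):
        node = next(
            lf for lf in phy.tree.leaf_node_iter() if lf.taxon.label == label
        )
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path

    pa, pb = root_path(a), root_path(b)
    shared = {id(n) for n in pa} & {id(n) for n in pb}
    dist = sum(n.edge.length or 0.0 for n in pa if id(n) not in shared)
    dist += sum(n.edge.length or 0.0 for n in pb if id(n) not in shared)
    return dist


def brute_mpd(sample, D: cp.DistanceMatrix) -> float:
    pairs = list(combinations(sorted(sample), 2))
    lookup = {lb: i for i, lb in enumerate(D.labels)}
    return sum(D.values[lookup[a], lookup[b]] for a, b in pairs) / len(pairs)


def brute_mntd(sample, D: cp.DistanceMatrix) -> float:
    sample = sorted(sample)
    lookup = {lb: i for i, lb in enumerate(D.labels)}
    total = 0.0
    for a in sample:
        total += min(
            D.values[lookup[a], lookup[b]] for b in sample if b != a
        )
    return total / len(sample)


def exhaustive_null(pool_labels, k, D, metric):
    """Exact null mean/sd of a metric over all k-subsets of the pool."""
    fn = brute_mpd if metric == "mpd" else brute_mntd
    values = [fn(set(sub), D) for sub in combinations(sorted(pool_labels), k)]
    values = np.asarray(values)
    mean = values.mean()
    sd = values.std(ddof=0)  # population over the complete enumeration
    return mean, sd, values


def make_taxonomy(rows):
    """rows: list of (species, genus, family, order)."""
    import pandas as pd

    return cp.TaxonomyTable(
        pd.DataFrame(rows, columns=["species", "genus", "family", "order"])
    )


def make_community(site_species: dict[str, set[str]]):
    import pandas as pd

    species = sorted({sp for s in site_species.values() for sp in s})
    matrix = pd.DataFrame(
        [[1 if sp in members else 0 for sp in species]
         for members in site_species.values()],
        index=list(site_species),
        columns=species,
    )
    return cp.CommunityTable(matrix)
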