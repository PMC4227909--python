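"""Per-node clade over/under-representation test.

For every internal node of the phylogeny (pruned to the species pool), the
number of a site's species descending from that node is compared with its
distribution under random assemblages of equal richness drawn uniformly from
the pool.  Nodes whose observed count exceeds the upper null quantile are
flagged MORE (the clade contributes more species to the site than expected);
nodes below the lower quantile are flagged FEWER.  Because the null draw is
uniform without replacement, each node's count follows a hypergeometric
distribution with population |pool|, successes = the node's descendant-tip
count, and draws = site richness; the Monte-Carlo quantiles converge to the
hypergeometric ones.

Per-node tests are NOT corrected for multiplicity, matching the classic
algorithm; counts are small integers, so the nominal alpha is rarely
attainable exactly and the attainable per-node alpha is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .community_data import SpeciesPool
from .phylo_io import Phylogeny, TaxonomyTable
from .structure import DegenerateNullError, _substream

__all__ = ["NodeEnrichment", "nodesig", "nodesig_summary"]


@dataclass(frozen=True)
class NodeEnrichment:
    """Enrichment verdict for one internal node of the pool-pruned tree."""

    node_id: int          # preorder index in the pool-pruned tree
    label: str            # smallest taxonomic rank covering the node, if known
    n_node_tips: int      # descendant tips (within the pool)
    observed: int         # sample species descending from the node
    q_low: float          # alpha/2 null quantile of the count
    q_high: float         # 1 - alpha/2 null quantile
    verdict: str          # MORE | FEWER | ns
    attainable_alpha: float  # empirical P(count outside (q_low, q_high))
    is_root: bool


def nodesig(
    sample: Iterable[str],
    pool: SpeciesPool,
    phy: Phylogeny,
    n_iter: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    site: str = "",
    taxonomy: TaxonomyTable | None = None,
) -> list[NodeEnrichment]:
    """Score every internal node of the tree pruned to `pool`.

    Verdicts use strict inequality beyond the empirical null quantiles:
    MORE iff observed > q(1-alpha/2), FEWER iff observed < q(alpha/2).
    The root always holds the whole sample in every draw and is ns.
    """
    sample = set(sample)
    if not sample <= pool.species:
        raise ValueError(f"sample not contained in pool {pool.name!r}")
    if not pool.species <= set(phy.tip_labels):
        missing = sorted(pool.species - set(phy.tip_labels))
        raise ValueError(f"pool species absent from tree: {missing}")
    if len(pool.species) <= len(sample):
        raise DegenerateNullError(
            "pool must be strictly larger than the sample"
        )
    pruned = phy.prune_to(pool.species)
    pool_labels = sorted(pool.species)
    pos = {lb: i for i, lb in enumerate(pool_labels)}
    n_pool = len(pool_labels)

    internal = pruned.internal_nodes()  # preorder; [0] is the root
    membership = np.zeros((len(internal), n_pool), dtype=bool)
    for k, nd in enumerate(internal):
        for lb in Phylogeny.leaf_labels_under(nd):
            membership[k, pos[lb]] = True

    sample_vec = np.zeros(n_pool, dtype=bool)
    for lb in sample:
        sample_vec[pos[lb]] = True
    observed = membership.astype(np.int64) @ sample_vec.astype(np.int64)

    rng = _substream(seed, site, pool.name, "nodesig")
    richness = len(sample)
    perms = rng.permuted(
        np.broadcast_to(np.arange(n_pool), (n_iter, n_pool)), axis=1
    )
    draws = perms[:, :richness]  # (n_iter, richness)
    indicator = np.zeros((n_pool, n_iter), dtype=np.uint8)
    indicator[draws.T, np.arange(n_iter)[None, :].repeat(richness, axis=0)] = 1
    null_counts = membership.astype(np.uint16) @ indicator  # (n_nodes, n_iter)

    q_low = np.quantile(null_counts, alpha / 2, axis=1)
    q_high = np.quantile(null_counts, 1 - alpha / 2, axis=1)

    results = []
    for k, nd in enumerate(internal):
        is_root = nd is pruned.tree.seed_node
        if is_root:
            verdict = "ns"
        elif observed[k] > q_high[k]:
            verdict = "MORE"
        elif observed[k] < q_low[k]:
            verdict = "FEWER"
        else:
            verdict = "ns"
        attainable = float(
            np.mean((null_counts[k] > q_high[k]) | (null_counts[k] < q_low[k]))
        )
        label = ""
        if taxonomy is not None:
            covering = taxonomy.smallest_covering_rank(
                Phylogeny.leaf_labels_under(nd)
            )
            if covering is not None:
                label = f"{covering[1]} ({covering[0]})"
        results.append(
            NodeEnrichment(
                node_id=k,
                label=label,
                n_node_tips=int(membership[k].sum()),
                observed=int(observed[k]),
                q_low=float(q_low[k]),
                q_high=float(q_high[k]),
                verdict=verdict,
                attainable_alpha=attainable,
                is_root=is_root,
            )
        )
    return results


def nodesig_summary(results: Sequence[NodeEnrichment]) -> dict[str, list[str]]:
    """Two readable columns per site: over- and under-represented clades."""
    over = [r.label or f"node {r.node_id}" for r in results if r.verdict == "MORE"]
    under = [r.label or f"node {r.node_id}" for r in results if r.verdict == "FEWER"]
    return {"overrepresented": over, "underrepresented": under}
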