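"""Synthetic phylogenies, taxonomies, traits and communities with known
assembly structure.

The generator emulates the inputs of a regional community-phylogenetics
study: an ultrametric phylogeny for the regional flora (pure-birth), a rank
taxonomy cut from tree depth, a single phylogenetically conserved trait
(Brownian motion — standing in for, e.g., drought tolerance along a water
availability gradient), and site x species presence/absence communities
assembled under one of three mechanisms:

* neutral    — uniform draws from the species list;
* filtering  — environmental filtering: inclusion probability falls off as a
  Gaussian in the distance between a species' trait and the site's
  environmental optimum (window width w); sites in the same group (e.g. the
  same soil type) share an optimum, which induces soil-pool-like nesting;
* repulsion  — limiting similarity: species too close (in patristic
  distance) to an already-admitted member are rejected.

Filtering produces phylogenetically clustered communities (positive NRI),
repulsion produces even ones (negative NRI), neutral communities are the
null; these ground truths are what the pipeline's tests recover.

All randomness flows from a single seed through named substreams (tree,
traits, per-site assembly), so scenarios are reproducible and independent of
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo_io import CommunityTable, Phylogeny, PoolAssignment, TaxonomyTable
from .structure import DistanceMatrix, _substream, patristic_matrix

__all__ = [
    "AssemblyScenario",
    "simulate_yule",
    "evolve_bm",
    "assemble",
    "synth_taxonomy",
    "simulate_bundle",
    "collapse_random_nodes",
    "collapse_below_age",
]


def simulate_yule(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> Phylogeny:
    """Pure-birth (Yule) tree grown from a crown pair to `n_tips` extant
    lineages, then extended by one final exponential waiting time at rate
    n_tips * birth_rate (the tree is observed just before the next
    speciation).  Branch lengths are in time units; the tree is ultrametric;
    crown age has expectation sum_{k=2..n} 1/(k*lambda).

    Random integer supports in [50, 100] are attached to internal nodes so
    diagnostics have something to chew on.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _substream(seed, "yule")
    tree = dendropy.Tree()
    root = tree.seed_node
    left, right = dendropy.Node(), dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    birth_times = {left: 0.0, right: 0.0}  # time the lineage was born
    active = [left, right]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        parent = active[rng.integers(k)]
        parent.edge.length = t - birth_times.pop(parent)
        children = [dendropy.Node(), dendropy.Node()]
        for ch in children:
            parent.add_child(ch)
            birth_times[ch] = t
        active.remove(parent)
        active.extend(children)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    ns = dendropy.TaxonNamespace()
    width = len(str(n_tips))
    for i, lf in enumerate(active):
        lf.edge.length = t - birth_times[lf]
        lf.taxon = ns.new_taxon(f"t{i + 1:0{width}d}")
    tree.taxon_namespace = ns
    for nd in tree.preorder_node_iter():
        if not nd.is_leaf():
            nd.label = str(int(rng.integers(50, 101)))
    tree.seed_node.edge.length = None
    return Phylogeny(tree, has_branch_lengths=True)


def evolve_bm(
    phy: Phylogeny,
    sigma2: float = 1.0,
    seed: int = 0,
    conserve_age: float = 0.0,
) -> pd.Series:
    """Brownian-motion trait from a root value of 0.

    Each edge adds an independent Normal(0, sigma2 * edge length) increment;
    tip variance is sigma2 * depth and the covariance of two tips is sigma2
    times their shared path length.

    conserve_age > 0 freezes the trait over the part of every branch younger
    than that age (time before present), so all members of a clade whose
    stem crosses the conservation age share one niche value.  This is the
    niche-conservatism variant used by filtering scenarios: with pure BM the
    trait's extreme tail is phylogenetically scattered (terminal branches
    contribute independent variance), and a trait-window filter then selects
    communities that are clustered near the tips but not tree-wide.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    if conserve_age < 0:
        raise ValueError("conserve_age must be nonnegative")
    rng = _substream(seed, "bm")
    ages = phy.node_ages() if conserve_age > 0 else None
    values: dict[dendropy.Node, float] = {phy.tree.seed_node: 0.0}
    traits = {}
    for nd in phy.tree.preorder_node_iter():
        if nd is phy.tree.seed_node:
            continue
        if ages is None:
            effective = nd.edge.length or 0.0
        else:
            # only the part of the edge older than the conservation age evolves
            effective = max(
                0.0, ages[nd.parent_node] - max(ages[nd], conserve_age)
            )
        values[nd] = values[nd.parent_node] + rng.normal(
            0.0, np.sqrt(sigma2 * effective)
        )
        if nd.is_leaf():
            traits[nd.taxon.label] = values[nd]
    return pd.Series(traits).sort_index()


@dataclass(frozen=True)
class AssemblyScenario:
    """Study design for a set of simulated communities.

    site_groups maps site -> group (e.g. soil type); group_optima maps group
    -> environmental optimum on the trait axis.  filter_width is the
    Gaussian window w of the environmental filter, in trait units;
    repulsion_quantile sets the limiting-similarity threshold as a quantile
    of the species list's nearest-neighbor patristic distances (the natural
    scale for "too similar": pairwise distances on a large tree concentrate
    near twice its depth and make quantiles of all pairs infeasibly strict).
    """

    mode: str = "neutral"  # neutral | filtering | repulsion
    richness: dict[str, int] = field(default_factory=dict)  # site -> richness
    site_groups: dict[str, str] = field(default_factory=dict)
    group_optima: dict[str, float] = field(default_factory=dict)
    filter_width: float = 1.0
    repulsion_quantile: float = 0.9
    max_retries: int = 200

    def __post_init__(self):
        if self.mode not in ("neutral", "filtering", "repulsion"):
            raise ValueError(f"unknown assembly mode {self.mode!r}")
        if not self.richness:
            raise ValueError("scenario needs at least one site")
        if any(r < 2 for r in self.richness.values()):
            raise ValueError("site richness must be >= 2")
        if self.mode == "filtering":
            if self.filter_width <= 0:
                raise ValueError("filter width must be positive")
            for site in self.richness:
                group = self.site_groups.get(site)
                if group is None or group not in self.group_optima:
                    raise ValueError(
                        f"filtering mode: site {site!r} needs a group with an optimum"
                    )


def _assemble_site(
    rng: np.random.Generator,
    scenario: AssemblyScenario,
    site: str,
    species: list[str],
    traits: pd.Series | None,
    D: DistanceMatrix | None,
) -> set[str]:
    s = scenario.richness[site]
    n = len(species)
    if s > n:
        raise ValueError(f"site {site!r} richness {s} exceeds species list {n}")
    if scenario.mode == "neutral":
        idx = rng.choice(n, size=s, replace=False)
        return {species[i] for i in idx}
    if scenario.mode == "filtering":
        opt = scenario.group_optima[scenario.site_groups[site]]
        z = traits[species].to_numpy()
        logw = -((z - opt) ** 2) / (2 * scenario.filter_width**2)
        # Gumbel-max trick: top-s keys = weighted sample without replacement
        keys = logw + rng.gumbel(size=n)
        idx = np.argsort(keys)[-s:]
        return {species[i] for i in idx}
    # repulsion: sequential admission with a minimum-distance rule on the
    # nearest-neighbor distance scale
    D_sub = D.submatrix(species)
    offdiag = D_sub + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    threshold = np.quantile(offdiag.min(axis=1), scenario.repulsion_quantile)
    for _ in range(scenario.max_retries):
        order = rng.permutation(n)
        chosen: list[int] = []
        for i in order:
            if all(D_sub[i, j] > threshold for j in chosen):
                chosen.append(i)
                if len(chosen) == s:
                    return {species[i] for i in chosen}
    raise RuntimeError(
        f"repulsion assembly infeasible for site {site!r}: could not place "
        f"{s} species at min distance {threshold:.3g} "
        f"in {scenario.max_retries} attempts"
    )


def assemble(
    phy: Phylogeny,
    traits: pd.Series | None,
    scenario: AssemblyScenario,
    seed: int = 0,
) -> tuple[CommunityTable, PoolAssignment]:
    """Assemble presence/absence communities for every site of a scenario.

    Returns the community table and the site -> group assignment (sites
    without an explicit group go into a single group 'all').
    """
    species = sorted(phy.tip_labels)
    D = patristic_matrix(phy) if scenario.mode == "repulsion" else None
    if scenario.mode == "filtering" and traits is None:
        raise ValueError("filtering mode needs tip traits")
    rows = {}
    for site in sorted(scenario.richness):
        rng = _substream(seed, "assembly", site)
        members = _assemble_site(rng, scenario, site, species, traits, D)
        rows[site] = [1 if sp in members else 0 for sp in species]
    matrix = pd.DataFrame.from_dict(
        rows, orient="index", columns=species
    )
    comm = CommunityTable(matrix)
    groups = {
        site: scenario.site_groups.get(site, "all") for site in comm.sites
    }
    return comm, PoolAssignment(groups)


def synth_taxonomy(phy: Phylogeny, cut_ages: tuple[float, float, float]) -> TaxonomyTable:
    """Rank taxonomy from time slices of an ultrametric tree.

    cut_ages are three strictly increasing ages (time before present):
    genus, family, order.  Each rank's groups are the connected components
    of the tree sliced at that age — i.e. the clades whose stem crosses the
    slice — so the taxonomy is nested by construction.  A cut age of 0+
    makes every species its own genus; a cut above the root age yields a
    single group.
    """
    g, f, o = cut_ages
    if not (g < f < o):
        raise ValueError("cut ages must be strictly increasing (genus < family < order)")
    if any(c <= 0 for c in cut_ages):
        raise ValueError("cut ages must be positive")
    ages = phy.node_ages()

    def component_root(leaf: dendropy.Node, cut: float) -> dendropy.Node:
        # highest ancestor whose stem edge crosses the slice; the root if
        # the slice sits above the crown
        nd = leaf
        while nd.parent_node is not None and ages[nd.parent_node] < cut:
            nd = nd.parent_node
        return nd

    prefixes = {"genus": "g", "family": "f", "order": "o"}
    comp_ids: dict[str, dict[dendropy.Node, str]] = {r: {} for r in prefixes}
    records = []
    for leaf in phy.tree.leaf_node_iter():
        row = {"species": leaf.taxon.label}
        for rank, cut in zip(("genus", "family", "order"), (g, f, o)):
            comp = component_root(leaf, cut)
            ids = comp_ids[rank]
            if comp not in ids:
                ids[comp] = f"{prefixes[rank]}{len(ids) + 1}"
            row[rank] = ids[comp]
        records.append(row)
    df = pd.DataFrame.from_records(records).sort_values("species")
    return TaxonomyTable(df.reset_index(drop=True))


def collapse_random_nodes(
    phy: Phylogeny, fraction: float = 0.5, seed: int = 0
) -> Phylogeny:
    """Degrade resolution by collapsing a random fraction of internal
    non-root nodes into their parents (children inherit the collapsed
    node's edge length), emulating a poorly resolved reference phylogeny.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = _substream(seed, "collapse")
    from .phylo_io import read_newick, write_newick

    clone = read_newick(write_newick(phy))  # deep copy via round-trip
    candidates = [
        nd
        for nd in clone.internal_nodes()
        if nd.parent_node is not None
    ]
    k = int(round(fraction * len(candidates)))
    for idx in sorted(
        rng.choice(len(candidates), size=k, replace=False), reverse=True
    ):
        nd = candidates[idx]
        parent = nd.parent_node
        extra = nd.edge.length or 0.0
        for ch in list(nd.child_nodes()):
            nd.remove_child(ch)
            if ch.edge.length is not None:
                ch.edge.length += extra
            parent.add_child(ch)
        parent.remove_child(nd)
    return Phylogeny(clone.tree, clone.has_branch_lengths)


def collapse_below_age(phy: Phylogeny, age: float) -> Phylogeny:
    """Collapse every internal node younger than `age` into its parent,
    emulating a reference megatree: resolved at deep nodes, unresolved
    (star polytomies) within the shallow clades.  Tip depths are preserved
    (children inherit collapsed edge lengths)."""
    if age <= 0:
        raise ValueError("age must be positive")
    from .phylo_io import read_newick, write_newick

    clone = read_newick(write_newick(phy))
    ages = clone.node_ages()
    # postorder so children are reattached before their parent is examined
    for nd in list(clone.tree.postorder_internal_node_iter()):
        if nd.parent_node is None or ages[nd] >= age:
            continue
        parent = nd.parent_node
        extra = nd.edge.length or 0.0
        for ch in list(nd.child_nodes()):
            nd.remove_child(ch)
            if ch.edge.length is not None:
                ch.edge.length += extra
            parent.add_child(ch)
        parent.remove_child(nd)
    return Phylogeny(clone.tree, clone.has_branch_lengths)


def simulate_bundle(
    n_tips: int = 200,
    birth_rate: float = 1.0,
    sigma2: float = 1.0,
    scenario: AssemblyScenario | None = None,
    seed: int = 0,
    conserve_frac: float = 0.4,
) -> dict:
    """Tree + traits + taxonomy + community + pool assignment in one call.

    Default scenario: 15 sites of richness 30 in 4 groups under neutral
    assembly.  Taxonomy cuts sit at 15/40/70% of tree depth; the niche
    trait is conserved below conserve_frac of tree depth (0 = pure BM).
    """
    phy = simulate_yule(n_tips, birth_rate, seed=seed)
    traits = evolve_bm(
        phy, sigma2, seed=seed,
        conserve_age=conserve_frac * phy.max_depth(),
    )
    if scenario is None:
        sites = [f"s{i + 1:02d}" for i in range(15)]
        scenario = AssemblyScenario(
            mode="neutral",
            richness={s: 30 for s in sites},
            site_groups={s: f"grp{i % 4 + 1}" for i, s in enumerate(sites)},
        )
    comm, assign = assemble(phy, traits, scenario, seed=seed)
    depth = phy.max_depth()
    tax = synth_taxonomy(phy, (0.15 * depth, 0.40 * depth, 0.70 * depth))
    return {
        "phylogeny": phy,
        "traits": traits,
        "taxonomy": tax,
        "community": comm,
        "pools": assign,
        "scenario": scenario,
    }
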