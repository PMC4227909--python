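"""Phylogeny-quality diagnostics: resolution, bootstrap-support profiles,
monophyly of named taxonomic ranks, and within-group support averages.

Conventions
-----------
Trees are rooted; the root counts as an internal node.  A fully bifurcating
rooted tree with n tips has n-1 internal nodes, so resolution defaults to
n_internal / (n_tips - 1); an unrooted convention (n_internal - 1)/(n_tips - 2)
is selectable.  Constrained nodes (backbone-fixed, no bootstrap value) can be
masked out of support profiles.  Monophyly is MRCA-exact: a named group is
monophyletic iff the tip set under its MRCA equals the group exactly, so a
group sitting inside an unresolved polytomy together with intruders counts as
not monophyletic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .phylo_io import Phylogeny, TaxonomyTable, RANKS

__all__ = [
    "SupportProfile",
    "MonophylyVerdict",
    "MonophylyReport",
    "GroupSupportReport",
    "resolution",
    "support_profile",
    "is_monophyletic",
    "monophyly_report",
    "group_support_profile",
]


@dataclass(frozen=True)
class SupportProfile:
    threshold: float
    proportion_all_nodes: float
    proportion_unconstrained_nodes: float | None
    n_nodes_total: int
    n_nodes_unconstrained: int


class MonophylyVerdict(str, Enum):
    MONOPHYLETIC = "monophyletic"
    NOT_MONOPHYLETIC = "not"
    SINGLE_MEMBER = "single-member"
    ABSENT = "absent-from-tree"


@dataclass(frozen=True)
class MonophylyReport:
    rank: str
    verdicts: dict[str, MonophylyVerdict]
    proportion: float          # over multi-member groups present in the tree
    proportion_with_singletons: float  # singletons counted as monophyletic

    @property
    def n_monophyletic(self) -> int:
        return sum(
            1 for v in self.verdicts.values() if v is MonophylyVerdict.MONOPHYLETIC
        )


@dataclass(frozen=True)
class GroupSupportReport:
    rank: str
    threshold: float
    fractions: dict[str, float]  # per multi-member group
    mean: float
    sd: float


def resolution(phy: Phylogeny, convention: str = "rooted") -> float:
    """Proportion of internal nodes resolved.

    rooted: n_internal/(n_tips-1); unrooted: (n_internal-1)/(n_tips-2).
    """
    n = phy.n_tips
    if n < 3:
        raise ValueError(f"resolution needs >=3 tips, got {n}")
    k = phy.n_internal
    if convention == "rooted":
        return k / (n - 1)
    if convention == "unrooted":
        return (k - 1) / (n - 2)
    raise ValueError(f"unknown convention {convention!r}")


def support_profile(
    phy: Phylogeny,
    thresholds: Sequence[float],
    scope: str = "all",
) -> list[SupportProfile]:
    """Proportion of internal nodes with bootstrap support >= each threshold.

    scope='all' counts every internal node (missing, non-constrained support
    fails every threshold); scope='unconstrained' drops constrained nodes
    from numerator and denominator.
    """
    if not thresholds:
        raise ValueError("empty threshold list")
    if scope not in ("all", "unconstrained"):
        raise ValueError(f"scope must be 'all' or 'unconstrained', got {scope!r}")
    nodes = phy.internal_nodes()
    unconstrained = [nd for nd in nodes if not nd.constrained]
    if scope == "unconstrained" and not unconstrained:
        raise ValueError("no unconstrained internal nodes in scope")
    profiles = []
    for t in thresholds:
        def passing(pool):
            return sum(1 for nd in pool if nd.support is not None and nd.support >= t)
        prop_all = passing(nodes) / len(nodes)
        prop_unc = (
            passing(unconstrained) / len(unconstrained) if unconstrained else None
        )
        profiles.append(
            SupportProfile(
                threshold=float(t),
                proportion_all_nodes=prop_all,
                proportion_unconstrained_nodes=prop_unc,
                n_nodes_total=len(nodes),
                n_nodes_unconstrained=len(unconstrained),
            )
        )
    return profiles


def is_monophyletic(phy: Phylogeny, tips: set[str]) -> MonophylyVerdict:
    """MRCA-exact monophyly of a tip set; singletons are vacuous."""
    if not tips:
        raise ValueError("empty tip set")
    present = set(phy.tip_labels)
    missing = tips - present
    if missing:
        raise KeyError(f"tips absent from tree: {sorted(missing)}")
    if len(tips) == 1:
        return MonophylyVerdict.SINGLE_MEMBER
    mrca = phy.mrca(tips)
    descendants = Phylogeny.leaf_labels_under(mrca)
    return (
        MonophylyVerdict.MONOPHYLETIC
        if descendants == tips
        else MonophylyVerdict.NOT_MONOPHYLETIC
    )


def monophyly_report(
    phy: Phylogeny, tax: TaxonomyTable, rank: str
) -> MonophylyReport:
    """Monophyly verdict per named group at a rank, plus summary proportions.

    The headline proportion is monophyletic/(monophyletic+not) over
    multi-member groups whose members occur in the tree; a second tally
    counting single-member groups as trivially monophyletic is also given.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    present = set(phy.tip_labels)
    verdicts: dict[str, MonophylyVerdict] = {}
    for name, members in tax.groups(rank).items():
        in_tree = members & present
        if not in_tree:
            verdicts[name] = MonophylyVerdict.ABSENT
        elif len(in_tree) == 1:
            verdicts[name] = MonophylyVerdict.SINGLE_MEMBER
        else:
            verdicts[name] = is_monophyletic(phy, in_tree)
    n_mono = sum(
        1 for v in verdicts.values() if v is MonophylyVerdict.MONOPHYLETIC
    )
    n_not = sum(
        1 for v in verdicts.values() if v is MonophylyVerdict.NOT_MONOPHYLETIC
    )
    n_single = sum(
        1 for v in verdicts.values() if v is MonophylyVerdict.SINGLE_MEMBER
    )
    if n_mono + n_not == 0:
        raise ValueError(f"no multi-member {rank} groups present in the tree")
    return MonophylyReport(
        rank=rank,
        verdicts=verdicts,
        proportion=n_mono / (n_mono + n_not),
        proportion_with_singletons=(n_mono + n_single)
        / (n_mono + n_not + n_single),
    )


def group_support_profile(
    phy: Phylogeny,
    tax: TaxonomyTable,
    rank: str,
    threshold: float = 50.0,
    include_mrca: bool = True,
) -> GroupSupportReport:
    """Per-group proportion of well-supported nodes inside each group's MRCA
    subtree, and the unweighted mean +- sd across groups.

    Counts internal nodes of the subtree rooted at the group MRCA (the MRCA
    itself included unless include_mrca=False); constrained nodes are
    excluded; groups whose subtree has no countable node are skipped.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    present = set(phy.tip_labels)
    fractions: dict[str, float] = {}
    for name, members in tax.groups(rank).items():
        in_tree = members & present
        if len(in_tree) < 2:
            continue
        mrca = phy.mrca(in_tree)
        nodes = [nd for nd in mrca.preorder_iter() if not nd.is_leaf()]
        if not include_mrca:
            nodes = [nd for nd in nodes if nd is not mrca]
        nodes = [nd for nd in nodes if not nd.constrained]
        if not nodes:
            continue
        n_pass = sum(
            1 for nd in nodes if nd.support is not None and nd.support >= threshold
        )
        fractions[name] = n_pass / len(nodes)
    if not fractions:
        raise ValueError(f"no scoreable multi-member {rank} groups")
    values = list(fractions.values())
    mean = sum(values) / len(values)
    sd = (
        math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        if len(values) > 1
        else 0.0
    )
    return GroupSupportReport(
        rank=rank, threshold=float(threshold), fractions=fractions, mean=mean, sd=sd
    )
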