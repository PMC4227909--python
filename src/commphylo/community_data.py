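"""Joining community, phylogeny and pool tables into analysis-ready samples
and species pools.

The species pool is the sampling universe of the null model.  Two pool modes
are supported: the "island" pool (all species observed anywhere in the
community data) and "grouped" pools (one pool per site group, e.g. all
species recorded on the same soil parent material).  Pools are built from the
community AFTER it has been pruned to the phylogeny, so the pool sizes used
by the null model reflect the species actually analysed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .phylo_io import (
    CommunityTable,
    Phylogeny,
    PoolAssignment,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = ["SpeciesPool", "PruneReport", "prune_to_phylogeny", "build_pools"]

ISLAND_POOL = "island"


@dataclass(frozen=True)
class SpeciesPool:
    """A named species subset used as the null-model sampling universe."""

    name: str
    species: frozenset[str]

    def __post_init__(self):
        if not self.species:
            raise ValidationError(f"pool {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class PruneReport:
    n_dropped: int
    dropped_record_fraction: float
    dropped_species: tuple[str, ...]
    dropped_sites: tuple[str, ...]


def prune_to_phylogeny(
    comm: CommunityTable, phy: Phylogeny
) -> tuple[CommunityTable, PruneReport]:
    """Restrict the community to species that are tips of the phylogeny.

    The report quantifies exclusions as a fraction of presence records
    (the study-design quantity: how much observed occurrence information the
    phylogeny fails to cover).  Sites left without species are dropped with
    a warning.
    """
    tips = set(phy.tip_labels)
    keep = [sp for sp in comm.species if sp in tips]
    dropped = [sp for sp in comm.species if sp not in tips]
    if not keep:
        raise ValidationError("no community species present in the phylogeny")
    total_records = comm.n_records
    sub = comm.matrix[keep]
    dropped_records = total_records - int(sub.to_numpy().sum())
    empty_sites = sub.index[sub.sum(axis=1) == 0].tolist()
    if empty_sites:
        logger.warning(
            "dropping sites left empty after pruning to phylogeny: %s", empty_sites
        )
        sub = sub.drop(index=empty_sites)
    if not len(sub):
        raise ValidationError("all sites empty after pruning to phylogeny")
    pruned = CommunityTable(sub)
    report = PruneReport(
        n_dropped=len(dropped),
        dropped_record_fraction=dropped_records / total_records,
        dropped_species=tuple(dropped),
        dropped_sites=tuple(empty_sites),
    )
    return pruned, report


def build_pools(
    comm: CommunityTable,
    assign: PoolAssignment | None = None,
    mode: str = "island",
) -> tuple[list[SpeciesPool], dict[str, str]]:
    """Build species pools and the site -> pool-name map.

    island: one pool, the union of all species over all sites.
    grouped: one pool per group, the union of species over the group's sites;
    a species observed in several groups belongs to every one of their pools.
    """
    if mode == "island":
        union = frozenset(
            sp for site in comm.sites for sp in comm.site_species(site)
        )
        pool = SpeciesPool(ISLAND_POOL, union)
        return [pool], {site: ISLAND_POOL for site in comm.sites}
    if mode != "grouped":
        raise ValueError(f"mode must be 'island' or 'grouped', got {mode!r}")
    if assign is None:
        raise ValidationError("grouped mode requires a pool assignment")
    missing = [s for s in comm.sites if s not in assign.mapping]
    if missing:
        raise ValidationError(f"sites without group assignment: {missing}")
    members: dict[str, set[str]] = {}
    for site in comm.sites:
        members.setdefault(assign.group_of(site), set()).update(
            comm.site_species(site)
        )
    pools = [
        SpeciesPool(name, frozenset(spp)) for name, spp in sorted(members.items())
    ]
    site_map = {site: assign.group_of(site) for site in comm.sites}
    return pools, site_map
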