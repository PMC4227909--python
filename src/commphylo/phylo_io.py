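"""Reading and writing phylogenies and the tabular inputs of a community
phylogenetics study.

Phylogenies are Newick files whose internal-node labels are bootstrap
percentages (0-100) or the literal token ``NA`` marking nodes whose topology
was fixed a priori by a backbone constraint and therefore carries no bootstrap
value.  Tabular inputs are a species taxonomy (species -> genus/family/order),
a site x species presence/absence community table (wide matrix or long
triplets), and a site -> group assignment used to build restricted species
pools (e.g. by soil parent material).

Supports are stored exactly as printed, on the 0-100 scale; values on a 0-1
scale are never rescaled.  Trees are treated as rooted as written.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "TaxonomyTable",
    "CommunityTable",
    "PoolAssignment",
    "NewickParseError",
    "ValidationError",
    "read_newick",
    "read_newick_file",
    "write_newick",
    "read_taxonomy",
    "read_community",
    "read_pools",
]

RANKS = ("genus", "family", "order")


class NewickParseError(ValueError):
    """Raised when a Newick string violates syntax or the label contract."""


class ValidationError(ValueError):
    """Raised when a tabular input violates its invariants."""


# --------------------------------------------------------------------------
# Phylogeny
# --------------------------------------------------------------------------

class Phylogeny:
    """A rooted phylogeny with optional branch lengths and node supports.

    Thin wrapper over a :class:`dendropy.Tree`.  Each internal node carries
    ``support`` (float in [0, 100] or None) and ``constrained`` (bool, True
    iff the serialized label was the token ``NA``).  Polytomies are
    preserved; unifurcations are collapsed at parse time with branch lengths
    summed.
    """

    def __init__(self, tree: dendropy.Tree, has_branch_lengths: bool):
        tree.is_rooted = True  # trees are treated as rooted as written
        self._tree = tree
        self.has_branch_lengths = has_branch_lengths
        self._annotate()
        self._validate()

    # -- construction helpers ------------------------------------------------

    def _annotate(self) -> None:
        """Derive support/constrained attributes from internal-node labels."""
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            label = nd.label
            if label is None or label == "":
                nd.support = None
                nd.constrained = False
            elif label == "NA":
                nd.support = None
                nd.constrained = True
            else:
                try:
                    value = float(label)
                except ValueError:
                    raise NewickParseError(
                        f"internal node label {label!r} is neither a decimal "
                        "number nor the token 'NA'"
                    ) from None
                if not 0.0 <= value <= 100.0:
                    raise NewickParseError(
                        f"support {value} outside [0, 100] (supports are "
                        "percentages; 0-1 scaled inputs are not accepted)"
                    )
                nd.support = value
                nd.constrained = False

    def _validate(self) -> None:
        labels = [lf.taxon.label for lf in self._tree.leaf_node_iter()]
        if any(lb is None or lb == "" for lb in labels):
            raise NewickParseError("empty tip label")
        seen: set[str] = set()
        for lb in labels:
            if lb in seen:
                raise NewickParseError(f"duplicate tip label {lb!r}")
            seen.add(lb)
        for nd in self._tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {nd.edge.length} on edge above "
                    f"{describe_node(nd)}"
                )

    # -- basic accessors -----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def internal_nodes(self) -> list[dendropy.Node]:
        """All internal nodes, root included."""
        return [nd for nd in self._tree.preorder_node_iter() if not nd.is_leaf()]

    @property
    def n_internal(self) -> int:
        return len(self.internal_nodes())

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = list(labels)
        missing = [lb for lb in labels if lb not in set(self.tip_labels)]
        if missing:
            raise KeyError(f"tips absent from tree: {missing}")
        taxa = [self._tree.taxon_namespace.get_taxon(lb) for lb in labels]
        return self._tree.mrca(taxa=taxa)

    @staticmethod
    def leaf_labels_under(node: dendropy.Node) -> set[str]:
        return {lf.taxon.label for lf in node.leaf_iter()}

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Restrict to a tip subset; unifurcations created by the pruning are
        collapsed with branch lengths summed, so node identities are relative
        to the retained tips."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips absent from tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(clone, self.has_branch_lengths)

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age of each node = max distance to a descendant tip (tips age 0)."""
        if not self.has_branch_lengths:
            raise ValueError("tree has no branch lengths")
        ages: dict[dendropy.Node, float] = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                ages[nd] = 0.0
            else:
                ages[nd] = max(
                    ages[ch] + (ch.edge.length or 0.0) for ch in nd.child_nodes()
                )
        return ages

    def max_depth(self) -> float:
        return self.node_ages()[self._tree.seed_node]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny: {self.n_tips} tips, {self.n_internal} internal nodes>"


def describe_node(nd: dendropy.Node) -> str:
    if nd.is_leaf():
        return f"tip {nd.taxon.label!r}"
    tips = sorted(Phylogeny.leaf_labels_under(nd))
    head = ",".join(tips[:3]) + ("..." if len(tips) > 3 else "")
    return f"internal node ({len(tips)} tips: {head})"


def read_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree from a string.

    Numeric internal labels become bootstrap supports; the token ``NA``
    marks a constrained node; unifurcations are collapsed (lengths summed);
    polytomies are preserved.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, Exception) as exc:
        if "dendropy" not in type(exc).__module__:
            raise
        raise NewickParseError(str(exc)) from exc
    tree.suppress_unifurcations()
    lengths = [nd.edge.length for nd in tree.preorder_node_iter() if nd.parent_node]
    any_present = any(x is not None for x in lengths)
    if any_present and any(x is None for x in lengths):
        logger.warning(
            "tree has %d edges without branch lengths; treating them as 0",
            sum(x is None for x in lengths),
        )
        for nd in tree.preorder_node_iter():
            if nd.parent_node and nd.edge.length is None:
                nd.edge.length = 0.0
    return Phylogeny(tree, has_branch_lengths=any_present)


def read_newick_file(path) -> list[Phylogeny]:
    """Read one or more ';'-terminated trees from a Newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        content = fh.read()
    chunks = [c.strip() for c in content.split(";") if c.strip()]
    if not chunks:
        raise NewickParseError(f"no trees found in {path}")
    return [read_newick(chunk + ";") for chunk in chunks]


def write_newick(phy: Phylogeny) -> str:
    """Serialize a tree; supports are written as internal labels, constrained
    nodes as the token ``NA``. Round-trips through :func:`read_newick`."""
    for nd in phy.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        if nd.constrained:
            nd.label = "NA"
        elif nd.support is not None:
            s = nd.support
            nd.label = f"{s:g}"
        else:
            nd.label = None
    text = phy.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + "\n"


# --------------------------------------------------------------------------
# Tabular inputs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyTable:
    """Species -> (genus, family, order), with nested rank structure."""

    table: pd.DataFrame  # columns: species, genus, family, order

    def __post_init__(self):
        df = self.table
        required = {"species", *RANKS}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"taxonomy needs columns {sorted(required)}, got {list(df.columns)}"
            )
        dup = df[df["species"].duplicated(keep=False)]
        if len(dup):
            raise ValidationError(
                f"duplicate species rows: {sorted(dup.index.tolist())}"
            )
        for lo, hi in (("genus", "family"), ("family", "order")):
            parents = df.groupby(lo)[hi].nunique()
            bad = parents[parents > 1]
            if len(bad):
                offender = bad.index[0]
                rows = df.index[df[lo] == offender].tolist()
                raise ValidationError(
                    f"{lo} {offender!r} maps to multiple {hi} values "
                    f"(rows {rows}); taxonomy must be nested"
                )

    @property
    def species(self) -> list[str]:
        return self.table["species"].tolist()

    def groups(self, rank: str) -> dict[str, set[str]]:
        """Species sets per named group at a rank."""
        if rank not in RANKS:
            raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
        return {
            name: set(sub["species"])
            for name, sub in self.table.groupby(rank, sort=True)
        }

    def smallest_covering_rank(self, species: set[str]) -> tuple[str, str] | None:
        """Smallest (rank, group) whose species set covers `species`, or None."""
        for rank in RANKS:
            for name, members in self.groups(rank).items():
                if species <= members:
                    return rank, name
        return None


@dataclass(frozen=True)
class CommunityTable:
    """Sites x species incidence (0/1) matrix."""

    matrix: pd.DataFrame  # index: sites, columns: species, values in {0,1}

    def __post_init__(self):
        m = self.matrix
        if m.index.duplicated().any() or m.columns.duplicated().any():
            raise ValidationError("duplicate site or species identifiers")
        values = m.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValidationError("incidence values must be 0 or 1")
        empty = m.index[m.sum(axis=1) == 0].tolist()
        if empty:
            raise ValidationError(f"sites with no present species: {empty}")

    @property
    def sites(self) -> list[str]:
        return self.matrix.index.tolist()

    @property
    def species(self) -> list[str]:
        return self.matrix.columns.tolist()

    def site_species(self, site: str) -> set[str]:
        row = self.matrix.loc[site]
        return set(row.index[row == 1])

    @property
    def n_records(self) -> int:
        return int(self.matrix.to_numpy().sum())

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CommunityTable":
        dup = df.duplicated(subset=["site", "species"], keep=False)
        if dup.any():
            raise ValidationError(
                f"duplicate (site, species) rows: {df.index[dup].tolist()}"
            )
        bad = ~df["incidence"].isin((0, 1))
        if bad.any():
            raise ValidationError(
                f"incidence outside {{0,1}} in rows: {df.index[bad].tolist()}"
            )
        wide = (
            df.pivot(index="site", columns="species", values="incidence")
            .fillna(0)
            .astype(int)
        )
        wide = wide.loc[:, wide.sum(axis=0) > 0]
        wide.index.name = None
        wide.columns.name = None
        return cls(wide)


@dataclass(frozen=True)
class PoolAssignment:
    """Site -> group label (e.g. soil parent material)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def group_of(self, site: str) -> str:
        try:
            return self.mapping[site]
        except KeyError:
            raise ValidationError(f"site {site!r} has no group assignment") from None

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def _read_delimited(source) -> pd.DataFrame:
    """CSV or TSV, auto-detected from the header line."""
    if isinstance(source, (str,)) and "\n" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep=None, engine="python")


def read_taxonomy(source) -> TaxonomyTable:
    df = _read_delimited(source)
    df = df[["species", "genus", "family", "order"]].astype(str)
    if df.isin(("", "nan")).any().any():
        rows = df.index[df.isin(("", "nan")).any(axis=1)].tolist()
        raise ValidationError(f"empty taxonomy fields in rows: {rows}")
    return TaxonomyTable(df.reset_index(drop=True))


def read_community(source) -> CommunityTable:
    """Read a community table in wide (matrix, first column = site) or long
    (site,species,incidence triplets) dialect, auto-detected by header."""
    df = _read_delimited(source)
    cols = [c.lower() for c in df.columns]
    if {"site", "species"}.issubset(cols):
        df.columns = cols
        if "incidence" not in cols:
            df["incidence"] = 1
        df["incidence"] = pd.to_numeric(df["incidence"])
        return CommunityTable.from_long(df)
    wide = df.set_index(df.columns[0])
    wide.index = wide.index.astype(str)
    wide.index.name = None
    return CommunityTable(wide.astype(int))


def read_pools(source) -> PoolAssignment:
    df = _read_delimited(source)
    cols = [c.lower() for c in df.columns]
    if not {"site", "group"}.issubset(cols):
        raise ValidationError(
            f"pool table needs columns site,group; got {list(df.columns)}"
        )
    df.columns = cols
    if df["site"].duplicated().any():
        rows = df.index[df["site"].duplicated(keep=False)].tolist()
        raise ValidationError(f"duplicate site rows in pool table: {rows}")
    return PoolAssignment(dict(zip(df["site"].astype(str), df["group"].astype(str))))
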