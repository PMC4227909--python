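"""Phylogenetic community-structure statistics.

Implements the standard presence/absence metrics of community phylogenetics:

* MPD — mean patristic distance over all unordered pairs of co-occurring
  species (a tree-wide measure of relatedness);
* MNTD — mean distance from each species to its nearest co-occurring
  relative (a tips-focused measure);
* their standardized effect sizes against a taxa-label permutation null
  restricted to a species pool, reported with the community-ecology sign
  convention NRI = -SES(MPD), NTI = -SES(MNTD), so positive values mean
  phylogenetic clustering and negative values phylogenetic evenness;
* the comparison statistics used to contrast pools and phylogenies:
  a one-tailed paired t-test and Pearson correlation.

The taxa-labels null permutes taxon labels across the patristic distance
matrix restricted to the pool, preserving the richness of the observed
sample.  When a single sample is scored this is distributionally identical
to drawing uniform richness-sized subsets of the pool; both implementations
are provided and the label shuffle is the default.

Reproducibility: every (site, pool, metric) combination draws from its own
RNG substream derived from the master seed and the combination's names, so
results do not depend on evaluation order and are shared across phylogenies
scored with the same master seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .community_data import SpeciesPool
from .phylo_io import CommunityTable, Phylogeny

__all__ = [
    "DistanceMatrix",
    "StructureResult",
    "DegenerateNullError",
    "patristic_matrix",
    "mpd",
    "mntd",
    "ses_structure",
    "structure_table",
    "paired_t_one_tailed",
    "pearson",
    "metric_index_name",
]

METRICS = ("mpd", "mntd")
_INDEX_NAME = {"mpd": "NRI", "mntd": "NTI"}

# cap on the size of the (chunk, s, s) gather used to score null draws
_CHUNK_CELLS = 20_000_000


class DegenerateNullError(ValueError):
    """Null distribution has zero spread (e.g. pool == sample)."""


def metric_index_name(metric: str) -> str:
    return _INDEX_NAME[metric]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic (path-length) distances among tips."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(v < 0):
            raise ValueError("negative distances")

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        lookup = {lb: i for i, lb in enumerate(self.labels)}
        try:
            return np.array([lookup[lb] for lb in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not in distance matrix") from None

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.index_of(labels)
        return self.values[np.ix_(idx, idx)]


def patristic_matrix(
    phy: Phylogeny, tips: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise path-length distances among the requested tips (default all),
    in a deterministic sorted-label order."""
    if not phy.has_branch_lengths:
        raise ValueError("tree has no branch lengths; patristic distances undefined")
    labels = sorted(tips) if tips is not None else sorted(phy.tip_labels)
    present = set(phy.tip_labels)
    missing = [lb for lb in labels if lb not in present]
    if missing:
        raise KeyError(f"tips absent from tree: {missing}")
    pdm = phy.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phy.tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(tuple(labels), out)


def mpd(sample: Iterable[str], D: DistanceMatrix) -> float:
    """Mean pairwise distance over unordered pairs of sample members."""
    sub = D.submatrix(sorted(set(sample)))
    s = sub.shape[0]
    if s < 2:
        raise ValueError("MPD needs at least 2 species")
    return float(sub.sum() / (s * (s - 1)))


def mntd(sample: Iterable[str], D: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest other member."""
    sub = D.submatrix(sorted(set(sample))).copy()
    s = sub.shape[0]
    if s < 2:
        raise ValueError("MNTD needs at least 2 species")
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_metric_values(
    D_pool: np.ndarray,
    richness: int,
    n_iter: int,
    rng: np.random.Generator,
    metric: str,
    method: str,
) -> np.ndarray:
    """Score `n_iter` null assemblages of size `richness` from the pool.

    method='shuffle' permutes the pool's taxon labels and reads the sample
    positions; method='subset' draws uniform subsets directly.  Both yield
    uniform richness-sized subsets of the pool.
    """
    n_pool = D_pool.shape[0]
    if method == "shuffle":
        perms = rng.permuted(
            np.broadcast_to(np.arange(n_pool), (n_iter, n_pool)), axis=1
        )
        draws = perms[:, :richness]
    elif method == "subset":
        draws = np.empty((n_iter, richness), dtype=np.intp)
        for i in range(n_iter):
            draws[i] = rng.choice(n_pool, size=richness, replace=False)
    else:
        raise ValueError(f"unknown null method {method!r}")
    values = np.empty(n_iter)
    chunk = max(1, _CHUNK_CELLS // (richness * richness))
    for start in range(0, n_iter, chunk):
        idx = draws[start : start + chunk]
        sub = D_pool[idx[:, :, None], idx[:, None, :]]
        if metric == "mpd":
            values[start : start + len(idx)] = sub.sum(axis=(1, 2)) / (
                richness * (richness - 1)
            )
        elif metric == "mntd":
            k = np.arange(richness)
            sub[:, k, k] = np.inf
            values[start : start + len(idx)] = sub.min(axis=2).mean(axis=1)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return values


@dataclass(frozen=True)
class StructureResult:
    """One SES computation: observed metric, null moments, signed index,
    rank p-values and provenance."""

    site: str
    pool: str
    metric: str
    richness: int
    obs: float
    null_mean: float
    null_sd: float
    index: float  # NRI (metric=mpd) or NTI (metric=mntd); positive = clustering
    p_low: float
    p_high: float
    n_iter: int
    seed: int

    @property
    def index_name(self) -> str:
        return metric_index_name(self.metric)

    def significant(self, alpha: float = 0.05) -> bool:
        """Two-tailed significance: either rank p at or below alpha/2."""
        return self.p_low <= alpha / 2 or self.p_high <= alpha / 2


def _substream(seed: int, *names: str) -> np.random.Generator:
    """Named RNG substream: stable across run order and platforms."""
    key = zlib.crc32("|".join(names).encode())
    return np.random.default_rng([int(seed), key])


def ses_structure(
    sample: Iterable[str],
    pool: SpeciesPool,
    D: DistanceMatrix,
    metric: str = "mpd",
    n_iter: int = 999,
    seed: int = 0,
    site: str = "",
    method: str = "shuffle",
) -> StructureResult:
    """Standardized effect size of MPD or MNTD against the taxa-labels null.

    index = -(obs - mean(null))/sd(null); null sd is the n-1 sample
    estimator over the n_iter null values; rank p-values use the +1
    convention, (#{null >= obs} + 1)/(n_iter + 1) for the high tail, with
    ties counted into both tails.
    """
    sample = set(sample)
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(sample) < 2:
        raise ValueError("sample must contain at least 2 species")
    if not sample <= pool.species:
        raise ValueError(
            f"sample not contained in pool {pool.name!r}: "
            f"{sorted(sample - pool.species)}"
        )
    if len(pool.species) <= len(sample):
        raise DegenerateNullError(
            f"pool {pool.name!r} ({len(pool.species)} spp) must be larger than "
            f"the sample ({len(sample)} spp) for a non-degenerate null"
        )
    pool_labels = sorted(pool.species)
    D_pool = D.values[np.ix_(D.index_of(pool_labels), D.index_of(pool_labels))]
    obs = mpd(sample, D) if metric == "mpd" else mntd(sample, D)
    rng = _substream(seed, site, pool.name, metric)
    null = _null_metric_values(
        D_pool, len(sample), n_iter, rng, metric, method
    )
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0:
        raise DegenerateNullError(
            f"null distribution for site {site!r} in pool {pool.name!r} has "
            "zero spread"
        )
    index = -(obs - null_mean) / null_sd
    p_high = (np.count_nonzero(null >= obs) + 1) / (n_iter + 1)
    p_low = (np.count_nonzero(null <= obs) + 1) / (n_iter + 1)
    return StructureResult(
        site=site,
        pool=pool.name,
        metric=metric,
        richness=len(sample),
        obs=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        index=float(index),
        p_low=float(p_low),
        p_high=float(p_high),
        n_iter=n_iter,
        seed=seed,
    )


def structure_table(
    comm: CommunityTable,
    pools: Sequence[SpeciesPool],
    site_pool_map: dict[str, str],
    D: DistanceMatrix,
    metrics: Sequence[str] = METRICS,
    n_iter: int = 999,
    seed: int = 0,
    method: str = "shuffle",
) -> list[StructureResult]:
    """One StructureResult per (site, metric) against each site's assigned
    pool.  Results are independent of site ordering for a fixed master seed
    because every combination uses its own named substream."""
    by_name = {p.name: p for p in pools}
    results = []
    for site in comm.sites:
        pool = by_name[site_pool_map[site]]
        sample = comm.site_species(site)
        for metric in metrics:
            results.append(
                ses_structure(
                    sample,
                    pool,
                    D,
                    metric=metric,
                    n_iter=n_iter,
                    seed=seed,
                    site=site,
                    method=method,
                )
            )
    return results


def results_frame(results: Sequence[StructureResult], alpha: float = 0.05) -> pd.DataFrame:
    """Tidy frame of StructureResults, one row each."""
    rows = []
    for r in results:
        rows.append(
            {
                "site": r.site,
                "pool": r.pool,
                "metric": r.metric,
                "index_name": r.index_name,
                "richness": r.richness,
                "obs": r.obs,
                "null_mean": r.null_mean,
                "null_sd": r.null_sd,
                "index": r.index,
                "p_low": r.p_low,
                "p_high": r.p_high,
                "significant": r.significant(alpha),
                "n_iter": r.n_iter,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)


def paired_t_one_tailed(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> tuple[float, int, float]:
    """Paired t-test on d = x - y; one-tailed.

    alternative='greater' tests mean(d) > 0 (i.e. y < x), 'less' the
    reverse.  Returns (t, df, p) with df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0) and not np.allclose(d, 0):
        raise ValueError("zero-variance nonzero differences")
    if np.allclose(d, 0):
        return 0.0, len(d) - 1, 0.5
    res = stats.ttest_rel(x, y, alternative=alternative)
    return float(res.statistic), int(len(x) - 1), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson needs equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
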