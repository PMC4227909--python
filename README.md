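# commphylo

Community phylogenetics for regional floras: phylogeny-quality diagnostics,
net relatedness / nearest taxon indices under permutation nulls with
configurable species pools, node-based clade enrichment tests, and a
synthetic-data generator for validating the whole pipeline on communities
with known assembly structure.

## The problem

Ecologists ask whether the species co-occurring at a site are more closely
related than chance (phylogenetic *clustering*, the classic signature of
environmental filtering) or less (*evenness*, suggesting competitive
exclusion of close relatives).  The answer depends on two methodological
choices this package makes explicit and testable:

1. **Phylogeny quality.** Consensus trees and reference "megatrees" contain
   polytomies and unsupported nodes.  `commphylo` quantifies resolution
   (proportion of internal nodes present relative to a fully bifurcating
   rooted tree), bootstrap-support profiles at arbitrary thresholds with
   masking of backbone-constrained nodes (internal label `NA`), monophyly
   of named genera/families/orders, and within-group support averages.
2. **Species-pool definition.** Null assemblages must be drawn from some
   pool.  `commphylo` builds an "island" pool (every species observed in
   the dataset) and grouped pools (e.g. all species recorded on the same
   soil parent material) and contrasts the two with a paired one-tailed
   *t*-test; robustness across phylogenies is measured by Pearson
   correlation of per-site indices.

## The statistics

For a site with species set *S* and patristic distance matrix *d*:

- MPD(*S*) = mean of *d(i,j)* over unordered pairs in *S*;
- MNTD(*S*) = mean over *i* in *S* of min<sub>*j* ≠ *i*</sub> *d(i,j)*;
- the null distribution permutes taxon labels on the distance matrix
  restricted to the pool ("taxa-labels" null, 999 iterations by default),
  preserving site richness;
- NRI = −(MPD<sub>obs</sub> − mean MPD<sub>null</sub>)/sd MPD<sub>null</sub>,
  and NTI likewise from MNTD.  Positive values mean clustering, negative
  evenness; significance is a two-tailed rank test (p ≤ α/2 in either
  tail, α = 0.05 by default).

The `nodesig` analysis asks *which* clades drive a pattern: for every
internal node, the number of the site's species descending from it is
compared against its null-draw quantiles (a hypergeometric count under the
uniform null), flagging clades contributing significantly MORE or FEWER
species than expected.  Per-node tests are deliberately not
multiplicity-corrected, matching the classic algorithm; the discrete null's
attainable α is reported per node.

## Worked example

Simulate a 120-species regional flora with six communities assembled under
strong environmental filtering (two groups of sites with different
environmental optima on a phylogenetically conserved trait), then score
each site against the island pool:

```sh
commphylo simulate --n-tips 120 --mode filtering --sites 6 --richness 20 \
    --groups 2 --seed 7 --outdir demo
```

```python
import commphylo as cp

phy = cp.read_newick_file("demo/tree.nwk")[0]
comm, report = cp.prune_to_phylogeny(cp.read_community("demo/community.tsv"), phy)
pools, site_map = cp.build_pools(comm, mode="island")
D = cp.patristic_matrix(phy, sorted(comm.species))
for r in cp.structure_table(comm, pools, site_map, D, metrics=("mpd",),
                            n_iter=999, seed=7):
    flag = "*" if r.significant() else " "
    print(f"{r.site}  {r.index_name} = {r.index:+.2f}{flag}  "
          f"(obs {r.obs:.2f}, null {r.null_mean:.2f} ± {r.null_sd:.2f}, "
          f"p_low {r.p_low:.3f})")
```

```
s01  NRI = +9.82*  (obs 4.00, null 5.14 ± 0.12, p_low 0.001)
s02  NRI = +5.54*  (obs 4.55, null 5.15 ± 0.11, p_low 0.001)
s03  NRI = +11.10*  (obs 3.89, null 5.15 ± 0.11, p_low 0.001)
s04  NRI = +5.55*  (obs 4.52, null 5.16 ± 0.11, p_low 0.001)
s05  NRI = +14.74*  (obs 3.48, null 5.15 ± 0.11, p_low 0.001)
s06  NRI = +4.74*  (obs 4.62, null 5.15 ± 0.11, p_low 0.001)
```

Every filtered site is strongly clustered (observed MPD well below the
null mean; NRI ≫ 0, rank p at the 1/1000 floor), which is exactly the
built-in ground truth of the filtering scenario.  A full case study — one
or more trees, diagnostics, island and grouped pools, nodesig, and the
cross-pool/cross-tree comparison statistics — runs from a flat config
file:

```sh
commphylo run --config run.cfg
```

writing `diagnostics.tsv`, `structure.tsv`, `nodesig.tsv`,
`comparison.tsv` and a `manifest.json` that suffices to reproduce the run.

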