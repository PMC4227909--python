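# Methods

This note documents the models, conventions and numerical choices behind
`commphylo`, in the order a case study uses them: tree input and
diagnostics, community/pool construction, the permutation-null structure
metrics, the node-based enrichment test, the synthetic-data generator, and
the simulation studies that calibrate and validate the whole pipeline.

## Phylogeny input

Trees are Newick, possibly multifurcating, rooted as written; no automatic
rerooting is performed, because resolution counts and MRCA semantics both
depend on the root.  Internal-node labels must be decimal bootstrap
percentages in [0, 100] or the literal token `NA`, which marks nodes whose
topology was fixed a priori by a backbone constraint and which therefore
carry no bootstrap value.  Supports are stored exactly as printed; inputs
on a 0–1 scale are rejected rather than silently rescaled (silent rescaling
is a classic source of wrong support profiles).  Labels are attached to the
node subtending the branch, the standard Newick convention; unifurcations
are collapsed at parse time with branch lengths summed.  A tree with some
missing branch lengths gets zeros (with a warning); a tree with *no*
branch lengths is accepted for topology-only diagnostics and rejected by
every distance-based operation.

## Tree diagnostics

**Resolution** is n_internal/(n_tips − 1): a fully bifurcating *rooted*
tree has n − 1 internal nodes, and the root counts as internal throughout
the package.  The unrooted convention (n_internal − 1)/(n_tips − 2) is
available by flag; at several hundred tips the two differ by under a
percentage point, but the convention used is always reported.

**Support profiles** give, per threshold, the proportion of internal nodes
with support at or above it.  Two scopes: `all` counts every internal node
(a node with no support and no constraint flag fails every threshold —
absence of evidence is counted against the tree); `unconstrained` removes
constrained nodes from numerator and denominator, isolating the part of
the tree the data actually had to resolve.

**Monophyly** of a named group is MRCA-exact: the group is monophyletic iff
the tip set under its MRCA equals the group.  A group sitting inside an
unresolved polytomy together with intruders is counted as *not*
monophyletic — the proportion reported is "monophyly supported", not
"monophyly not rejected".  Single-member groups are vacuous and excluded
from the headline proportion; because reasonable people tally these
differently, a second proportion counting singletons as trivially
monophyletic is also emitted.

**Group support averages** score, for each multi-member group, the
proportion of well-supported internal nodes inside the group's MRCA
subtree (MRCA included by default, flag to exclude; constrained nodes
excluded), then report the unweighted mean ± sd across groups.

## Communities and species pools

Communities are presence/absence (site × species); abundance weighting is
out of scope.  The community is pruned to the phylogeny's tips first, and
the prune report quantifies the loss as a fraction of presence records.
Pools are built *from the pruned community*: the island pool is the union
of all observed species, grouped pools are per-group unions (a species
observed in two groups belongs to both pools).  Pool construction order
matters because pool size sets the null variance, so it is fixed and
documented rather than left to the caller.

## NRI / NTI

MPD is the mean patristic distance over unordered pairs; MNTD the mean
nearest-co-occurring-neighbor distance.  The null permutes taxon labels on
the distance matrix restricted to the pool; scoring a single site, this is
distributionally identical to drawing uniform richness-sized subsets of
the pool, and both implementations are provided (label shuffle is the
default; their agreement is tested).  Conventions, chosen for
compatibility with the standard R implementations:

- null sd is the n − 1 sample estimator over the iteration values;
- rank p-values use the +1 convention, p_high = (#{null ≥ obs} + 1)/(n_iter
  + 1), with ties counted into both tails (conservative);
- NRI = −SES(MPD), NTI = −SES(MNTD); positive = clustering;
- significance is two-tailed at α = 0.05: either rank p ≤ α/2;
- a pool equal to the sample makes the null degenerate and raises an
  explicit error rather than returning NaN.

Reproducibility: every (site, pool, metric) combination draws from a
dedicated RNG substream keyed by the master seed and the combination's
*names* (CRC-32 of `site|pool|metric`), so results are independent of
evaluation order, island-pool results do not change when grouped pools are
also requested, and two phylogenies scored under the same master seed share
their null draws — which keeps cross-phylogeny correlations free of
independent Monte-Carlo noise (toggleable in the pipeline).

The comparison statistics are a paired t-test, one-tailed in the predicted
direction (restricting the pool to the site's own group removes the
between-group component of filtering, so island-pool indices should exceed
grouped-pool indices), and the product-moment correlation with a two-tailed
p.  Since NRI is a sign-flipped SES, |t| is identical whichever sign
convention a caller prefers.

## Node enrichment (nodesig)

The tree is pruned to the pool and degree-collapsed, so node identities are
pool-relative.  For each internal node the observed count of the site's
species descending from it is compared with empirical α/2 and 1 − α/2
quantiles of the count under uniform richness-sized draws (the count is
hypergeometric: population |pool|, successes = node tip count, draws =
richness; Monte-Carlo quantiles are tested against the exact ones).
Verdicts use strict inequality beyond the quantiles; because counts are
small integers the nominal α is rarely attainable, and the attainable
per-node α is reported.  The root holds the entire sample in every draw
and is always `ns`.  Per-node tests are *not* multiplicity-corrected — the
output states this — matching the classic algorithm's behavior; when a
taxonomy is supplied, nodes are labelled with the smallest rank whose
species set covers them, giving readable clade names.

## Synthetic data

The generator emulates the four inputs of a regional study with known
ground truth.

**Tree**: pure-birth (Yule), grown from a crown pair to n tips and then
extended by one final exponential waiting time at rate nλ (the tree is
observed "just before" the next speciation), giving E[crown age] =
Σ_{k=2..n} 1/(kλ) — the closed form used as the simulator's test oracle.
Branch lengths are in time units and the tree is ultrametric.  Random
integer supports in [50, 100] are attached so diagnostics are exercised.
Death rate is omitted: extinction adds nothing to what the metrics consume.

**Trait**: one-dimensional Brownian motion from a root value of 0 (tip
variance σ²T, tip covariance σ² × shared path).  A single conserved axis
suffices for the filtering mechanism being emulated (e.g. drought
tolerance along a water-availability gradient).  An optional conservation
age freezes the trait over the parts of branches younger than that age, so
every clade whose stem crosses the age shares one niche value.  This
matters: under pure BM on a Yule tree, terminal branches are long and
contribute independent variance, so the species in any trait window — even
the w → 0 limit — are phylogenetically scattered in a substantial fraction
of realizations, and trait filtering then produces tip-level clustering
(NTI) without reliable tree-wide clustering (NRI).  Filtering scenarios
therefore default to a conservation age of 0.4 × tree depth (niche
conserved at roughly the "family" level, matching the default taxonomy
cut); pure BM (conservation age 0) remains the default of `evolve_bm`
itself.

**Taxonomy**: genus/family/order labels are the connected components of the
tree sliced at three increasing ages (defaults 15%/40%/70% of tree depth),
nested by construction; a cut age near 0 makes every species its own
genus, a cut above the root age gives a single group.

**Communities** (target richness per site, sampled without replacement):

- *neutral* — uniform draws from the species list;
- *filtering* — inclusion probability ∝ exp(−(trait − optimum)²/(2w²)),
  sampled by the Gumbel top-k trick (equivalent to successive
  probability-proportional draws); sites in a group share an optimum, which
  induces soil-pool-like nesting;
- *repulsion* — random-order admission rejecting any species whose minimum
  patristic distance to the current members is below a threshold.  The
  threshold is a quantile (default 0.9) of the species list's
  *nearest-neighbor* distances: on a 200-tip Yule tree, pairwise distances
  concentrate near twice the depth, so thresholds on the all-pairs scale
  are either vacuous or infeasible, while the NN scale expresses exactly
  "no two members closer than typical sister spacing".  Infeasible
  configurations error after a bounded number of restart attempts.

All randomness descends from one master seed through named substreams
(tree, traits, per-site assembly), so bundles are reproducible and
order-independent.

## Simulation studies and problem sizes

`commphylo.studies` packages the validation experiments run by the test
suite and `scripts/acceptance.py`:

- **Type-I calibration**: 1000 neutral communities (richness 15 from a
  120-tip pool, 999 iterations); the two-tailed significance count of NRI
  and of NTI is checked against the exact binomial 99% interval around
  0.05.
- **Filtering recovery**: 200 sites (20 tree/trait realizations × 10
  sites; richness 30, 200-tip pool, w = 0.25 × trait sd, optima ±2 trait
  sd, conservation age 0.4 × depth, 999 iterations).  Aggregating over
  realizations is deliberate: whether a single tree's trait tail is
  clade-concentrated is itself random, and a multi-realization rate is the
  property the generator actually guarantees (~0.9 site-level
  significance; mean NRI strongly positive).
- **Repulsion recovery**: 100 sites over 10 realizations, same sizes;
  mean NRI negative.
- **Pool attenuation**: 15 sites in 4 groups, filtering between groups;
  island vs grouped indices compared with the paired one-tailed t (df =
  14).
- **Phylogeny comparison**: per-site NRI/NTI from a resolved tree vs a
  megatree-like copy (every node younger than 0.2 × depth collapsed:
  deep structure intact, shallow clades star polytomies), Pearson r across
  40 neutral sites under shared null substreams.  NRI agreement
  consistently exceeds NTI agreement (≈0.95 vs ≈0.2–0.7): tip-level
  signal is what shallow polytomies destroy.  Neutral sites are used
  deliberately — filtered sites have nearly constant indices within a
  group, leaving the correlation noise-driven.  Uniform random collapse
  was rejected for this study: it sometimes removes deep nodes, and then
  neither metric is reliably robust.

These sizes keep the full suite and the acceptance script each within a
minute or two on one CPU while matching the per-site conditions stated
above exactly.

## Limitations

Synthetic communities are binary, equal-richness-per-draw snapshots with a
single trait axis; real occurrence data add observation error, richness
gradients correlated with the environment, spatial autocorrelation, and
multi-trait filtering, none of which the generator emulates.  Passing the
recovery studies therefore shows the estimators detect the mechanisms they
target under their own assumptions — not that those mechanisms are
identifiable in any particular empirical dataset.  The taxa-labels null
controls richness and occupancy only; other null models (independent swap,
frequency) are intentionally out of scope.  Monophyly verdicts on
consensus trees are conservative by design (polytomies with intruders
count against), and resolution conventions matter at the margin — both
conventions are exposed for that reason.
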