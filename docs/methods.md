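# Methods

## Posterior pooling

MCMC tree samplers emit one tree per sampling interval per run.  The pool
is formed by discarding every sample whose generation index is **less than
or equal to** the burn-in cutoff and concatenating the retained samples
across runs in run order.  The inclusive-discard convention matters at the
boundary: with samples at generations 1000..10⁷ in steps of 1000 and a
cutoff of 4×10⁶, each run retains 6,000 trees, so two runs pool to 12,000.
When a tree file carries no generation indices (plain Newick, or Nexus
tree names without `STATE_N`/`gen = N`), indices are assigned as
i·interval starting at the interval; the first sampled generation may be
either 0 or the interval, and both conventions retain the same count for
cutoffs that are multiples of the interval.

## Node distance

The response of the regression is topological: entry (i, j) is the number
of internal nodes on the path between leaves i and j, equivalently the
path length in edges minus one.  A cherry is at distance 1.  This choice
is robust to heterogeneous gene sampling, which distorts branch-length
(patristic or model-corrected) distances; a patristic matrix is available
as an alternative response when branch lengths are trusted.

Rooting is part of the statistic: the root is an internal node on every
path that crosses it, so a rooted four-leaf caterpillar puts its extreme
leaves at distance 3 while the unrooted topology puts them at 2.  Trees
are measured as rooted in the input file; `unroot=True` (CLI `--unroot`)
collapses a bifurcating or singleton root first.  The choice is recorded
in the pipeline report.

## Model matrices

- **Taxonomy**: 0 within a subgenus, 1 across subgenera.
- **Habitat**: 0 when the habitat sets intersect, 1 otherwise.  A taxon
  occupying two habitats is thereby "equally close" to specialists of
  both.  Codes form a closed vocabulary {cave, burrow, stream}; unknown
  codes fail at load because a silent typo would corrupt the matrix.
- **Geography**: great-circle (haversine) distance on a sphere of radius
  6,371,008.8 m (IUGG mean radius).  The radius is a parameter; the
  spherical model is chosen over an ellipsoid for reproducibility, and the
  error relative to an ellipsoid (< 0.5%) is far below the noise level of
  sample coordinates.  Distances are between samples (table rows), not
  species centroids; kilometer scaling is available so that regression
  coefficients have magnitudes comparable to the binary predictors.

All matrices are emitted in the canonical taxon order of the metadata
table so that response and predictors align positionally.

## The regression and its permutation test

The n(n−1)/2 lower-triangle entries of each matrix are vectorized
(row-major, i > j) and fit by OLS with an intercept.  Explanatory power is
decomposed into **sequential (type-I) sums of squares** in the supplied
predictor order (default taxonomy, geography, habitat): SSₖ is the gain in
regression sum of squares when predictor k joins predictors 1..k−1.
Sequential SS are the only decomposition for which SST = Σ SSₖ + SSE holds
exactly, which the implementation exploits: the design matrix is QR-
factorized once and SSₖ is the squared projection of the response on the
k-th successively orthogonalized direction.  Partial correlations are
residual–residual correlations (response and predictor k each residualized
on the intercept and the other predictors).

Pairs within a distance matrix are not independent observations, so
parametric OLS inference is invalid; significance comes from a
**taxon-level permutation test**: a uniform random permutation of the taxa
is applied simultaneously to the rows and columns of the response
(predictors fixed), the model refit, and extremeness counted with the
add-one convention p = (b+1)/(R+1).  β p-values are two-sided via |β|; SS
p-values are upper-tailed (SS is nonnegative).  With R = 10,000 the
smallest reportable p is ≈ 0.0001.  The permutation stream is shared by
both statistics within a run, driven by one user seed.

Two implementation details with statistical content:

- Sampled permutations are drawn from the **non-identity** permutations
  (rejection sampling; negligible cost for n ≥ 6).  The exhaustive mode
  enumerates all n! permutations and counts exceedances including the
  identity, so the exact p and the saturated sampled estimator coincide,
  and the sampled p attains its floor 1/(R+1) on a perfect fit.
- Exceedance comparisons carry a 1e-9 relative slack so that exact ties
  (the identity and automorphic permutations) count as exceedances despite
  float-level differences between the batched and observed computations.
  Ties at that tolerance are otherwise measure-zero for continuous data.

Permuting the response or permuting all predictors jointly are equivalent
up to relabelling; the `permute="predictors"` sensitivity variant is
implemented through that equivalence (inverse permutation applied to the
response) and flagged in the output metadata.

Degenerate designs — an all-equal predictor (e.g. a single-subgenus
table), exactly collinear predictors, a constant response — are rejected
with errors naming the offending matrices rather than silently dropped.

## Topology tests

Posterior samples are effectively unrooted, so monophyly of a group G is
evaluated as **bipartition existence**: some edge must split the leaves
exactly into (G | rest).  A polytomy covering G plus extra taxa is not an
exact split and does not count.  When an outgroup is supplied the rooted
reading ("a node whose descendants are exactly G") is equivalent, because
the outgroup is required to be disjoint from G.

Composite hypotheses name several disjoint groups and optionally a
backbone tree over the group names.  Consistency of a sampled tree is
evaluated on the tree **restricted** to the grouped taxa (plus outgroup
taxa, when given): each group of ≥ 2 members must be an exact split there,
and each backbone clade, expanded to its taxon set, must be a split of the
restricted tree.  The restriction is "soft": taxa assigned to no group are
ignored, so ungrouped taxa cannot break a hypothesis that is only about
the groups.  Two boundary rules follow from this design:

- a lone group with no backbone and no outgroup is tested against the
  full tree (otherwise the restricted test would be vacuous);
- a 3-group backbone is a star when unrooted, so arrangements like
  ((G1,G2),G3) only become falsifiable when an outgroup roots them; the
  outgroup taxa join the restriction universe on the far side of every
  tested split.

pP is reported as the exact rational 100·N/total, displayed at two
decimals with half-up rounding computed in rational arithmetic (so
33/12,000 = 0.275% displays as 0.28 regardless of binary-float ties).

## Synthetic data

The generators exist to make every stage falsifiable with known ground
truth; they are deliberately minimal models, not simulations of sequence
evolution.

- **Trees**: pure-birth topologies by iterative uniform leaf splitting,
  i.i.d. Exponential(mean 0.1) branch lengths.
- **Posterior pools**: a mixture of trees containing a focal clade
  (random topology with the clade attached as one unit) and trees that
  break it (one member regrafted beside an outside taxon).  The
  deterministic mode plants an exact count — the planted/total arithmetic
  is then checkable to the last display digit; the Bernoulli mode gives
  binomial scatter around the target frequency.
- **Metadata**: `clustered` mode paints subgenus labels onto contiguous
  clades (obtained by repeatedly splitting the largest clade), so
  taxonomy genuinely tracks the phylogeny that generates the response;
  `random` mode shuffles the same labels and is the null.  Habitats are
  drawn per taxon (defaults 0.5/0.3/0.2 stream/burrow/cave, 10%
  two-habitat taxa); coordinates are uniform in a southern-Appalachian
  bounding box (33–41°N, 89–79°W).
- **Regression datasets**: response built entrywise as
  intercept + Σ βₖ·xₖ + Gaussian pair noise, symmetrized, clipped at zero.
  Defaults (intercept 8, β = (5.5, −0.002/km, 1.0), noise sd 5) are sized
  so node-distance-scale responses, a dominant taxonomy effect and a weak
  negative per-kilometer geography effect mirror the magnitudes a
  subgenus-level empirical study reports.  Pair-level i.i.d. noise is a
  simplification — real tree distances are correlated across pairs — so
  passing recovery tests demonstrate correctness of the estimator under
  exchangeability, not realism of the error structure.

What the synthetic suite does **not** emulate: sequence-level uncertainty,
MCMC autocorrelation within runs, non-uniform spatial sampling, and
correlated pair errors.  Conclusions about real-data power or calibration
beyond taxon exchangeability are out of scope.

## Problem sizes and numerical choices

The test suite and the acceptance script run the permutation machinery at
n = 30 taxa with R = 199 permutations for null calibration (1000
simulated datasets), 500 replicates at n = 40 for bias checks, and
12,000-tree pools for the planted-frequency arithmetic — sizes at which
the checks are sharp while a full run stays in the tens of seconds on one
CPU.  Exhaustive permutation enumeration is capped at n = 8 (40,320
permutations).  Symmetry of input matrices is enforced at 1e-9 absolute;
rank deficiency at 1e-8 relative to the largest QR pivot; the additivity
identity SST = Σ SS + SSE holds to 1e-8 relative on every fit.

## Known limitations

- Node distance is computed on a single summary tree; propagating
  posterior uncertainty through the regression (one MRM per sampled tree)
  is not implemented.
- The habitat vocabulary is fixed at three codes; extending it is a
  one-line config change but intentionally not a data-driven one.
- The permutation test assumes taxa are exchangeable under the null;
  phylogenetic autocorrelation in the predictors is not corrected for
  (no Mantel variants, no distance-matrix GLS).
- Geographic distance is great-circle; drainage-network distances, which
  are arguably the right metric for freshwater taxa, are out of scope.
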