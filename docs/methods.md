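# Methods

## The experimental design

The package implements a fully synthetic version of a common robustness
question in community phylogenetics: if the same communities and traits are
analysed on a purpose-built chronogram and on cheaper synthesis-style trees,
how much do diversity metrics and signal estimates change?  One experimental
unit is a *tree quintet* on a common tip set:

1. **tree_purpose** — a Kingman coalescent tree (with k lineages the waiting
   time to the next coalescence is Exp(k(k−1)/2); the coalescing pair is
   uniform), rescaled so the root age equals a target T (default 100 time
   units).  The coalescent is used as a neutral, standard null shape for a
   bifurcating ultrametric chronogram; the generator is pluggable.
2. **apg-like** — 40% of internal nodes collapsed youngest-first,
   re-dated keeping 30% of node ages (a classification backbone resolved only
   at deep levels, dated at few calibration points).
3. **zanne-like** — 25% collapsed at random, all surviving node ages kept (a
   calibrated megatree whose branch lengths are largely retained).
4. **otl-like** — 15% collapsed at random, half the node ages kept (a
   supertree re-dated from an external age database).
5. **tree_random** — an independent coalescent tree on the same tips,
   rescaled to the mean root age of the degraded variants; a negative
   control that should carry no signal.

All three variants drop the *same* 5% of tips (`tip_drop_fraction = 0.05`),
so the harmonised common tip set has size ⌈0.95 n⌉ — the ~95% overlap
typical between purpose-built trees and their synthesis counterparts.  A
shared drop set was chosen over independent per-variant drops because the
quantity that matters downstream is the common tip set, and independent
drops would shrink it to ~0.86 n.

### Degradation operators

**collapse_nodes** deletes ⌈fraction × #internal non-root nodes⌉ internal
nodes, attaching their children to their parents (creating polytomies); the
root is never collapsed, surviving nodes keep their original ages.
*youngest-first* deletes the shallowest splits (terminal polytomies, the
typical failure mode of classification backbones); *random* spreads the loss
over all depths.

**bladj_date** assigns ages to undated internal nodes by even interpolation:
processing breadth-first from the root, an undated node on the path between
its (already dated) parent at age a and its nearest fixed-or-tip descendant
at age d, with m edges still to go to that descendant, receives
a − (a − d)/(m + 1).  First-assigned ages win; ties between equally near
dated descendants break toward the oldest; ages are clamped to the parent so
branch lengths are never negative (zero-length branches are legal).  Tips
are dated 0 and the root age is always fixed, so the output is exactly
ultrametric by construction.

**Which ages survive re-dating** is not a free random choice: the retained
`dated_node_fraction` is the *oldest* fraction of surviving nodes.  Real
calibration sets (family-level fossil ages, divergence-time databases)
overwhelmingly date deep, well-known nodes; random retention would let bladj
re-interpolate shallow cherries to arbitrarily old ages, a failure mode no
real calibration produces.  A consequence worth knowing: with deep ages kept
exactly, the apg-like variant (which only loses *shallow* resolution) ends
up the most faithful variant in this emulation, so the severity ordering of
real synthesis resources is not reproduced per se; the directional effects
(inflated diversity, attenuated slopes, degraded rank correlations) are.

## Communities

Presence/absence matrices with 30 sites; every site is an independent
uniform sample of exactly 50 species from the common tip pool.  Fixing
richness removes the richness-driven correlation that would otherwise make
any two trees — even unrelated ones — agree.  The uniform sampler is
deliberate: selection scheme has been shown to matter little for this class
of comparison, and abundance weighting is out of scope.

## Diversity metrics

* **PD** — branch-length sum of the spanning subtree of the site's tips,
  excluding the stem between the subtree's basal node (the site MRCA) and
  the tree root.  Implemented per edge: an edge belongs to the rootless
  spanning subtree iff the number of site members below it is strictly
  between 0 and the site richness.
* **MPD / MNTD** — mean pairwise and mean nearest-taxon patristic distance.
* **SES** — each null replicate applies one uniform tip-label permutation of
  the tree, shared across sites (composition retained, tips shuffled);
  SES = (obs − mean null)/sd null; sites with zero null spread get NaN with
  a warning.  Default 999 nulls.
* **UniFrac** — 1 − shared/total, where *total* is the branch length of the
  union's rootless spanning subtree and *shared* the length common to the
  two sites' own rootless spanning subtrees.  Note this per-assemblage
  rootless convention differs from implementations that classify every
  branch of the rooted tree (e.g. picante), which count the path between a
  site's MRCA and the union root as belonging to that site.
* **MPD_beta / MNTD_beta** — cross-assemblage analogues; MPD_beta averages
  over all ordered cross pairs with conspecific pairs contributing 0
  (the comdist convention); MNTD_beta symmetrises the two directed
  nearest-neighbour means weighted by assemblage size.
* **PCD** — with V the correlation-scaled phylogenetic covariance
  (C divided so diag = 1), D(A|B) = mean diag(V_AA − V_AB V_BB⁻¹ V_BA);
  PCD = (|A| D(A|B) + |B| D(B|A)) / (|A| E[D(A|R)] + |B| E[D(B|R)]), the
  expectation over uniform random assemblages of matching richness estimated
  by Monte Carlo (default 999 draws; 199 in the scaled-down runs).  PCDc is
  the same construction on a star phylogeny (pure composition), and
  PCDp = PCD/PCDc.  Draws are made in sorted-label space with a shared seed
  for both orientations and all five trees of a replicate, which makes PCD
  symmetric and makes identical trees give identical values.  A singular
  conditioning block gets a 1e-10 ridge with a warning.  Because the
  normalisation is Monte-Carlo rather than one of the published analytic
  expectations, absolute PCD values can differ from other implementations by
  a small normalisation factor; rank-based comparisons are unaffected.

## Trait simulation and signal

Traits start at 0 at the root.  BM: child = parent + N(0, σ²t) along a
branch of length t.  OU toward optimum 0: child = parent·e^(−αt) +
N(0, σ²(1 − e^(−2αt))/(2α)); α = 0 falls back to the BM expression with the
same draws, so the reduction is exact, not asymptotic.  Default grids follow
the 12-trait design σ² ∈ {0.2, 0.75, 1.5} × α ∈ {0, 0.05, 0.5, 1}.

**Pagel's λ** multiplies the off-diagonal of C.  The phylogenetic mean and
rate are profiled analytically (GLS mean, rate = quadratic form / n), leaving
a 1-D bounded ML search (tolerance 1e-8) on [0, λ_max] with λ_max =
T / max off-diagonal C — the largest value keeping the covariance valid,
which permits λ > 1.  On ultrametric trees C and I are simultaneously
diagonalised once (Σ(λ) = λC + (1−λ)T·I shares C's eigenvectors), so each
likelihood evaluation is O(n); non-ultrametric trees fall back to a Cholesky
per evaluation.  Significance is a likelihood-ratio test against λ = 0 with
a plain χ²₁ reference — no boundary 50:50 mixture — which makes the test
conservative at the null (empirically ~half the nominal level); the type-I
test asserts control, not exactness.

**Blomberg's K** = (MSE₀/MSE) / [(tr C − n/(1'C⁻¹1))/(n−1)], with the
phylogenetically corrected mean â = 1'C⁻¹x / 1'C⁻¹1, MSE₀ the ordinary and
MSE the C-weighted mean square.  The permutation test shuffles tip values
(default 999, add-one correction) and is exact under exchangeability.  Both
estimators are invariant to shifting and positive scaling of the trait; K is
right-skewed with mean (not median) 1 under BM.

## Comparison statistics

Spearman correlations are computed per replicate (30 sites, or 435 site
pairs) and summarised by both the median and the mean across replicates; the
median is the headline number.  Mixed-model slopes standardise both value
vectors globally (mean 0, sd 1), force the line through the origin and fit
REML with a random intercept per replicate (statsmodels MixedLM); the beta
design adds variance components for site1 within replicate and site2 within
site1, falling back to the single-intercept design with a warning if the
nested fit fails.  Confidence intervals are Wald (±1.96 SE); a degenerate
zero-residual fit reports a zero-width interval.  λ comparisons use mean
absolute differences (λ̂ on the generating tree has variance < 1e-7, making
correlations uninformative); K comparisons use Spearman ρ plus a paired
Wilcoxon test.

Seed discipline: a master seed feeds named counter-based substreams
(SeedSequence([master, …path])) for trees, per-replicate communities,
traits, PCD draws and permutations, so any component can be re-run
independently and two runs with the same master seed produce byte-identical
CSVs.

## Problem sizes

Default scaled-down study conditions: 300-tip quintet, 100 replicate
matrices for alpha diversity, 50 for beta (PCD with 199 draws), 100 trait
replicates, 199 permutations; signal recovery benchmarks use a 200-tip tree
with 500 BM traits.  The full-scale design (1,000 replicates, 999
nulls/draws) is available as `ExperimentConfig.paper_scale()`.

## What the generator does and does not emulate

It reproduces the *structure* of the comparison — polytomy inflation,
missing tips, interpolated ages, an unrelated control — with all randomness
explicit and seedable.  It does not emulate: empirical tree shape (real
plant chronograms are stemmier than coalescent trees, with longer terminal
branches, so rank correlations for nearest-taxon metrics here are, if
anything, pessimistic); topological *error* (variants are always compatible
with the true tree — only resolution and dating degrade); taxonomic gap
filling; or abundance-weighted communities.  Passing tests therefore show
the metrics and estimators behave correctly and that the directional
conclusions hold under controlled degradation — not that any particular
empirical correlation value will be matched.

## Known limitations

* UniFrac values are not comparable with rooted-convention implementations
  (documented above), though ranks largely are.
* The λ LRT is conservative at the boundary; power numbers should be read
  accordingly.
* Quintet-level variance is substantial: with a random collapse rule, a
  single unlucky deep-node collapse can markedly depress UniFrac agreement
  for that quintet.  Medians across replicate matrices do not average over
  this tree-level randomness.
* The nested beta mixed model can be slow for large runs; the alpha-style
  fallback changes the CI, not materially the slope.
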