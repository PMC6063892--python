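# Methods

`cagscape` implements an inference chain for 16S rRNA cohort studies that
asks four questions of a sample × OTU abundance table: (i) does the cohort
fall into discrete community types (enterotypes) or vary along a continuum
(an enterogradient)? (ii) which OTUs form co-abundance groups (CAGs), and
are those groups robust to sampling noise and to compositional artifacts?
(iii) which samples are dominated by a single CAG, and are those dominated
communities separable from each other? (iv) how do CAG abundances relate to
host variables and to inferred community function?  A synthetic-cohort
generator with recorded ground truth makes every stage testable by
recovery.

## The analysis chain

**Filtering.** OTU abundances are closed per sample (relative mode) and
OTUs are retained when their across-sample *median* relative abundance is
at least a threshold (default 0.0001, i.e. 0.01%).  Median with even n is
the midpoint of the central order statistics.  Retained columns are *not*
re-closed: their per-sample sum reports how much of the community the
abundant OTUs capture, which is itself a quantity of interest.

**Beta diversity.** Two distances:

- sqrt Jensen-Shannon divergence, `d(p,q) = sqrt(JSD(p,q))` with base-2
  logs so `d ∈ [0,1]` and the triangle inequality holds (the square root
  of JSD is a metric; the suite checks this on 1,000 random composition
  triples).  Computed via `scipy`'s `jensenshannon` with a base
  conversion.
- UniFrac on a rooted, branch-length tree.  Weighted-normalized:
  `d = Σ_b L_b |A_b − B_b| / Σ_b L_b (A_b + B_b)` over branches `b`, where
  `A_b` is the summed relative abundance of leaves below `b`; unweighted:
  unique branch length over the union branch length of taxa present in
  either sample.  Branches ancestral to the last common ancestor of the
  taxa present in either sample of a pair contribute to neither sum.  The
  implementation precomputes a branch × leaf incidence table; tests check
  it against an independently written per-branch enumeration, frozen hand
  computations on a 4-leaf caterpillar, scikit-bio's normalized weighted
  UniFrac, and invariance to degree-2 node insertion.

**PCoA.** Gower-centered `−d²/2`, eigendecomposed.  Negative eigenvalues
(non-Euclidean distances) are dropped — no Cailliez/Lingoes correction —
and excluded from the proportion-explained denominator; the count of
dropped eigenvalues is reported on the `Ordination` object.

**Enterotype scan.** Partitioning around medoids is implemented
deterministically: greedy BUILD, then best-improvement SWAP iterated to a
local optimum, ties broken by lowest index, so the silhouette-versus-k
curve is exactly reproducible (the `seed` argument is accepted for
interface stability but unused).  A 6-point brute-force enumeration of all
medoid pairs anchors correctness.  The average silhouette (singletons score
0) over k = 2..20 is summarized with the conventional thresholds: < 0.50
no cluster support, 0.50–0.75 moderate, > 0.75 strong.

**Enterogradient.** Spearman correlation of every retained OTU with the
first three PCoA axes, two-sided p by the t-approximation (exact
permutation below n = 10), Benjamini-Hochberg FDR across the whole
OTU × axis family, and a separate `|rho| > 0.3` flag.  The flag and the
q-value are reported independently because "significant" can reasonably
mean either.

**CAG discovery.** Pairwise Spearman between retained OTUs (average-rank
ties; constant OTUs are reported missing and excluded from clustering with
a warning), Ward linkage on `d = 1 − rho` (ward.D2 convention via scipy;
a ward.D switch applies the square-root transform of the dissimilarities,
which reproduces ward.D memberships exactly), cut into K groups.  K
defaults to 5 and is a configuration parameter, not auto-selected.
`1 − rho` rather than `1 − |rho|` keeps co-*excluding* OTUs apart: CAGs
are positive co-abundance consortia.  Each CAG is named after its member
OTU with the highest median abundance.

**Robustness.** Two independent validations:

- *Split-half Mantel*: samples are split into random halves, the OTU × OTU
  Spearman matrix is computed on each half, and r is the Pearson
  correlation of the lower triangles.  One-sided p by simultaneous
  row/column permutation of one matrix; percentile CI by bootstrap over
  OTUs resampled jointly in both matrices (self-pairs from duplicated OTUs
  are dropped).  Defaults are 10,000 permutations and 10,000 bootstraps;
  the test suite and the acceptance script use 1,000 of each, which
  already puts the permutation-p floor at 1/1001.
- *SparCC*: per instance, per-sample fractions are drawn from
  Dirichlet(counts + 1); log-ratio variances `t_ij = var(log f_i/f_j)`
  give the linear system `(diag(n_i) + P) ω = Σ_j t_ij` for the basis
  variances ω under the sparsity approximation;
  `rho_ij = (ω_i + ω_j − t_ij) / (2 sqrt(ω_i ω_j))`, clamped to [−1,1].
  The most-correlated pair is iteratively excluded from the solver while
  any |rho| exceeds 0.1 (at most 10 exclusions).  The reported network is
  the per-pair *median over 20 Dirichlet-resampled instances*; both the
  instance count and the exclusion depth are parameters, since "20
  iterations" can be read either way.  On dense, non-sparse simulations
  SparCC tracks Pearson correlation of the true log absolute abundances
  within ±0.1 (tested); note that *no* consistent correlation estimator
  can push the maximum null correlation over ~1,200 pairs below the
  1/sqrt(n) sampling floor (~0.25 at n = 200), so null-network edges of
  that size are expected and not a compositional artifact.

**Dominance.** Per CAG, the threshold is the 95th percentile
(linear/type-7 interpolation, the convention of the common statistical
environments) of that CAG's abundance over all samples.  A sample is
dominated when it reaches the threshold of *exactly one* CAG; samples
exceeding two or more thresholds are excluded and reported rather than
tie-broken — the stricter reading of single-CAG dominance.  Separability
of the dominated groups is measured by the out-of-bag accuracy of a bagged
decision-tree ensemble (1,000 trees, sqrt(p) feature candidates, Gini,
grown to purity).  OOB accuracy is the headline number because
resubstitution accuracy of purity-grown ensembles is ~1 by construction;
resubstitution is also reported.  Reduced-error-pruning variants of the
ensemble are deliberately not reproduced: the quantity of interest is
separability, not a specific classifier.

**Host associations.** PERMANOVA (single factor, run separately per
covariate):  `SS_total = Σ_{i<j} d²_ij / n`, within-group analogue per
group, `R² = SS_between/SS_total`, pseudo-F with (a−1, n−a) degrees of
freedom, p by whole-sample label permutation with the +1 correction.
Dominated-group profiles: one-way ANOVA on `ln(x + shift)` (shift = half
the smallest positive value, extended by −min(x) when negatives occur)
with Tukey HSD contrasts for continuous variables; uncorrected Pearson
chi-squared for categorical ones; BH-FDR across the variable family.
Whole-cohort: Spearman rho per variable × CAG pair (pairwise-complete,
per-pair n reported), including the alpha-diversity indices (richness,
Shannon in nats, Pielou J = H/ln S with J undefined at S = 1), BH-FDR
across all pairs.  Marker-taxon tests: per genus, abundances are
aggregated by exact case-sensitive label match and tested one-sided for
mean > 0; an all-zero aggregate is reported as not significant rather
than raised.  BH is the FDR default throughout: it is conservative
relative to Storey-type q-values, so q-values here can be slightly larger
than ones computed with a π₀ estimate.

**Functional projection.** Community function is the matrix product of
the sample × OTU relative abundances (restricted to OTUs shared with the
genome-content table, re-closed) with the OTU × function weights, rows
re-closed.  Modules are sums of member functions (overlapping modules are
flagged; missing functions counted and warned).  Ternary coordinates close
exactly three chosen modules to sum 1 per sample.  Group differences per
module use tie-corrected Kruskal-Wallis with BH-FDR across modules;
module × CAG relations use Spearman.  Building a reference genome-content
database is out of scope — the table is an input, and the synthetic
generator emits one with block-exclusive marker functions so the whole
arithmetic chain has a recoverable truth.

## The synthetic cohort

The generator emulates a single-timepoint urban cohort of 441 stool
microbiomes with ~100 abundant OTUs.  Latent model:

    log y_ij = mu_i + lambda_i * s_{j,b(i)} + eps_ij

- `b(i)`: block of OTU i; 100 abundant OTUs in 5 contiguous blocks of 20,
  plus 20 rare OTUs (`mu` shifted by −6) that the 0.01% median filter
  removes, so the filter has real work.
- `mu_i ~ N(0,1)` baseline log-abundances; `eps ~ N(0, 0.7²)` per-entry
  noise.
- `lambda_i ~ U(0.8, 1.2)` positive within-block loadings.
- activities `s_jk ~ Gamma(shape 1.2, scale 1)` i.i.d. in gradient mode:
  heavy-tailed, so roughly 5% of samples sit in the upper tail of a single
  block without any discrete cluster structure.  In clusters mode each
  sample's own-block activity is `3.0 + Gamma(2, 0.5)` against a
  `Gamma(0.5, 0.2)` background, producing K well-separated modes.
- compositions are the row-wise softmax of `log y`; counts are multinomial
  at depth 30,000 reads/sample (an overdispersion switch replaces the
  multinomial with a Dirichlet-multinomial; off by default, matching the
  resampling model SparCC assumes).
- the last block is *pathogen-like*: loadings `U(0.8, 2.2)` and baseline
  shift −1.8.  When it dominates, a few of its OTUs take over the
  community, so the pathogen-dominated group has the lowest alpha
  diversity (group-mean Shannon ≈ 2.5 versus ≈ 3.0 for the others on the
  default cohort).  This is a *tail* property: the cohort-wide Shannon
  correlation of the pathogen CAG is still positive, because at moderate
  activities raising any block's activity lifts 20 OTUs out of the
  baseline and increases evenness.  Stronger pathogen settings were
  rejected as defaults because they manufacture a discrete pathogen
  cluster and destroy the gradient structure the gradient mode exists to
  provide.
- metadata: continuous variables `v_j = β0 + Σ_k β_k s_jk + N(0, σ_v²)`
  with a default effect table (blood pressure and BMI raised by the
  pathogen block, adiponectin raised by the protective block, fiber by
  block 1, `body_fat_pct` a deliberate null); city is drawn with
  softmax(0.8 · s) weights mapping city k to block k; sex and age range
  are independent coin flips; BMI class cuts `bmi` at 25 and 30.  Effect
  sizes were chosen so each planted sign is recoverable with q < 0.1 at
  n = 441 *through the compositional profile*: closure lets a strong
  coupling on one block cancel a weak same-sign coupling on another, so
  the weakest default slope is 1.2 activity-SD per residual-SD.
- the tree grows each block as a separate random-attachment subtree before
  joining the blocks, so planted blocks are phylogenetically coherent;
  topology is drawn first and all branch lengths are then i.i.d. Exp(1)
  (splitting existing branches at attachment time would break the i.i.d.
  property).
- genome content: 10 shared background functions (Dirichlet weights) plus
  one marker function per block, carried exclusively by that block's OTUs
  at weight 0.3.

**What the generator does not emulate** — and what passing recovery tests
therefore do not show about real data: no overdispersion beyond the
optional Dirichlet-multinomial, no sequencing-depth variation between
samples, no batch or run effects, no phylogenetic signal in abundances
beyond block structure, no taxonomy errors, metadata effects are linear
in activities with Gaussian residuals, and blocks are disjoint while real
consortia can overlap.  Recovery on this cohort demonstrates that the
inference chain is implemented correctly, not that CAGs exist in any
particular real population.

## Reproducibility and numerics

Every stochastic stage draws its seed by SHA-256 hashing of
(master seed, stage name), truncated below 2³¹, so changing one stage's
stream leaves upstream outputs byte-identical (tested on manifest
checksums).  Degenerate inputs have explicit conventions: singleton
silhouette 0; Pielou J missing at richness 1; constant OTUs reported as
missing correlations; all-zero samples and empty OTU overlaps are errors
naming the offending sample; identical groups give PERMANOVA F = ∞ and
the permutation p still behaves.  Distance matrices are symmetrized and
clipped at 0 before wrapping; silhouette and PAM tie-breaks go to the
lowest index.

Problem sizes in the test suite and the acceptance script are the
package's own choices: the full 441-sample cohort for every recovery
claim, 1,000 Mantel permutations/bootstraps, 199-permutation PERMANOVA
inside the 200-replicate calibration loops, and reduced cohorts
(60–120 samples) for smoke and CLI tests.

## Known limitations

- PAM is a deterministic local search; no multi-restart option is wired
  in, so a pathological distance matrix could in principle stop at a
  local optimum (the exhaustive-search test covers only small n).
- SparCC p-values (bootstrapped pseudo-p) are not implemented; the network
  is reported as median correlations only.
- PERMANOVA is single-factor; sequential multi-factor decomposition is out
  of scope.
- BH-FDR differs from Storey q-values by the π₀ factor; analyses that used
  the latter will show slightly smaller q on the same p-values.
- The unweighted-UniFrac "presence" of a branch uses abundance > 0 on the
  closed table; detection-limit effects of real count data are only
  represented through the multinomial sampling of the generator.
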