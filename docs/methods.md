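# Methods

This note records the models, numerical choices and limitations behind
`divshift`, in the order the pipeline runs.

## Community composition

**Quality filter.** Genomes are kept when completeness ≥ 50% *and*
contamination < 10% — the MIMAG medium/high-quality convention.  The
completeness bound is inclusive and the contamination bound strict; both are
configurable (`min_completeness`, `max_contamination`).  Filtering happens
before normalization, so proportions are renormalized over the retained
genomes; normalizing against all mapped reads instead can be obtained by
normalizing first and subsetting afterwards.

**Normalization.** Relative abundance is reads mapped to a genome divided by
total reads mapped in that sample.  Columns of a proportion-mode table must
sum to 1 within 1e-9; violations are construction errors, not warnings.

**Pooling.** Location classes pool their samples by summing raw counts and
renormalizing (default), which weights samples by sequencing depth, or by
averaging per-sample proportions (`pooling="mean"`), which weights them
equally.  The two differ only when depths differ appreciably.  Taxa absent
from a class keep explicit zero rows so taxon sets stay aligned.

**Max-site assignment.** Each genome maps to its argmax sample; exact ties go
to the lexicographically smallest sample id.  The rule is part of the
contract so downstream ordinations are reproducible.

## The diversity-shift statistic

**Class ordering.** Profile columns are clustered agglomeratively
(Euclidean, average linkage by default; both recorded in the report).  The
leaf order is chosen by exact enumeration over all orders the merge tree
admits (each internal node may flip — at most 2^(m−1) orders for m classes),
constrained to start with the earliest-merged pair, minimizing the total
distance between adjacent leaves, with a lexicographic tie-break.  This makes
the later-joining, more dissimilar classes land at the far end — the
behaviour the downstream regression needs — where unconstrained optimal leaf
ordering can park the most dissimilar class at either end.  Above 10 classes
(impossible in the 4-class design) the implementation falls back to scipy's
optimal leaf ordering.  Identical columns yield a warning and a deterministic
(input-order) result.  Dendrograms export as Newick with branch lengths.

**Slopes.** Each taxon's pooled proportion is regressed on class rank
x = 0,…,m−1.  Only the slope is used; its sign is classified with tolerance
1e-12.  The sign is invariant to any increasing affine recoding of x, so the
integer coding is immaterial to the test.

**Sign enrichment.** Exact one-sided binomial tail
P(X ≥ k), X ~ Bin(n, ½), summed with integer binomial coefficients and
divided once — exact to float precision for any n.  Exact-zero slopes are
excluded from both k and n (a sign test is only defined on informative
signs) and their count is reported.  A two-sided option doubles the smaller
tail, capped at 1; the one-sided "greater" alternative is the default.
Because the null distribution is discrete the test is conservative: with
n = 25 the rejection threshold at α = 0.05 is k ≥ 18, whose null mass is
0.022.

## Functional potential

**Inclusion cutoff.** A genome enters the functional analysis at a site when
−log₁₀(p_gs / max_s' p_gs') ≤ 0.25, i.e. it is within 10^0.25 ≈ 1.78-fold of
its own best site ("max_scaled", the default).  The alternative "raw"
transform, −log₁₀(p_gs) ≤ 0.25, demands a genome exceed ~56% of a sample —
effectively impossible for a 300-genome community — and is provided for
completeness; the transform used is recorded in run reports.

**Pathway parsimony.** Per genome, the smallest set of pathways whose enzyme
sets cover all coverable observed enzymes: exact branch-and-bound (branching
on the enzyme with fewest candidate pathways, greedy upper bound,
covering-size lower bound, lexicographically smallest optimum returned) when
at most 20 pathways intersect the observation, greedy set cover otherwise.
Pathways supported by a single observed enzyme are flagged and, by default,
excluded from profiles (multi-gene support only).  Enzymes in no definition
are reported, not silently dropped.

**Profiles and the functional shift test.** Rows are (taxon, pathway) pairs —
presence counts among the genomes included anywhere in a class, set
semantics per genome — normalized per class column.  Proteobacteria are
split by class here (and only here) because their functional repertoires
diverge strongly at class level.  The same ordering/slope/sign-test
machinery then applies; rows may optionally be collapsed to taxa first.

**Nutrient-cycle comparisons.** Per process, presence/absence of its
functions is cross-tabulated against the pooled L and H transects and tested
with the package's own exact Fisher test: two-sided by the minimum-likelihood
rule (sum over all tables with the observed margins whose hypergeometric
probability does not exceed the observed one), with a 1e-9 relative
tolerance absorbing floating-point ties.  Site dendrograms on process-level
counts get ordinary bootstrap probabilities (functions resampled, B = 1000
by default) and approximately unbiased support from a multiscale bootstrap:
scales r ∈ {0.5,…,1.4}, z_r = Φ⁻¹(1 − BP_r) fitted by weighted least squares
to d√r + c/√r, AU = 1 − Φ(d − c).  A perfectly flat BP curve is outside the
span of that model (the fit would return ≈0.59 for a clade supported in
every resample), so flat curves return AU = BP directly — the saturated-case
convention, consistent with the expectation that AU ≈ BP when the curve
carries no curvature.

## Geochemistry

PCA is computed on centered, unit-variance features (correlation structure),
via SVD, with each component's sign fixed so its largest-magnitude loading
is positive.  PAM is the classic deterministic BUILD + best-improvement SWAP
on the score matrix; k is chosen to maximize mean silhouette width over
k = 2,…,n−1, ties toward smaller k, duplicate points warn.  Dunn pairwise
z-statistics use pooled ranks with the tie-corrected variance
(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ), two-sided normal p-values,
Benjamini–Hochberg step-up adjustment, significance flagged at α = 0.025.
NMDS is two-dimensional non-metric scaling of Bray–Curtis dissimilarities
(the dissimilarity is configurable; none is canonical), 20 random restarts
with the lowest normalized stress kept and non-convergence reported; each
chemistry feature is fitted as a least-squares vector on the ordination with
r² and the add-one permutation p-value (1 + #{r²_perm ≥ r²})/(1 + n_perm),
n_perm = 999 by default — the estimator never returns 0.

## Synthetic watershed generator

The generator emulates the study conditions the pipeline is built for:
300 genomes over 25 phyla; samples L1, L2, H1, H2, C, S1–S3; expected depth
10⁶ mapped reads per sample.

* **Phylum sizes** come from a stick-breaking split (Beta(1, 2) sticks; every
  phylum seeded with one genome) so a few phyla dominate and several are
  singletons — the long tail typical of MAG recovery, and a deliberate
  exercise of tie/edge handling downstream.
* **Base phylum proportions** are one Dirichlet draw with concentration
  50/25 = 2 per phylum: moderately uneven communities (typical base Pielou
  evenness ≈ 0.95) rather than implausibly flat ones.  L, C and S share
  these expectations; only the runoff tilt differentiates H.
* **Runoff tilt.** H-class phylum proportions are re-weighted by
  exp(−δ·rank) (rank 0 = most abundant) and renormalized.  Evenness of the
  H expectation is non-increasing in δ; δ = 0 is the exact null.
  `calibrate_runoff_tilt` bisects δ to any target evenness ratio — the
  pipeline's power analyses use evenness(H)/evenness(L) = 0.6.  The default
  δ = 0.15 injects a visible but not overwhelming effect.
* **Counts** are Multinomial(depth, class probabilities) with
  depth ~ Poisson(10⁶); within-phylum genome weights are a flat Dirichlet
  draw shared across samples.
* **Quality** records are drawn so ~10% of genomes fail the MIMAG filter
  (half by completeness, half by contamination), keeping the filter stage
  observable.
* **Annotations.** Each phylum owns a 40-function pool from a 120-function
  vocabulary whose first 30% are designated oxidative; a genome carries each
  pool function with probability 0.7 (genome incompleteness).  Genomes of
  H-dominant phyla (expected proportion raised by the tilt) lose each
  oxidative function with probability `oxidative_drop` (default 0.5),
  mimicking the loss of oxidative metabolism under reducing, high-
  sedimentation conditions.  Every function maps to a
  carbon/nitrogen/sulfur oxidation-or-reduction process in the truth record.
* **Geochemistry** is Normal per feature around class-specific means chosen
  to caricature oxygenated low-runoff porewaters (high O₂, redox, NO₂⁻+NO₃⁻)
  versus reducing high-runoff ones (high NH₃, SO₄²⁻, CaCO₃); values are
  sample-level, not depth-interval profiles.
* **Reproducibility.** One seed governs everything through a SeedSequence
  that spawns an independent child stream per section (structure, counts,
  quality, annotations, pathways, geochemistry).  Multinomial sampling
  consumes a data-dependent amount of its stream, so sectioned streams are
  what make two configs differing only in δ share identical phylum
  structure, taxonomy, quality and function-presence draws.

**What the generator does not emulate:** read-level error or mapping
ambiguity, assembly/binning artifacts, phylogenetic correlation between
phyla, within-transect depth gradients, compositional coupling between
chemistry and community beyond the shared class labels, and temporal
dynamics.  Tests passing on this generator demonstrate that the pipeline
recovers the effects it injects at realistic scale and noise — not that any
particular real watershed behaves this way.

## Problem sizes used in validation

The packaged validation runs use 200 simulated watersheds per operating
characteristic (type-I error under δ = 0; power at an evenness ratio of
0.6), the full 300-genome/25-phylum scale per replicate; exact-oracle
comparisons cover every binomial tail with n ≤ 25, every 2×2 table with
total count ≤ 30, and 1000 fuzzed set-cover instances (exhaustive
cross-check up to 12 pathways).  These sizes give Monte-Carlo standard
errors below 2 percentage points on the rate estimates while keeping the
whole suite in the minutes range on a single CPU.

## Known limitations

* With one pooled value per class the per-taxon regressions have no error
  model; all inference rides on the cross-taxon sign test, which assumes
  taxa are exchangeable under the null.  Proportions summing to 1 induce
  mild negative dependence between taxa; empirically the test stays
  conservative (type-I well under the nominal level), but the binomial null
  is an approximation.
* The data-driven class ordering is estimated from the same profile that is
  regressed; the type-I simulations cover exactly this double use.
* AU support is asymptotic in B and in the scale grid; with B = 1000 its
  Monte-Carlo error is a few percent.
* PAM's silhouette criterion cannot select k = 1 and penalizes singleton
  clusters, so a location class represented by one sample will usually be
  absorbed into its nearest neighbour.
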