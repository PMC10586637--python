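# Methods

`omnidiet` implements a two-track analysis of the diet of an omnivorous
consumer, designed around the data a combined DNA-metabarcoding and
stable-isotope study produces: annotated amplicon sequence variant (ASV)
read-count tables from fecal samples, and δ¹³C/δ¹⁵N measurements of
consumer tissue and candidate food taxa.

## Track 1: occurrence statistics from read counts

Read counts from diet metabarcoding are not a reliable proxy for biomass
consumed, so the pipeline reduces them to presence/absence through a fixed
filtering ladder:

1. drop ASVs outside the marker's target phylum (Streptophyta for the plant
   ITS2 marker, Arthropoda for the COI marker);
2. keep only ASVs assigned at least to genus (unassigned ranks are stored
   as empty strings, never as missing values, so the filter is total);
3. drop bait genera (*Arachis*, *Avena* — peanut butter and oats);
4. convert counts to relative read abundance (RRA): reads per ASV divided
   by the sample's total retained reads.  This is the only reading under
   which per-sample proportions sum to one; samples with zero retained
   reads are flagged and kept as all-absent rows, since they remain real
   samples and belong in frequency denominators;
5. call a taxon present when RRA ≥ 1% (inclusive).  The 5% source-selection
   rule is likewise inclusive.

Percent frequency of occurrence (%FOO) is 100 × detections / n samples,
kept at full precision internally and rounded to one decimal only for
display.  Per-habitat and per-session %FOO use each level's own sample
count as denominator.

### Multivariate structure

Diet structure over habitats and trapping sessions is tested on the
Sørensen dissimilarity (b+c)/(2a+b+c) of the binary profiles.  Pairs of
all-absent samples have an empty denominator; they are set to 0 and
flagged.  PCoA eigendecomposes the Gower-centred matrix G = −½ J D² J and
retains negative eigenvalues (no Lingoes/Cailliez correction) because the
dispersion test needs them.

PERMANOVA follows the McArdle–Anderson trace formulation.  Sums of squares
are partial (Type III): with sum-to-zero contrasts, SS(term) =
tr((H_full − H_drop)G) where H_drop omits the term's columns, and SS(res) =
tr((I − H_full)G).  The two-way crossed design always includes the
interaction; a design with an empty habitat × session cell is rejected with
an error naming the cell.  p-values use permutation of residuals under the
reduced model (Freedman–Lane): the residual Gower matrix
G_r = (I − H_red) G (I − H_red) is row/column-permuted and the pseudo-F
recomputed; p = (#{F* ≥ F} + 1)/(n_perm + 1), so p is never 0.  The
permutation stream is keyed to the sorted sample ids, making p-values
invariant to input order.

Components of variation are the multivariate analogues of the classical
unbiased estimators: Var(term) = (MS_term − MS_res)/k_term with k_term the
mean cell size of the term (n divided by its number of cells), exact on
balanced designs and a documented approximation otherwise.  Negative
estimates are kept in the table; only the reported SD truncates at zero.

PERMDISP computes distances to group centroids in PCoA space with the
negative-axis correction z = √max(d²₊ − d²₋, 0), takes the one-way ANOVA F
on z, and permutes the distances among groups (the convention of
`vegan::permutest.betadisper`; the null distribution is the same as
permuting residuals in the one-way layout).  Pairwise comparisons report
t = √pseudo-F with raw permutation p-values and no multiplicity
correction, matching the reporting convention of the commercial package
this mirrors.

## Track 2: isotope mixing model

### Source grouping

Candidate sources are the taxa at ≥5% FOO plus any forced additions (food
known from other evidence but invisible to the marker, e.g. seabird
tissue).  A-priori groups (C₃ plants, C₄ plants, seabird) are fixed; the
remaining taxa are clustered with Ward's method (ward.D2 = Ward on
Euclidean distances) on per-taxon mean (δ¹³C, δ¹⁵N) in raw ‰ units — the
two tracers are on comparable scales in this system, so no standardisation
is applied.  The number of groups is chosen by the within-versus-among
variance principle: among the cuts where every group's within-group
specimen variance (pooled over tracers) is below the among-group variance
of group means, the cut with the largest relative jump in Ward merge
heights wins.  The bare "smallest admissible k" rule is not used because
every coarse split of well-separated data is admissible, so it always
answers k = 2; the dendrogram-gap arbiter recovers generated cluster
structure while still honouring the variance criterion.  Structureless
(identical-mean) data resolve to the lower bound of the k range.

### Feasibility screening (mixing polygons)

A linear two-tracer mixing model can only explain consumers inside the
convex hull of discrimination-corrected source signatures.  Each
Monte-Carlo iteration draws every source's corrected signature from
Normal(μ + Δ, √(s² + Δsd²)) per tracer — source SD and discrimination SD
combine in quadrature — builds the hull, and tests each consumer (boundary
counts as inside, preventing seed-dependent flapping at vertices;
degenerate collinear draws fall back to a segment test).  A consumer's
inclusion probability is the fraction of iterations inside; consumers
strictly below 5% lie outside the 95% mixing region and are excluded from
the model.  Candidate discrimination factors are ranked by the number of
consumers covered, then mean inclusion probability, each candidate scored
with a stream keyed to its own values so identical candidates tie exactly.

### The hierarchical model

With K source groups, tracers j ∈ {δ¹³C, δ¹⁵N}, and c_kj group k's mean
elemental concentration (%C or %N):

- global proportions p ~ Dirichlet(α), α = 1 by default (the
  "uninformative"/generalist prior);
- φ = ilr(p) under a fixed orthonormal Helmert basis with sources in name
  order (proportions are basis-invariant; the basis is pinned so
  random-effect coordinates are reproducible);
- random effects ε_{f,ℓ,m} ~ Normal(0, σ²_{f,m}) per factor f (habitat,
  trapping session), level ℓ, ILR coordinate m, additive with no
  interaction; σ ~ Uniform(0, 20) in ILR units;
- consumer proportions p_i = ilr⁻¹(φ + Σ_f ε_{f,level_f(i)});
- likelihood δ_ij ~ Normal(m_ij, √v_ij) with concentration-dependent
  moments

      p̃_ikj = p_ik c_kj / Σ_l p_il c_lj
      m_ij  = Σ_k p̃_ikj (μ_kj + Δ_j)
      v_ij  = ξ_j Σ_k p̃²_ikj (s²_kj + Δsd²_j)

  The discrimination factor enters the likelihood (mean shift on sources,
  variance added in quadrature); consumer values are never pre-subtracted —
  the subtraction convention exists only for display and polygon geometry.
  The multiplicative residual factor ξ_j ~ Uniform(0, 20) is the
  process×residual error structure: ξ = 1 is pure process error.  This is
  one concrete reading of that error family; it is documented, not asserted
  identical to any other implementation.

Under the orthonormal ILR basis the Dirichlet prior plus transform
Jacobian collapse to Σ_k α log p_k(φ), which the prior-predictive test
exploits: with the likelihood disabled the sampled p must reproduce
Dirichlet(α) moments.

### Sampling

Inference is a self-contained adaptive block Metropolis-within-Gibbs
sampler (no probabilistic-programming dependency):

- the φ block uses an empirical proposal covariance (Haario-style adaptive
  Metropolis) that keeps updating from the second half of the chain's
  history for the whole run — updates diminish by construction as the
  history grows, and freezing the covariance at the end of burn-in proved
  fragile when burn-in under-explored the weakly identified direction.
  The block runs four sweeps per iteration: with two tracers and K > 3
  sources, one simplex direction is informed only by the prior and needs
  the extra mixing;
- each factor level's ε vector is a block, accepted against its partial
  likelihood;
- a recentering move exploits the exact flat direction
  (φ, ε_f) → (φ − c, ε_f + c): c is proposed from its Gaussian full
  conditional under the ε prior, so only the Dirichlet factor enters the
  acceptance ratio.  Without it the chain drifts slowly along this ridge
  and σ estimates are destroyed;
- σ and ξ get scalar Metropolis updates (ξ per tracer, the tracer
  likelihoods being separable);
- all proposal scales adapt by diminishing Robbins–Monro steps toward
  standard acceptance targets (0.3 for blocks, 0.44 for scalars).

Defaults are a desk-scale schedule of 3 chains × 20,000 iterations,
10,000 burn-in, thinning 10 (≈ 3,000 kept draws); the study-scale schedule
of 3 × 1,000,000 / 500,000 / 500 is available as `FULL_MCMC`.  Convergence
is judged by the classic Gelman–Rubin potential scale reduction factor on
every monitored scalar (global proportions, σ, ξ), with < 1.1 as the
pass mark, plus an autocorrelation-based effective sample size.

### Reporting

Posterior summaries are mean, SD, and equal-tailed 50%/95% credible
intervals, overall and per factor level.  A-posteriori aggregation sums
member proportions within each draw (e.g. five arthropod groups into one),
preserving their covariation.  Variance partitioning reports two
quantities per factor: the hierarchical variance σ² (the spread of a
hypothetical new level — with only 4–7 levels its posterior is strongly
right-skewed under the uniform prior) and the realized variance of the
fitted level effects, which measures the diet variation actually
attributable to the observed levels.  The between-factor ratio uses the
realized variance: in recovery runs at a true ratio of 4 it centres on the
truth, while the σ²-based ratio is biased high by the heavy tails.

## Synthetic data

The generators define the conditions under which the pipeline is testable
without the study's (undeposited) raw data.

The ASV generator emulates the published occurrence structure: ~20 taxa
with presence probabilities stepping from 0.6 down to 0.2% (few common
taxa, long rare tail, as in the published tables where the commonest taxa
occur in 50–63% of 318 samples), habitat/session multipliers on presence,
negative-binomial read depths (the standard overdispersed count model;
no read-depth model is stated in the source material), contamination reads
injected at 0.1–0.9% RRA so the 1% rule is exercised on both sides, bait
genera, and off-target/unassigned ASVs for the filter ladder.  It emits the
true presence indicators alongside the data.

The isotope generator runs the model forwards: source specimens from the
configured group truths, consumer tracer values from the
concentration-dependent moments at p_i built from a known global simplex
plus ILR random effects, planted infeasible consumers placed ≥5 combined
SDs outside the corrected hull.  Two deliberate design choices:

- **Conditional random effects.** Drawn level effects are centred and
  rescaled so their realized root-mean-square equals the configured SD.
  With only four habitat levels, unconstrained draws make the realized
  variance ratio vary several-fold between seeds, so the configured ratio
  would say little about the data actually generated.
- **Identifiable recovery geometry.** With two tracers, K = 4 proportions
  are only partially identified: the data fix two mixture-mean equations
  for three free simplex coordinates, leaving a one-dimensional ridge that
  the flat prior resolves.  The K = 4 recovery design places the corrected
  source means on a parallelogram whose null direction (+1, −1, +1, −1) is
  symmetric, and uses a truth equidistant from the simplex boundary along
  it, so the prior-weighted ridge centroid coincides with the truth and
  posterior means are consistent.  Equal concentrations across sources
  preserve the symmetry.  K = 2 and K = 3 designs are fully identified and
  need no such care.

What passing these tests does *not* show about real data: the generators
draw from exactly the fitted model family (no lipid effects, no
within-group concentration variation, no tissue-specific discrimination
error beyond the stated SDs), the source groups are truly Gaussian and
well-separated, and samples are nearly balanced across cells.  Real
diet data violate all of these to some degree; the tests validate the
machinery, not the biology.

## Numerical choices and limitations

- Thresholds (1%, 5%) are inclusive; outlier exclusion (< 5% inclusion
  probability) is strict, per their respective definitions.
- Permutation p-values use the +1 convention and a ≥ comparison with a
  1e-12 slack against floating-point ties.
- PCoA eigenvalues within 1e-10 (relative) of zero are treated as zero.
- Components of variation for unbalanced designs use mean cell sizes as
  EMS multipliers; the exact estimator of the commercial reference
  implementation for unbalanced two-way designs is not published, so
  numeric agreement there is not claimed.
- The mixing model requires every consumer to carry both tracers; missing
  elemental concentrations inherit group means with a warning.
- Desk-scale MCMC trades posterior-quantile precision for runtime; the
  published-scale schedule is a config switch away but takes hours.
- Reported headline diet proportions of the original field study are not
  reproducible here because the raw per-mouse data were not deposited;
  the acceptance layer therefore validates the *methods* (exact table
  statistics, oracle agreement, calibration, parameter recovery) rather
  than those numbers.
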