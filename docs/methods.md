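# Methods

This note documents the statistical machinery, the synthetic study design,
the numerical choices, and the places where the design was genuinely open.

## 1. Genotype container and quality control

Genotypes are diploid biallelic dosages (0/1/2 copies of the alternate
allele, −1 for a failed call) in an individuals × loci matrix with one
population (site) label per individual. Genepop files (2- or 3-digit
allele codes, zeros = missing) and a long CSV are the on-disk forms; the
genepop writer emits ids `CODE_i` and the reader recovers the population
label as the prefix before the last underscore.

The filter ledger, in order, with all thresholds as parameters:

1. **Missingness** — loci failing in > 15% of samples, then samples
   missing > 15% of the *retained* loci. The order (loci first) is a
   design decision, recorded in the report.
2. **Monomorphic / MAF** — monomorphic loci and loci with overall minor
   allele frequency < 0.01 (strict `<`, so MAF exactly 0.01 is kept).
3. **Two-pass |Fis|** — candidates are loci whose global Weir–Cockerham
   Fis across all populations exceeds ±0.3; a candidate is discarded only
   if its per-population Fis exceeds the bound in > 50% of the
   *non-admixed* populations. Heterozygote-deficit outliers that are
   explained by admixture (a Wahlund effect of mixed ancestry) therefore
   survive; technical artefacts do not. The admixed/non-admixed status
   comes from a preliminary admixture pass (§5).
4. **Fst pruning** (only ahead of pairwise-θ estimation) — "interferes
   with the estimator" is operationalised as: some population has zero
   complete genotypes at the locus, leaving that pair's variance
   components undefined. Interfering loci are removed iteratively,
   highest overall missingness first (preferring loci whose missingness
   lies in the 2–8% band), ties broken by locus id; each removal is
   listed in the report.

Every filter records one primary reason per discard and conserves
`retained + discarded = input` on both axes; all filters are idempotent.

## 2. Diversity and differentiation

* **Ho / He**: Ho is the heterozygote fraction among non-missing calls;
  He is Nei's unbiased expectation 2p(1−p)·2n/(2n−1), averaged over loci
  with data.
* **Allelic richness**: rarefied expectation
  Ar = Σ<sub>alleles</sub> [1 − C(2N−N<sub>a</sub>, g)/C(2N, g)]. The
  rarefaction depth defaults, per locus, to the smallest non-missing
  allele-copy count across populations (an open choice; recorded in
  output).
* **Weir & Cockerham (1984)**: per-locus variance components a (among
  populations), b (among individuals within populations), c (within
  individuals). θ = Σa/Σ(a+b+c) and f = 1 − Σc/Σ(b+c) are ratios of
  summed components over loci, never averages of per-locus ratios.
  Single-population Fis uses the r = 1 degeneration of b and c. Loci
  with undefined terms for a pair are excluded pair-by-pair (empty after
  pruning). Negative θ estimates are reported as computed.
* **Permutation significance**: the statistic is the genotype-table
  log-likelihood G summed over loci (rows = populations, columns =
  genotype classes), which does not assume Hardy–Weinberg within
  samples; whole multilocus genotypes are permuted between the two
  populations. p = (1 + #{permuted ≥ observed})/(1 + n<sub>perm</sub>),
  so the smallest attainable p is 1/(n<sub>perm</sub>+1). The Bonferroni
  level is α / C(n<sub>pops</sub>, 2), reported at 3 significant figures
  alongside full precision.
* **DAPC**: per-locus mean imputation of missing calls, centring, PCA to
  `n_pcs` components (default min(n−1, L, 50)), then linear discriminant
  analysis on the group labels; per-axis percentages are discriminant
  (between-group) variance shares.

## 3. LD effective population size

The estimator averages squared pairwise-complete dosage correlations
(the Burrows composite measure) over all locus pairs passing a
minor-allele-frequency screen (p<sub>crit</sub> = 0.02 by default),
weighted by the per-pair complete sample size, subtracts the sampling
expectation E[r²|S], and maps the drift signal to
N<sub>e</sub> = (1/3 + √(1/9 − 2.76 r̂²'))/(2 r̂²') (random mating,
S ≥ 30; the 0.308/2.08 small-sample variant below that). A non-positive
drift signal is the INFINITE estimate; the report layer substitutes 1000
only when a log10 scale is needed for plotting, never in inference.

Two deliberate departures from the commonest defaults, both validated by
simulation against Wright–Fisher truth (N<sub>e</sub> = 50, 50
individuals × 200 unlinked loci):

* **Sampling expectation by null calibration.** The asymptotic
  E[r²|S] = 1/S + 3.19/S² is derived for a small sample from a large
  population and over-corrects as the sample approaches the whole
  population, biasing N<sub>e</sub> upward (≈ +20% at S = N = 50).
  The default therefore *simulates* E[r²|S]: `n_null` (12) replicates of
  independent Hardy–Weinberg loci at the observed allele frequencies,
  with the observed missingness pattern, seeded and deterministic. The
  closed form remains available (`correction='asymptotic'`).
* **Confidence interval by delete-one-individual jackknife** with a
  t(S−1) quantile, transformed to the N<sub>e</sub> scale. A jackknife
  over locus *pairs* ignores the strong correlation between pairs
  sharing a locus and is far too narrow (≈ 30% coverage at nominal 95%
  in our WF experiments); the individual jackknife achieves ≈ 90%.

## 4. Admixture

The likelihood is the standard unlinked-loci admixture model:
g<sub>il</sub> ~ Binomial(2, μ<sub>il</sub>),
μ<sub>il</sub> = Σ<sub>k</sub> q<sub>ik</sub> f<sub>kl</sub>, with Q rows
on the simplex and cluster frequencies clamped to [10⁻⁶, 1−10⁻⁶] to keep
the likelihood finite. Fitting is expectation–maximisation: the E-step
attributes each of the two gene copies to a cluster, the M-step updates Q
and F in closed form; each iteration provably does not decrease the
log-likelihood (asserted in tests). Missing calls contribute nothing.
Convergence: |Δℓ| < 10⁻⁶ (default), max 2000 iterations; initialisation
is Dirichlet(1) rows for Q and Uniform(0.05, 0.95) for F from the run
seed.

This deterministic ML estimator stands in for MCMC clustering software by
design: everything downstream (the Q matrix, the per-run likelihood, the
classification) is a function of quantities the ML fit provides.
Replicates from independent seeds play the role of independent chains:
label switching is undone by exhaustive permutation (K ≤ 6) against the
highest-likelihood replicate, the consensus Q is the mean of aligned Qs,
and Evanno's ΔK = |L(K+1) − 2L(K) + L(K−1)|/SD(K) is computed from the
replicate spread (≥ 3 replicates; a K with zero SD is flagged and
skipped; a weak top ΔK — less than twice the runner-up — is flagged).

**Classification** (K = 2): a population is admixed iff its mean
minority-cluster ancestry exceeds 0.2 (strict `>`); otherwise pure with
the dominant cluster's label (ties broken by cluster index and flagged).
`mode='individual_strict'` instead requires *every* individual below the
threshold for a population to count as pure — the stricter of the two
pure-lineage dataset designs, which is the appropriate one when the goal
is an uncontaminated within-lineage analysis.

## 5. Pipeline scheduling

The Fis filter needs the admixture classification, but the final
admixture should see the filtered panel. The pipeline resolves this
circularity with an explicit two-phase schedule: preliminary K = 2
admixture on the missingness/MAF-filtered panel → classification → Fis
two-pass filter → final admixture replicates across K with Evanno. Every
stage's seed derives from the master seed via `SeedSequence.spawn`, so an
identical config reproduces a byte-identical report (hash-checked; no
timestamps are embedded).

## 6. Seascape connectivity

Currents are u (eastward) and v (northward) m s⁻¹ on a regular lon/lat
grid, NaN on land, stored as ESRI ASCII (one file per component). Two
rasters of nested resolution merge by disaggregating the coarse one
(value replication) and letting fine values win where both are defined.
Sites snap to the nearest water-cell centre by haversine distance
(ties broken by (row, col) and flagged; sphere radius 6371 km).

The directed conductance for a step between 8-neighbouring water cells
with unit direction d̂ is c = max(ε, s₀ + w̄·d̂), where w̄ is the mean
current vector at the two cells. The linear downstream-advantage form is
the simplest scheme that is anisotropic, strictly positive, and reduces
to an isotropic surface when currents vanish; s₀ defaults to the maximum
current speed on the grid (1.0 if the field is identically zero) and
ε to 10⁻³·s₀. Geo-correction divides the conductance by the great-circle
distance between cell centres, so edge cost = dist/c and per-step costs
are comparable across latitudes and rook/diagonal moves (halving the cell
size changes cost-per-km by < 1% in tests). Least-cost distances are
Dijkstra shortest paths in both directions for every pair; unreachable
pairs are +∞.

Pair value = min(a→b, b→a). Categories: cat0 iff infinite; cat2 iff value
< cat2 threshold; cat1 otherwise. The band between the cat2 and cat1
thresholds is formally unassigned by the convention the thresholds come
from; it is placed in cat1 and flagged `middle_band` rather than silently
resolved. The sink–source network keeps only cat2 pairs, weight =
1/value, direction from the cheaper directed cost. The thresholds are
config values on whatever cost scale the raster implies; the synthetic
default study uses 400/150 (km per m s⁻¹ on its 0.1° grid), chosen from
the grid geometry so that all three categories occur.

## 7. Beta regression

Response y ∈ (0, 1) (boundary values are refused; `squeeze_unit_interval`
maps non-positive differentiation estimates to 0.001 — the field's
convention — and proportions through the Smithson–Verkuilen transform
only when a boundary value occurs). The mean model is logit μ = xᵀβ with
constant precision φ; ML fitting is delegated to statsmodels'
`BetaModel` (BFGS with a Nelder–Mead fallback; non-convergence raises,
carrying the optimiser trace). On top of the ML fit the package computes:

* pseudo-R² = squared Pearson correlation between the linear predictor
  and logit(y) (the convention the surrounding literature reports);
* hat values from the weighted projection matrix
  W = φ[ψ₁(μφ) + ψ₁((1−μ)φ)]·(μ(1−μ))² of the final fit (they sum to the
  mean-model dimension; points above 2(k+1)/n are flagged);
* AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k counting the precision
  parameter;
* inverse-logit coefficient reporting.

**Model selection** enumerates all candidate-predictor subsets except
those containing two or more members of an exclusion group (the device
that keeps, e.g., min/max/mean variants of one variable apart), ranks by
AICc, and returns the best fit. **VIF** is 1/(1−R²) from OLS of each
predictor on the rest; perfectly collinear predictors report the cap
(10⁶) with a flag. **LRT** compares nested fits by χ² = 2Δℓ on the
parameter-count difference. **Marginal means** evaluate each factor
level's link-scale prediction with the other covariates at their sample
means, back-transform, and test pairwise contrasts on the link scale with
Tukey (studentized-range, asymptotic df), Bonferroni, or no adjustment.

The genotype-composition regression supports both units of analysis
behind a flag: individual-level Q with site-level covariates (default —
the variance structure a per-individual response implies) or site means.
Pairwise-Fst regressions treat the C(n,2) pairs as independent
observations; pairs sharing a site are in truth positively dependent, so
those p-values are anti-conservative. This mirrors standard practice for
this model family and is a known limitation.

## 8. Synthetic study design

The generator produces what the analysis assumes, with one interpretable
knob per feature:

* **Lineage divergence**: Balding–Nichols — ancestral p ~ U(0.05, 0.95)
  per locus, lineage frequencies Beta(p(1−F)/F, (1−p)(1−F)/F). The F
  knob equals the expected Weir–Cockerham θ between pure descendant
  samples (recovered to ±0.03 at 5000 loci in tests). Default F = 0.3,
  in the empirical range for diagnostic panels between these lineages.
* **Individuals**: ancestry q ~ Beta with the population's mean and
  dispersion (point mass at dispersion 0), genotypes Binomial(2,
  q·p_A + (1−q)·p_B). Loci are unlinked and independent — there is no
  coalescent or recombination machinery, so the panel carries no linked
  selection or background LD, and recovery tests say nothing about those.
* **Environment**: covariates uniform on field-realistic ranges (wave
  height 0–3 m, SST and salinity in coastal North-East-Atlantic ranges);
  observed site ancestry Beta(μφ, (1−μ)φ) with logit μ linear in the
  covariates (default wave-height slope −0.89 on the link scale,
  precision φ = 30). An optional Gaussian-copula correlation knob makes
  covariates collinear to exercise the VIF/exclusion machinery.
* **Currents**: 'uniform' constant (u, v) or 'gyre' solid-body rotation
  with a land mask; the default study uses a 20×20 0.1° gyre with an
  enclosed lagoon so that unreachable (cat0) pairs exist.
* **Dropout**: uniform at random (no informative-missingness mechanism).
* **Wright–Fisher**: N monoecious diploids, random mating with selfing,
  free recombination; the drift-LD oracle for the N<sub>e</sub>
  estimator.

The default whole-study configuration mirrors the 26-site Irish design:
the packaged site table's sample sizes (summing to 781), three
lineage-A-dominated sites, an admixed west/south group, lineage-B
elsewhere, 91 loci, 2% dropout.

What passing tests do **not** show about real data: no genotyping-error
model, no null alleles, no within-locus linkage, missingness independent
of genotype, environments exactly beta-distributed around a log-linear
mean, and currents far smoother than a real shelf sea.

## 9. Problem sizes and numerical conventions

Default test/problem sizes are chosen to make each recovery property
measurable at desk scale: admixture recovery at n = 200 × 300 loci with
5-seed restarts; Evanno over K = 1..4 with 5 replicates; LD-Ne coverage
over 50 WF replicates; LRT calibration over 1000 fits at n = 200; dredge
consistency over 100 replicates at n = 400; pipeline smoke tests at 6
sites × 12 individuals × 40 loci with 30 permutations. Cluster
frequencies and mixture means clamp at 10⁻⁶; EM stops at |Δℓ| < 10⁻⁶;
shortest-path ties are resolved deterministically by cell index; all
random stages consume seeds spawned from a single master seed.
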