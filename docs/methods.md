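# Methods

This note documents the statistical models implemented in `florsel`, the design of
the synthetic-data generator, and the numerical and design choices a user should
know before trusting or extending the results.

## Selection analysis

Selection coefficients follow the classical regression framework for phenotypic
selection. Within each population, every trait is standardized to zero mean and
unit *sample* SD (n−1 denominator) and every fitness measure is relativized by its
population mean, never pooled across populations. The opportunity for selection I
is the sample variance of relative fitness; the selection differential S′ is the
sample covariance between a standardized trait and relative fitness; the selection
gradients β′ are the partial regression coefficients of relative fitness on all
standardized traits jointly, with classical OLS standard errors and two-sided t
p-values. Using (n−1) denominators throughout makes S′ identical to the univariate
OLS slope on a unit-variance predictor, which the test suite checks, along with
β′ = S′ for orthogonal in-sample designs.

Choices on points the framework leaves open:

- **p-values for S′** come from the univariate regression of w on zⱼ. A covariance
  has no canonical test; the univariate-slope test is the natural companion of the
  identity above. This is a documented assumption, not a convention forced by the
  math.
- **Missing data** are handled complete-case per analysis: pairwise for S′ (each
  trait keeps its own n), listwise for β′ (one n for the joint regression). Sample
  sizes are reported next to every coefficient.
- **No multiple-testing correction** is applied anywhere.
- Relative fitness for the Brown–Forsythe comparison of opportunities is computed
  within population and then pooled plant-level, giving the F(1, n₁+n₂−2) degrees
  of freedom structure.

The univariate machinery — Welch's t with Welch–Satterthwaite df (accepting either
raw samples or (mean, SE/SD, n) summaries; both routes agree to machine precision),
Brown–Forsythe/Levene deviation-variance tests (delegated to `scipy.stats.levene`),
Pearson correlation, and CV% — is standard. The Wilcoxon rank-sum test reports the
rank-sum W of the first sample with midrank ties; for combined n ≤ 12 the two-sided
p enumerates all C(n, n₁) assignments exactly (ties handled by enumeration), and
otherwise uses the normal approximation with the usual tie-corrected variance and
no continuity correction.

## Fitness construction

Female fitness per plant is seeds/fruit (mean over up to three sampled fruits,
fruits with zero ovules excluded and counted) times total fruits; a plant with zero
fruits has zero seed production but undefined seed-set. Male fitness converts mean
microscope counts per 10 µl subsample to grains in the 1.5 ml suspension, divides
by the number of anthers collected (1 or 2), scales by anthers per flower
(parameter, default 10 — the species has ten stamens; the per-flower scaling is not
uniquely pinned by the field protocol, so it is exposed), and subtracts from the
population's mean per-flower pollen production. Negative dispersal estimates —
possible when sampling noise pushes the undispersed estimate above the population
mean — are clamped to zero and flagged. Total male fitness multiplies by
hermaphrodite flowers only; female components use all flowers (female fitness is
independent of flower gender in gynomonoecious plants). Plants without assay data
are simply excluded from male-fitness analyses.

## Path analysis

The engine fits recursive (acyclic) linear structural models to covariance
structure only; means are saturated and ignored. Free parameters are the path
coefficients (matrix B), one residual or exogenous variance per variable, optional
residual covariances between endogenous variables (the rendering of "unresolved"
double-headed arrows), and implicit covariances among multiple exogenous variables.
With t free parameters and p variables, df = p(p+1)/2 − t.

- **Discrepancy and χ².** F_ML = ln|Σ(θ)| − ln|S| + tr(SΣ(θ)⁻¹) − p against the
  unbiased (n−1) sample covariance, with T = (N−1)·F_ML — the Jöreskog–Sörbom
  convention. Different engines use N or N−1 multipliers; all within-run
  comparisons (Δχ², AIC/BIC orderings) are invariant to the choice.
- **Optimization.** Free parameters are packed with residual variances on the log
  scale (positivity by construction); the analytic gradient of F_ML is supplied and
  L-BFGS-B polishes a per-equation OLS warm start (gtol 1e−8, ftol 1e−12). For a
  recursive model without residual covariances the likelihood factorizes over
  equations, so the OLS start is already the exact ML optimum; `solver="auto"`
  (used by the enumeration and bootstrap layers) exploits this closed form, and the
  equality of the two routes is itself a test. Non-positive-definite Σ during a
  line search returns a large penalty; convergence failures are flagged, and
  failing bootstrap replicates are dropped and counted (warning above 5%, error
  above 50%).
- **Information criteria** are reported on the χ²-plus-penalty scale, AIC = T + 2t
  and BIC = T + t·ln N. For fixed data these are rank-equivalent to the
  likelihood-based forms; absolute values are not comparable across engines, only
  orderings are meaningful.
- **Enumeration.** Near-saturated candidates are generated by taking, for every
  ordering of the endogenous variables (exogenous first), the saturated recursive
  DAG and removing k edges for k in the df set (default {1, 2}). Orderings generate
  many covariance-equivalent duplicates; candidates are deduplicated by the exact
  graphical criterion (equal skeletons and v-structures). On the six-variable
  system this yields 2,930 distinct classes — a principled reconstruction of
  "models differing in the order of unconnected variables"; no particular published
  candidate count is contracted. A fast ranking path scores all pure-DAG candidates
  through the factorized likelihood with per-(variable, parent-set) caching; it is
  exactly equal to the generic fit (tested).
- **Trimming** removes, at each step, the non-significant path (single-edge
  χ²-difference test at α, default 0.05) with the smallest |standardized
  coefficient|, stopping when all paths are significant or the reduction is
  rejected against the baseline. The final model among those visited is chosen by
  lowest BIC with AIC as tie-break. BIC-first is deliberate: an AIC-first choice
  re-admits a removed truly-zero path whenever its Δχ²₁ lands in (2, 3.84), i.e.
  ~16% of the time asymptotically, which defeats the purpose of trimming;
  `select="aic"` and `select="last"` are available.
- **Bootstrap** inference resamples plants with replacement, refits, and reports
  replicate-SD standard errors, percentile CIs, and normal-approximation Z and p
  per parameter (the data are not multivariate normal, so bootstrap SEs are
  preferred over information-matrix SEs). Indirect effects are products of
  unstandardized coefficients along directed paths; their Z/p use the bootstrap
  replicates of the product. Both the normal-approximation p and the percentile CI
  are reported, since which of the two an external engine uses is generally
  unstated.
- **Standardized coefficients** rescale by model-implied SDs and may exceed |1|
  when predictors are correlated. Total female fitness can be divided by 1,000
  before fitting (pipeline default: on) to tame its variance; standardized results
  are invariant to this.

## Synthetic-data generator

The generator emulates two wild populations as linear-Gaussian structural equation
systems over corolla color → {calyx color, flower number} → ovary predation →
seeds per plant, with percent corolla predation independent, floral display
correlated with flower number, and all remaining traits drawn independently from
their (mean, SD). Presets carry the two populations' published trait moments,
standardized path coefficients, display–flower correlations (0.49 / 0.83), mean
pollen production per flower, and dispersal-fraction moments chosen so the derived
dispersed-grains-per-flower distribution matches the field mean and SD.

**Discretization and calibration.** Counts (flowers, fruits, predated ovaries,
per-fruit seeds) are rounded and clamped at zero; corolla color is truncated at an
R:G ratio of 1.0; seeds are capped at 92% of ovule capacity; fruit counts are
reconciled with seed counts. These observation-level constraints censor the normal
tails, and for the mean/SD ratios of these populations the censoring is not
negligible: a naive latent-scale generator loses up to 0.05 of the largest
standardized coefficients and shifts the seeds mean by ~7% of an SD. Because the
published coefficients and moments describe real (censored, integer) data, the
presets are calibrated so that those values are properties of the *observable*
table: a damped fixed-point loop (internal fixed seed, common random numbers,
n = 150,000 per iteration) adjusts latent means, residual SDs, edge coefficients
and the latent display correlation until observable moments, the standardized
regression coefficients of the generating DAG, and the display correlation match
the preset targets to ~0.3% relative. Calibration is deterministic, cached per
preset, and exposed as `calibrate_preset` for modified presets; uncalibrated
(custom) presets take the stated values at face value on the latent scale. One
quantity is not fully matched: the derived fruit-set SD has a floor (~+0.03 for the
barra-like preset) caused by integer fruit counts at small flower numbers.

The per-plant coefficient targets are the regressions of each endogenous variable
on its *generating* parents (the DAG's nonzero edges): after discretization,
conditional independences of the latent model hold only approximately, so partial
and marginal coefficients differ slightly and the calibrated quantity is the one
the fitted generating topology recovers.

Other generator choices: Gaussian residuals throughout (the field paper gives no
residual distributions; this is an assumption); children of the DAG see latent
(pre-discretization) parent values; ~10% of plants are gynomonoecious with 80% of
their flowers hermaphrodite; per-fruit ovule counts scatter (SD 3) around the
plant's ovule number; the dispersal fraction is drawn from a normal whose
[0,1]-clipped moments match the preset targets (closed-form censored-normal
inversion). `discretize=False` returns the continuous latent table, on which
zero-noise presets give exact linear dependence.

**What passing tests do and do not show.** The generator reproduces first and
second moments, the causal regression structure, and the display–flower coupling of
the two field populations — so recovery tests demonstrate that the estimators are
consistent and the model-selection machinery finds the generating class under
realistic effect sizes and noise. Real field data additionally contain skewed and
zero-inflated distributions beyond censored-normal shape, spatial and temporal
structure, measurement error in color scoring, and trait–trait correlations not in
the generating DAG (e.g. corolla area with calyx length); none of these are
emulated, and the male-fitness side of the generator treats dispersal fractions as
independent of all traits, so male-fitness selection gradients on synthetic data
are null by construction.

## Problem sizes and determinism

Simulation-based checks use n = 5,000 plants per population — large enough that
standardized-coefficient sampling noise (~0.01) is well below the ±0.05 recovery
bands — and 100 replicates for the model-selection-consistency and trimming
experiments. Bootstrap defaults to B = 1,000 in the pipeline; tests use B = 100–150
except where bootstrap-vs-classical SE agreement itself is under test (B = 1,000 at
n = 1,000). Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); the pipeline derives per-stage seeds from one master
seed via `SeedSequence`, and identical configurations produce byte-identical output
files.

## Known limitations

- Only recursive (acyclic) systems with fully observed variables: no latent
  measurement models, no FIML for missing data, no robust/WLS estimators.
- The χ² and IC conventions follow one engine family; absolute AIC/BIC values are
  not portable across software.
- Enumeration is exact but exponential in the number of variables (guarded at 8).
- The equivalence-class signature (skeleton + v-structures) applies to pure-DAG
  candidates; models with residual covariances are never deduplicated against each
  other.
- The R:G color index assumes linear channel values; no gamma decoding, highlight
  masking or RAW support.
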