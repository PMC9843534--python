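# Methods

This note documents the models, numerical choices and known limitations of
the `wheatlocust` package.

## Study design being modelled

The analysis targets a two-subspecies wheat collection — 10 wild emmer
(ancestral) and 10 durum (modern) accessions — exposed to migratory locust
nymphs in two complementary experiments: a field cage experiment scoring
ordinal feeding damage (12 herbivory cages of 20 plants, each cage holding
two plants of each accession of a single subspecies), and 100 laboratory
paired-choice trials covering each wild × modern accession pair once.  Leaf
traits come from control cages (six replicates per accession).

## Leaf traits

* **SLA** (cm² g⁻¹) and **LDMC** (mg g⁻¹) follow the standard functional
  trait definitions.  **Leaf thickness** uses the allometric inversion
  `LT = (SLA × LDMC)⁻¹`; with SLA in cm² g⁻¹ and LDMC converted to g g⁻¹
  this is a length in cm, scaled to μm.  The algebraic identity
  `LT·SLA·LDMC = 10⁴` is enforced as a pipeline invariant.
* **Toughness.** Work to shear is the trapezoidal integral of force over
  vertical blade displacement (no smoothing — traces are inputs, not
  reconstructions).  The horizontal cut length is `Δz / tan(angle)` for a
  blade set at 30° from the horizontal.  Work-to-shear (J m⁻¹) divided by a
  thickness is dimensionally J m⁻²; because the field convention labels the
  thickness-standardized quantity in J m⁻¹, the package computes **both**,
  uses the thickness-standardized value (per mm of lamina) as the analysis
  trait `sws`, and carries explicit units in column headers
  (`sws_J_per_m_mm`, `work_to_shear_J_per_m`).
* **Aggregation** from replicates to accession is the arithmetic mean,
  NaN-skipping with a logged count.  Nutrient contents (LNC, LPrC, LChC, %
  dry mass) enter as numbers; assay chemistry and spectral calibration are
  out of scope.
* **Nutrient balance.** The LPrC:LChC ratio is compared with the locust
  nymph's optimal protein:carbohydrate intake ratio (two published targets,
  1.0 and 0.7).  Ratios are undefined (and excluded from summaries) when
  LChC = 0.  The nitrogen-to-protein factor is LPrC/LNC per accession.

## Feeding selectivity

Consumed dry biomass per trial side is `max(control − uneaten, 0) / SLA`
(negative differences arise from climatic-control measurement noise and are
clamped with a logged count).  FS proportions sum to one by construction;
trials with zero total consumption are uninformative and excluded.  The
paired t-test is the one-sample t on the differences `2·FS_wild − 1`
(trial-level by default; accession-level aggregation is a caller choice).

### Score model

The binary event "FS higher for the wild accession" is Bernoulli with
`P = 0.5 + BS_wild − BS_modern`, one score per accession with independent
Beta(2,2) priors shifted to (−0.5, 0.5).  The additive equation can leave
[0, 1] for extreme score pairs, so P is clamped to `[1e−6, 1 − 1e−6]` in
both the likelihood and the simulator; this preserves the equation on its
valid range while keeping the model proper everywhere.  FS ties at exactly
0.5 are excluded from the Bernoulli likelihood (kept for the t-test), since
the defining event is strict.

### Sampler

Component-wise random-walk Metropolis, one sweep over all 20 scores per
step.  Reference settings follow the study's chain plan: 100,000 steps,
burn-in 10,000, thinning 10 → 9,000 retained draws per chain; 4 chains with
sub-seeds derived from one master seed.  Proposal scales adapt
multiplicatively during burn-in only (target ≈ 35% acceptance, clamped to
[10⁻³, 0.5]), so the post-burn-in kernel is fixed and valid.  Convergence is
summarized by split-R̂ (via ArviZ), flagged above 1.1.  The likelihood uses
per-pair sufficient statistics (wins/trials), and the sweep loop is
JIT-compiled with numba; a full reference run takes well under a second.

Correctness gates: posterior means agree with a brute-force grid posterior
(midpoint rule, ≤ 3 accessions) within 0.01 on every toy fixture, and over
200 synthetic tournaments with truths drawn from the prior the 95% credible
intervals cover at ≈ 95% (simulation-based calibration).

## Feeding damage

Cumulative-logit mixed model with 4 strictly increasing thresholds, a
subspecies fixed effect (modern vs ancestral) and accession random
intercepts nested in subspecies: `P(FD ≤ c) = logistic(θ_c − β·modern −
u_a)`, `u_a ~ N(0, σ²)`.  The logit link is the framework default; probit
and cloglog are out of scope, as are crossed or cage random effects (an
optional grouping column exists but accession is the modelled unit, and
damage is analysed at plant granularity by default).

Laplace approximation: each accession's scalar intercept is profiled by
Newton iterations with vectorized step-halving (tolerance 1e−8), and the
marginal log-likelihood adds `−½ log σ² − ½ log(−g″(û))` per accession
(the 2π factors cancel).  The outer maximization runs L-BFGS-B on
(θ₀, log-increments of θ, β, log σ); `log σ` is bounded in [−6, 3] and a
solution at the lower bound is reported as a boundary estimate σ̂ = 0.
Against adaptive Gauss–Hermite quadrature the Laplace log-likelihood is
accurate to ~10⁻² at σ = 0.3 on this design, and it degenerates exactly to
the fixed-effects cumulative logit as σ → 0 (tested against the closed-form
saturated thresholds, the logits of empirical cumulative frequencies).

The subspecies test is a likelihood-ratio test against χ²₁ (Wald SE from a
numerical Hessian is also reported).  With only 20 accession-level clusters
the χ²₁ reference is approximate; over repeated null simulations at the
default design the empirical size is ≈ 0.04 at the 5% level, within the
tolerance the acceptance suite checks.  S-values are `−log₂(p)`, reported
raw and rounded up to the next whole bit.

## Multivariate analyses

PCA is computed on the correlation matrix (the five traits have
heterogeneous units), with deterministic signs (largest-magnitude loading
positive per component).  The two-group MANOVA uses Wilks Λ with the exact
two-group F transform.  The discriminant direction is
`W⁻¹(mean_modern − mean_ancestral)` on standardized traits, reported
unit-norm with the LNC coefficient fixed positive (raw-scale coefficients
are also emitted); LDA is gated on MANOVA p < 0.05, with an override flag.
Vector fitting regresses a response on the scores of components with
eigenvalue ≥ 1 and normalizes the coefficient vector; its permutation test
uses `p = (1 + #{r²_perm ≥ r²_obs})/(1 + n_perm)` with 999 permutations by
default.  All parametric p-values are validated against permutation
references in the test suite.

## Synthetic-data generator

The generator emulates the study conditions with known ground truth:

* **Traits**: multivariate-normal replicate draws around subspecies means in
  the order (LT μm, SWS, LNC, LPrC, LChC %).  Defaults place the
  domestication shift on toughness (+0.4) and nitrogen (+1.0%), with equal
  thickness and carbohydrate content and a protein-biased macronutrient
  ratio ≈ 3 — chosen to mirror the qualitative syndrome the analysis is
  meant to detect.  Accession-level offsets (covariance scaled by 0.7²) are
  drawn once so replicates within an accession correlate.  Raw measurement
  tables (leaf areas/masses, constant-force shear traces) are back-derived
  so the traits pipeline recovers the planted values exactly.
* **Choice trials**: ground-truth scores centre at ±0.07 per subspecies
  with accession scatter 0.08 (truncated to keep every pair probability in
  (0, 1)); outcomes are Bernoulli in the clamped score model, and
  continuous FS is a Beta(2, 2) draw rescaled into the chosen half of
  (0, 1), making the indicator and the proportion mutually consistent.
  Disk areas carry 2% multiplicative Gaussian noise by default.
* **Damage**: cumulative-logit draws with cutpoints (−2, −0.5, 0.5, 2),
  modern fixed effect −1.5 log-odds and accession-intercept SD 0.3.  The
  generator emits per-plant rows; the damage module can aggregate to cage
  level if desired.
* **Seeds**: one master seed; each component (traits, scores, trials,
  disks, damage, raw tables) draws from a stream with a fixed spawn key, so
  stages are independently reproducible and byte-identical across reruns.

What the generator does **not** emulate: spatial block effects in the
field, leaf aging between experiments, measurement correlation between
traits and selectivity, non-normal trait distributions, or any secondary
chemistry.  Passing tests therefore demonstrate correctness of the
estimators under the stated stochastic model, not robustness to every
feature of real field data.

## Problem sizes in the test and acceptance runs

The acceptance experiments use the study-scale design throughout (20
accessions, 100 trials, 240 damage scores).  Replicated calibration
experiments use 200 replicates; the score-recovery tournaments use 20
trials per pair with single chains of 20,000 steps (burn-in 4,000, thinning
8), which matches the reference posterior to well within the credible-band
widths while keeping the full suite around a minute of compute.  The
acceptance script's coverage experiment uses 100 tournaments.

## Known limitations

* The Laplace approximation is least accurate for large σ with few
  observations per accession; σ̂ frequently hits the boundary at the
  default design size, which is reported explicitly rather than hidden.
* The LRT's χ²₁ reference for a cluster-level fixed effect with 20 clusters
  is mildly conservative on average and variable across designs.
* The grid oracle is limited to 3 accessions by memory; it is a validation
  device, not an inference path.
* The score model has no home-advantage or trial covariates, matching the
  printed model; ties are handled by exclusion, an explicit choice where
  the defining event is silent.
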