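# wheatlocust

Analysis pipeline for a plant-domestication herbivory study: do migratory
locust nymphs (*Locusta migratoria*) feed differently on wild emmer wheat
(*Triticum turgidum dicoccoides*) than on its modern domesticated progeny,
durum wheat (*T. turgidum durum*), and which leaf traits explain the
difference?

The package implements every stage of the analysis as a tested library, with
a synthetic-data generator standing in for the field and laboratory tables
so the whole pipeline runs and is verifiable without any data download.

## What it computes

**Leaf traits** (`wheatlocust.traits`). From raw morphology, shear-test and
nutrient tables, five herbivory-related traits per accession:

- specific leaf area `SLA = area / dry mass` (cm² g⁻¹) and leaf dry matter
  content `LDMC = dry mass (mg) / water-saturated fresh mass (g)`;
- indirect leaf thickness `LT = (SLA × LDMC)⁻¹` (μm), so the identity
  `LT · SLA · LDMC = 10⁴` holds on every row;
- leaf toughness as specific work to shear: the trapezoidal integral of
  blade force over displacement, divided by the horizontal cut length
  (`L = Δz / tan(blade angle)`) and standardized by leaf thickness;
- nitrogen (LNC), soluble protein (LPrC) and digestible carbohydrate (LChC)
  contents, their sum and the protein:carbohydrate ratio, compared with the
  locust's optimal intake ratio (0.7–1.0).

**Feeding selectivity** (`wheatlocust.selectivity`). Per paired-choice trial,
consumed dry biomass = (control − uneaten disk area)/SLA and the feeding
selectivity FS = share of total consumed biomass (the two sides sum to 1).
A paired t-test compares wild vs modern FS.  Accession-level preference is
modelled with one latent score BS ∈ [−0.5, 0.5] per accession,

    P(choose wild) = 0.5 + BS_wild − BS_modern,

with shifted Beta(2,2) priors centred on 0, sampled by component-wise
random-walk Metropolis (4 chains × 100,000 steps, burn-in 10,000, thinned by
10; proposal scales auto-tuned in burn-in; split-R̂ convergence check).  A
brute-force grid posterior serves as an independent oracle on small
problems.

**Feeding damage** (`wheatlocust.damage`). Ordinal 0–4 damage scores are
fitted with a cumulative-logit mixed model
`P(FD ≤ c) = logistic(θ_c − β·modern − u_accession)`, `u ~ N(0, σ²)`,
the accession intercepts integrated out by a Laplace approximation (inner
Newton on each intercept, outer L-BFGS-B).  The subspecies effect is tested
by likelihood ratio and reported with the Shannon transform
`S = −log₂(p)` bits.

**Multivariate syndrome** (`wheatlocust.multivariate`). Correlation-matrix
PCA of the five traits, two-group MANOVA (Wilks Λ, exact F), a unit-norm
linear discriminant function (LNC coefficient fixed positive), vector
fitting of the herbivore responses onto PCs with eigenvalue ≥ 1, and linear
regressions of both responses on the discriminant scores.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
experiment (10 + 10 accessions, 100 choice trials, 12 herbivory cages × 20
plants) and write their tables to `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_traits.py
python analysis/03_selectivity.py
python analysis/04_damage.py
python analysis/05_multivariate.py
```

Output from the committed run (seed 20230117):

```
P:C ratio mean [min-max] = 3.5 [2.1-8.1] (every accession protein-biased ...)
nitrogen-to-protein factor 3.81 (corr LNC-LPrC 0.65)
paired t-test (100 trials): mean FS difference +7.7 pp in favour of the wild accession (t = 1.44, p = 0.15)
CLMM ... subspecies (modern) effect: -1.981 log-odds (SE 0.282)
  LRT: chi2 = 28.20, p = 1.1e-07, S = 24 bits
PCA: PC1+PC2 explain 73.4% (eigenvalues 2.44, 1.23)
MANOVA: Wilks lambda = 0.121, F(5,14) = 20.39, p = 5.6e-06
discriminant function: DF = -0.373 lt_um +0.528 sws +0.697 lnc_pct +0.295 macronutrient_sum +0.088 macronutrient_ratio
FD: vector fit r2 = 0.54 (perm p = 0.001); DF slope -0.378 (p = 0.00011, S = 14 bits)
```

Reading: leaves of all accessions are strongly protein-biased relative to
the locust's intake target; the modern subspecies is tougher and richer in
nitrogen (positive `sws`/`lnc_pct` discriminant coefficients) and suffers
markedly less feeding damage (negative DF→FD slope).  With a single choice
trial per pair the selectivity signal is directionally consistent (wild
preferred) but individually noisy — visible in the wide t-test p at this
seed.

The same pipeline is available as a CLI (`wheatlocust simulate|traits|
selectivity|damage|multivariate|run`) and as one call,
`wheatlocust.io.run_pipeline(RunConfig(...))`, which also writes a
`manifest.json` recording the seed, settings and SHA-256 hashes of every
input.

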