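# Methods

## The data-generating model

The simulator emulates a full-factorial inbred-line ageing study. For
feature *i* and a sample from line *l*, sex *s* (±1, males positive)
and age rank *r* (u = r/(k−1) − 1/2 ∈ [−0.5, 0.5] over k ordered ages),
the log intensity is

    log Y = b_i + a_i·u + x_i·s/2 + g_il + (a×s)_i·u·s
            + (a×g)_il·u + (s×g)_il·s/2 + ε,   ε ~ N(0, σ²_W)

and the raw intensity is exp(log Y) — a log-normal intensity model, so
effects are additive on the log scale the analysis works on. Defaults
(chosen once, as study conditions):

- design: 15 lines, 2 sexes, ages {3,10,24,36,51,66,81} d, 2 replicate
  pools of 3 flies per cell (420 samples); columns AE: 3091 and
  C18: 3714 features with 30% of chemicals shared (shared features
  carry the same planted truth and m/z but independent noise);
- baseline b ~ N(12, 1) log units (raw intensities ~ 10⁵, a realistic
  ion-count scale);
- residual variance σ²_W = 0.25 (≈28% coefficient of variation, typical
  of biological replicates in untargeted LC-MS); between-line variance
  σ²_B = 0.05 for genotype-affected features (intraclass correlation
  ≈ 0.17, inside the 0–0.32 range such screens report). Recovery
  experiments that target specific intraclass correlations use
  σ²_W = 3 and set σ²_B = t/(1−t)·σ²_W;
- effect sizes: fixed at 2·σ_W (the total young-to-old span for age
  effects, the male–female difference for sex, and the SD of per-line
  deviations for genotype-containing terms), planted on ~10% of
  features per factor. Assignments are independent, so a feature can
  carry several effects;
- age trends are linear in age rank by default; a "hump" mode plants a
  symmetric non-monotone profile whose linear contrast is zero, to
  exercise the ordered-factor machinery;
- missingness is left-censoring-like: P(missing) is logistic in log
  intensity with steepness 3 per log unit, centred (by root-finding) so
  the overall rate hits the 2% target. Steepness ∞ censors exactly the
  lowest quantile; steepness 0 degrades to intensity-independent
  dropout. Missing cells are absent values, never zeros;
- 25% of features receive a compound identity (observed m/z = neutral
  mass + proton, jittered up to ±3 ppm); pathways group those compounds,
  and "enriched" pathways draw members preferentially from age-affected
  features.

What the generator does **not** emulate: technical duplicate
injections and their merging (real studies run each extract multiple
times; we emit one value per biological sample), instrument drift and
batch effects, retention-time structure, correlated (adduct/isotope)
features, and real pathway topology. Passing tests therefore
demonstrate that the statistical machinery recovers what it claims
under the stated noise model — not that any given real dataset
satisfies that model.

## Quality control

Steps run in a fixed order: SNR filter → log transform → per-sex
missingness filter → LS imputation → m/z < 900 filter → per-sample
centring. Numerical conventions:

- SNR = mean/sample SD over observed raw intensities. Features with
  fewer than two observations are removed (SD undefined); constant
  features (SD exactly 0) are kept and flagged, since they carry no
  measurable noise and removal would be arbitrary.
- The SNR default threshold of 15 presumes a reproducibility-style
  variance estimate (technical replicates or a pooled standard). On
  biological samples, mean/SD ≥ 15 implies <7% CV and would remove most
  genuinely varying features, which is why the bundled example configs
  use a threshold of 0.5 when the cascade runs on simulated biological
  variance. The threshold is a config knob; the rule itself is fixed.
- The missingness rule is strict: a feature is removed iff missing from
  *more than* 5% of male samples or more than 5% of female samples.
- Imputation is the gene-wise least-squares variant: for a missing cell
  (i, j), the K = 10 features most |Pearson-r|-correlated with i (over
  jointly observed samples, minimum overlap 3) that are observed at j
  each contribute a single-regressor prediction, combined with weights
  ∝ r²; with no eligible neighbour the feature mean is used and the
  fallback is logged. Observed cells are never altered.
- Centring subtracts each sample's mean over features (to ~1e-16;
  asserted at 1e-10).

## Per-feature models

Age is an ordered factor: orthogonal polynomial contrasts over its
(equally spaced) ranks, so the degree-1 coefficient is the linear
trend. Sex is one ±1 contrast; genotype is deviation-coded. The model
is A + S + G + A·S + A·G + S·G, with the three-way term available as an
option (neither configuration is asserted as canonical). The oldest age
is dropped by default (`drop_age=(81,)`): in the emulated design that
cohort is small and incomplete.

Age, sex and age·sex are tested by partial F-tests. Genotype-containing
terms are tested by a likelihood-ratio statistic 2Δℓ = n·log(RSS₀/RSS₁)
on nested OLS fits. Its p-value is evaluated, by default, against the
statistic's **exact finite-sample null** — a monotone transform of the
partial-F distribution — rather than the asymptotic χ²: with Δdf up to
70 at n = 360 the χ² reference is grossly anticonservative (a null
feature lands below p = 10⁻³ about 6% of the time), which would destroy
FDR control. The classical χ² reference is available as
`genotype_test="chi2"`.

BH FDR runs separately per factor across features within a column
(columns are never merged; their chemistries differ). Direction labels
come from the sign of the linear age contrast and of the sex contrast,
assigned only to significant features; coefficients within 1e-10 of
zero are labelled "flat" and excluded from both direction counts. Ties
in ranked selections break by feature id for reproducibility.

## Heritability

The per-feature mixed model treats age and sex as fixed and line as a
single random intercept. REML is the default: after projecting out the
fixed effects with an orthonormal complement basis (computed once per
design), the restricted likelihood is a function of the single variance
ratio λ = σ²_B/σ²_W and is minimised on log λ ∈ [−30, 30]; σ²_W is then
profiled in closed form. The λ = 0 boundary is compared explicitly, and
estimates at the upper boundary (zero within-line variance) are
reported as t → 1−ε with a flag. Degenerate constant features return
(0, 0) and t = 0, flagged. The ANOVA method-of-moments estimator
(between/within mean squares of fixed-effect-adjusted residuals,
negative estimates truncated to zero) is retained as an independently
checkable oracle; a test also cross-checks REML against an external
mixed-model implementation.

The heritability proxy is the plain intraclass correlation
t = σ²_B/(σ²_B + σ²_W). Because each measured sample pools n = 3
individuals, a variant t = σ²_B/(σ²_B + σ²_W/n) is available behind the
`pooled_n` option; the plain ICC is the default and no conversion to
narrow-sense h² is attempted. Features are ranked per column (ties by
id), flagged at t ≥ 0.05, and the top 150 per column feed enrichment.

## PLS and sparse PLS-DA

NIPALS was chosen over SIMPLS for transparency; its correctness oracle
is the least-squares limit (at full-rank component count the PLS
prediction equals the normal-equations fit, asserted at 1e-8), and
successive scores are orthogonal by construction (asserted at 1e-8).
PLS regression centres X and y (no scaling by default); PLS-DA
regresses on the centred class-indicator matrix with unit-variance
scaling of X (the convention of standard discriminant implementations),
k−1 components for k classes, and classifies by nearest training-class
centroid in score space (the prediction rule is an artifact choice; the
distance metric of reference implementations is not standardised).
Sparsity hard-truncates each weight vector to the `keep` largest
absolute entries before the score is computed; the default grid is
{1, 2, 3, 4, 5, 10, 25, 50}. Degenerate weight vectors (zero norm after
truncation) raise; an exhausted response simply stops component
extraction early.

Validation: `keep` is chosen to minimise stratified ten-fold CV error
(ties → smallest keep). That minimised curve is the reported optimum,
but it is biased below chance under the null (minimum of noisy fold
means), so permutation comparisons use **nested CV** — the grid search
re-run inside every outer training fold — whose null distribution is
centred at chance; the CLI reports both. Age prediction uses random
2/3–1/3 splits repeated 20 times, the component count re-chosen by CV
inside each training set (capped at 10), and R² defined as the squared
Pearson correlation of predicted vs observed on the held-out third.
Permutation nulls (default 10 label permutations, without replacement)
re-run the complete pipeline per permutation; fold assignment, splits
and permutations are all derived from explicit seeds.

## Annotation and enrichment

Features are matched to compounds by positive-mode adduct mass (M+H,
M+Na, M+K, M+H−H₂O; the adduct list and the 10 ppm tolerance are
configurable artifact choices consistent with a 30k-resolution
instrument). A feature may match many compounds and vice versa; no
candidate resolution is attempted. Instead, the pathway statistic —
the number of selected features with at least one candidate compound in
the pathway — is compared against random same-size selections from the
full feature list, annotated with identical rules, so the ambiguity
contributes identically to observed and null counts and calibration is
preserved. This deliberately replaces network-module/activity scoring
of full annotation engines with the minimal calibrated core; it ranks
a planted enriched pathway first but makes no claim to resolve
identities.

Empirical p-values use the add-one estimator (1 + #{null ≥ obs})/(1 +
n_perm) ∈ [1/(1+n_perm), 1], which is conservative and discrete. For
calibration *testing* a randomised tie-broken variant (uniform on [0,1]
under the null even with integer-valued statistics) is reported
alongside, plus a compound-level hypergeometric p. The bundled compound
database is a synthetic fixture: real monoisotopic masses for fly
metabolites of interest grouped into illustrative pathway sets, meant
for tests and examples, with a loader for user-supplied
compound/pathway tables.

## Orchestration and reproducibility

One global seed deterministically derives per-stage substreams (seed
sequences keyed by stage), so stages re-run independently yet
reproducibly and a repeated `all` run is byte-identical. All tables are
tab-separated UTF-8 with headers; missing cells are empty fields. The
run manifest records the hash of the scientific configuration (output
location excluded), the seed, and the files each stage produced.

## Problem sizes in the validation suite

Recovery and calibration checks run at reduced feature counts chosen as
the smallest sizes at which the targeted quantities are stable: 200
features per intraclass-correlation level (full 420- or 360-sample
designs), 20 null simulations of 500 features for FDR behaviour, 2000
features for detection/direction recovery, 100 samples x 2000 noise
features for the leakage guards, 999 selection permutations for planted
enrichment and 30 seeds x 199 permutations for null calibration, and a
150 + 150-feature double pipeline run for determinism. The technical
duplicate question (how real studies combine repeated injections) is
left open deliberately; the simulator emits one value per biological
sample.

## Known limitations

- The exact-null LRT default departs from the classical χ² reference
  (see above); both are available, only one can be the default.
- REML assumes Gaussian residuals on the log scale; heavy-tailed
  contamination is not modelled or tested.
- The enrichment null permutes selections of features, not of samples;
  it calibrates annotation ambiguity but not selection-induced
  correlation between pathways sharing compounds.
- Direction labels summarise only the linear component of an ordered
  age trend; genuinely non-monotone trajectories are detected by the
  age F-test but labelled "flat" when their linear contrast vanishes.
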