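# Methods

This note documents the models, conventions and design choices behind
`gaitwomac`, in the package's own terms.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## WOMAC scoring and severity classes

A WOMAC record is 24 integer item responses in 0..4, partitioned 5 pain /
2 stiffness / 17 physical function; the total and subscale scores are plain
sums (no weighting).  Severity cut points come from the midpoints between
adjacent item response levels, 1.5 (mild→moderate) and 2.5
(moderate→severe), multiplied by the item count: 36/60 for the total,
7.5/12.5 (pain), 3/5 (stiffness), 25.5/42.5 (physical function).  Both cut
values classify as *moderate* (the inclusive reading of "between"); a
strict/half-open variant is one flag away
(`classify_severity(..., inclusive_moderate=False)`).  Incomplete or
out-of-range records are rejected; there is no imputation.

## Cycle axis and phase windows

Waveforms live on the 101-point axis 0, 1, …, 100 % of the gait cycle
(endpoints inclusive) — the dominant gait-lab convention.  Raw strides of
arbitrary length ≥ 8 samples are linearly interpolated onto this axis;
multi-trial data are pointwise-averaged after normalization.

The cycle splits at toe-off (default 60 %, configurable 30–80 %; per-subject
toe-off may be supplied via a phase CSV).  Stance sub-phases follow the
standard proportional split — loading response the first 1/6 of stance,
mid-stance and terminal stance 2/6 each, pre-swing the last 1/6 (the classic
0/10/30/50/60 boundaries at 60 % toe-off) — and swing splits into equal
thirds.  Windows are half-open `[start, end)` with the final window closed
at 100, so the seven sub-phases partition the cycle exactly and
concatenating their slices reproduces the waveform bit-for-bit.  Compound
windows (adjacent sub-phases, e.g. terminal stance through pre-swing) are
unions.

## Feature operators

All operators are deterministic functions of a sample vector:

- Summary statistics use the n−1 denominator for SD/variance.  Kurtosis is
  the **non-excess** fourth standardized moment `m4/m2²` with n-denominator
  moments (Gaussian → 3); this matches crest-factor-style reporting where
  values near 2 are sub-Gaussian.  `peak2rms` is the crest factor
  `max|x| / rms`.
- Areas under the curve are signed trapezoidal integrals of value against
  cycle percent (units: value·% cycle).
- Spectral features use the one-sided boxcar periodogram of the
  mean-removed signal with a 1 %-of-cycle sampling interval, so frequencies
  are in cycles per % of cycle and the rectangle sum of the density equals
  the population variance (Parseval).  `psd_auc` is the trapezoidal
  integral of the density.  The occupied bandwidth is the width of the
  interval that excludes the lowest and highest 0.5 % of cumulative power
  (99 % occupancy, configurable); each frequency bin's power is treated as
  uniform over its df-wide bin when interpolating the crossing points, so a
  pure tone yields a band of just under one bin width that brackets the
  tone.
- The autocorrelation lower bound is `min_{k≥1} r(k)` of the biased,
  mean-removed, normalized autocorrelation.
- The mid-reference level estimates the two state levels of a nominally
  bilevel signal by the bimodal-histogram method (100 bins; mode of the
  lower and upper halves of the occupied bins) and returns their midpoint;
  a constant signal is its own level.
- DTW uses the absolute-difference local cost (squared as a config switch),
  the unit step pattern {(1,0),(0,1),(1,1)}, boundary alignment and no
  warping window, returning the accumulated optimal-path cost.  The kernel
  is numba-compiled with a pure-Python fallback.

The default registry is the grid (11 summary statistics + AUC) × 10 windows
(full, stance, swing, 7 sub-phases) × 12 waveform parameters, plus the four
spectral features, the autocorrelation lower bound, the mid-reference level
and the stance/swing DTW distance per parameter, plus spatiotemporal
identity features — 1528 features by default.  A pinned 42-feature key
registry (windowed extrema, AUCs, crest factors, spectral and
autocorrelation descriptors across hip, pelvis, knee, ankle, foot and
spatiotemporal parameters) is available as `key_feature_registry()`.
Statistics undefined for a subject (zero-variance kurtosis, zero-signal
crest factor) are masked, and any feature masked for any subject is dropped
before selection with a logged warning.

One registry caveat: published tables of this feature family sometimes show
"mid-reference level" magnitudes (hundreds) that are irreconcilable with
the plain state-level definition for signals in single-digit degrees.  The
plain definition is implemented; no reverse-engineering was attempted.

## Selection

Per feature: classical one-way fixed-effects ANOVA across the three
severity classes (α₁ = 0.0001), then two-sided pooled-variance Student
t-tests for the three class pairs (α₂ = 0.00003, the printed Bonferroni
level; the exact 0.0001/3 and a Welch variant are config switches),
computed only for ANOVA passers.  Key features pass all three pairwise
comparisons; they are returned ordered by ascending ANOVA p (ties broken by
feature id).  Subscale association repeats both gates with classes defined
by each subscale's own cut points; a subscale whose classes cannot support
the tests is flagged unevaluable and the others proceed.  Zero pooled
variance makes a pairwise p undefined (NaN) and fails the gate.

## Synthetic cohort generator

The generator exists so that selection and estimation can be tested against
a known ground truth; it is **not** a biomechanical simulation.

A single latent severity ℓ ∈ [0, 1] drives both gait and WOMAC.  Subjects
are generated per group (default 140/182/53) with group latent means
0.15/0.5/0.85 and within-group SD 0.07 (z truncated at ±2.1 so latents stay
in [0, 1]).

**WOMAC.**  Within group g, the total is
`clip(loc_g + s_g · u, 0, 96)` with `u = (ρ z + √(1−ρ²) ε)/sd_u`
standardized to unit variance, ρ = 0.6 the latent–WOMAC coupling, and
`loc_g` solved by quadrature so the censored mean equals the target group
mean — 18.9 (11.9), 48.5 (6.8), 71.7 (10.3) points for mild/moderate/severe.
Totals are decomposed into items proportionally to subscale item counts
(largest-remainder rounding), spread multinomially within a subscale and
capped at 4 with deterministic redistribution, so records are always
internally consistent.  A `subscale_decoupled` option replaces one
subscale's target with an independent binomial draw, destroying its
severity association for calibration tests.

**Waveforms.**  Each parameter is a smooth periodic template (harmonic /
von-Mises-bump mixtures) plus a severity effect plus smooth subject noise
(random offset + harmonics 1–6 with per-parameter weights).  Default
effects, directions consistent with the severity-discriminating key-feature
pattern:

| parameter | effect | consequence |
|---|---|---|
| knee varus angle | multiplicative scale, +0.80·ℓ | stance/full AUC, RMS, extrema, mid-reference level increase |
| hip adduction angle | multiplicative scale, −0.65·ℓ | level features decrease |
| knee flexion angle | mean-centred excursion compression, −0.85·ℓ | variance, SD, range, spectral AUC decrease; mean level unchanged |
| total speed | −16 cm/s per unit ℓ | decreases |
| single-limb support | −4.5 % cycle per unit ℓ | decreases |
| initial double-limb support | +4.5 % cycle per unit ℓ | increases |

Templates for the scaled parameters are deliberately near-flat and
positive, and the knee flexion template is a single swing bump: these
shapes make the induced feature effects *bimodal* — a feature either moves
far beyond the selection thresholds or stays far below them — which is what
makes recovery tests sharp.  Physiological realism is limited to
qualitative shape; amplitudes, flatness and noise composition are chosen
for statistical structure, and the `weight_acceptance_timing` scalar and
the remaining nine waveform parameters carry no effect (they are the null
background).

**Planted ground truth.**  `planted_truth(config)` declares a feature
planted when its *pairwise detectability score* — the minimum over the
three class pairs of the pairwise Cohen's d divided by that pair's critical
effect size at α₂ and the study-scale class sizes, estimated from one large
internal cohort (4× group sizes, config-derived seed, classes from the
generated WOMAC totals exactly as the analysis defines them) — reaches
0.75.  A score of 1.0 is the 50 %-power edge of the selection procedure;
placing the threshold at 0.75 counts borderline features as planted, so
they can cost sensitivity (which has ample slack) instead of appearing as
false positives.  The pairwise form matters: the severe class has larger
within-class variance, so a globally pooled SD would understate
detectability.

**Attainable estimation accuracy.**  A model that recovers ℓ perfectly can
predict at best `E[WOMAC | ℓ]`; `attainable_correlation(config)` computes
`Cor(E[y|ℓ], y)` by Monte Carlo on the WOMAC generative model alone
(censored-normal conditional means in closed form), under the class-balanced
sampling the estimation stage uses.  Hold-out linear-model correlations on
synthetic cohorts should approach this ceiling from below; published
real-data correlations for this kind of model (≈ 0.72–0.74) are far lower
because real gait–symptom coupling is noisier — passing the synthetic
recovery test validates the pipeline, not the clinical effect size.

## Estimation protocol

Balancing trims the current largest severity class one subject at a time
until the target total (default 231) is reached — (140, 182, 53) →
(89, 89, 53) — keeping minority classes intact; the trimmed subjects are
chosen uniformly at random (seeded).  The hold-out split is stratified by
class with train size `round(0.7 n)` (largest-remainder rounding across
classes).  The linear model is OLS with intercept; by default the pipeline
caps its design at the top 20 key features by ANOVA p (gait features are
strongly collinear — means, AUCs and RMS of the same window nearly
duplicate one another), and a numerically rank-deficient design either
fails loudly naming the collinear columns or falls back to the minimum-norm
pseudo-inverse (`on_collinear="pinv"`, the pipeline default).  The random
forest uses 500 trees, ⅓ of features per split, unlimited depth, minimum
leaf 5, seeded.  The forest is evaluated on the hold-out set; the linear
model reports both in-sample and hold-out metrics, labelled.  RMSE is in
WOMAC points; the correlation is the sample Pearson r between actual and
estimated totals (undefined for constant actuals; constant predictions
report r = 0).

## Numerical choices and degenerate inputs

- Window index sets use a 1e-9 tolerance against floating boundary error so
  proportional sub-phase splits are exact for any toe-off.
- `evaluate` requires ≥ 3 pairs; `holdout_split` ≥ 10 subjects;
  `balance_downsample` rejects targets that cannot keep every class.
- Pairwise tests on zero-variance pairs yield NaN and fail the gate rather
  than raising, so one degenerate feature cannot abort a selection run.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline artifacts carry no timestamps, so identical configs give
  byte-identical outputs.
- Simulation sizes in the test suite (100 null resimulations, 20 planted
  seeds, 50 estimation seeds, 200 label permutations) were chosen as the
  smallest runs that make the statistical assertions stable across seeds.

## Known limitations

- CSV only; no C3D or marker-level processing, no gait-event detection —
  the package starts from normalized or raw per-cycle waveforms.
- Right leg only; no bilateral symmetry features.
- The synthetic generator omits trial-to-trial within-subject variability
  and models severity with a single latent scalar; passing tests therefore
  demonstrates correctness of the statistical machinery under a known
  model, not performance on real gait data.
- No FDR or permutation-based selection in the headline path; no
  cross-validation or external validation of the estimation models.
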