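# Methods

`cbmfrax` implements a surface-based analysis of proximal-femur cortical
bone for hip-fracture-type risk: per-vertex cortical measurement from
blurred CT-like density profiles, vertex-wise statistical parametric
mapping (SPM) with permutation multiplicity control to discover
fracture-type-specific patches, Barlow-weighted case-cohort Cox hazard
modelling, cross-validated logistic prediction, and paired-scan precision
estimation.  Because no public cohort with per-vertex QCT measurements
exists, the package ships a first-class synthetic-data module that
generates every input with known ground truth; all calibration and
recovery claims below are claims about that generative model.

## Cortical measurement from blurred profiles

A density profile along the surface normal is modelled as a three-level
step — soft tissue `y0`, cortex `y1` (CBMD, mg/cm³) over `[x0, x1]`,
trabecular bone `y2` — convolved with a Gaussian point-spread function of
SD `sigma` (mm):

    y(x) = y0 + (y1 − y0) Φ((x − x0)/σ) + (y2 − y1) Φ((x − x1)/σ)

Derived variables: cortical thickness CTh = x1 − x0 (mm), cortical mass
surface density CM = 0.1·CTh·y1 (mg/cm²), CBMD = y1, and endocortical
trabecular density ECTD either as the fitted `y2` (point convention,
default) or as the exact analytic mean of the fitted model over
`[x1 + σ, x1 + σ + 3 mm]` (band convention; the averaging depth for "close
to the cortex" is not canonical, so both conventions are exposed and
recorded in outputs).

Fitting is bounded nonlinear least squares with `x1` reparametrized as
`x0 + w`, `w ≥ 0` (the edge ordering is structural, not a penalty), `σ`
fitted in log-space, three starts on `x0` spread over the profile support,
lowest residual winning with ties broken toward the smaller thickness.
Parameter/function tolerances are 1e-10; a fit that exhausts its
evaluation budget is flagged non-converged and its measurements are
reported missing.  Constant or monotone profiles (no cortical peak) raise
a degenerate-input error.

Two modes matter scientifically.  The **free** mode estimates all six
parameters and is accurate when the cortex is comfortably wider than the
blur.  Below the blur width, thickness and density are jointly
unidentifiable in practice: a wide faint cortex and a thin dense one
produce profiles that differ by less than the intensity discretization of
a reconstructed CT image.  The **constrained-density** mode fixes `y1` at
a subject-global cortical density (the median free-mode `y1` over profiles
with CTh > 2σ) and estimates the rest, which keeps the *mass* CM
identifiable arbitrarily far below resolution.  The profile renderer
discretizes intensities to 1 mg/cm³ by default — the granularity of a
calibrated reconstruction — because with mathematically exact float64
profiles the free fit can still locate the zero-residual truth and the
identifiability failure the constrained mode exists to solve would be
invisible.  On discretized noise-free profiles at σ = 1.5 mm the sweep
CTh ∈ [0.3, 1.5] mm gives constrained-mode CM errors ≤ 0.5% while
free-mode CTh errors range from several percent to several hundred
percent; on exact profiles the free fit round-trips all parameters to
better than 1%.

## Synthetic cohort

The canonical surface is a closed sphere-topology surface of revolution
(head bulge, neck waist, trochanteric flare with a superolateral lobe,
shaft stub), ~2000 vertices by default (configurable; kept below
segmentation-scale meshes for desk-scale runtime), with every vertex
labelled by anatomical region.  A seeded 0.05 mm jitter makes distinct
seeds produce distinct geometry.

Per-subject fields are generated as

    field(v) = baseline(v) · (1 + covariate terms + u·loading + ε(v))

where `baseline(v)` is a smoothed regional profile (superior neck cortex
thin, shaft thick, trabecular density high in the head, low in the shaft)
around CTh 1.6 mm, CBMD 1100 mg/cm³, ECTD 170 mg/cm³ — chosen so the
implied CM (~176 mg/cm²) and the Table-scale coefficient-of-variation
relationships are realistic; `u` is a global bone-quality factor
(relative SD 0.05); `ε` is white noise smoothed over the 2-ring
(relative SD 0.10 for CTh/ECTD, 0.05 for CBMD).  CM ≡ 0.1·CTh·CBMD holds
identically at every vertex of every hip.  Left and right hips are the
common truth times independent 5% noise, so the two sides are strongly
correlated.  Covariates: age truncated-normal (74, 6) at ≥ 65 years,
weight N(84, 14) kg, height N(174, 7) cm, six clinical sites with small
calibration offsets.

Fracture-type structure is *labels-from-hazard*: each subject carries two
latent risk scores (correlated 0.3 with low bone quality); the upper half
on each score receives a −10% deficit in CTh and ECTD inside that type's
region (superolateral trochanter for trochanteric risk, superior femoral
neck for neck risk).  Fracture times then come from two competing
exponential processes whose log-rates are linear in the standardized
own-region CM and ECTD means and in age (β = −0.55, −0.75 per SD, and
0.59 per 5 years); the first event inside the 10-year horizon sets the
type, otherwise the subject is censored at the horizon.  Baseline rates
(0.0015 / 0.0019 per year) are inflated relative to a realistic elderly
male cohort so that a desk-scale population of ~1200–1500 yields on the
order of 100 cases — it is the absolute case count, not the rate, that
drives the power of the surface statistics and the prediction models.

The balance between the global factor (0.05) and the regional deficit
(−10% on half the subjects, also 0.05 relative SD in the patch mean) is a
deliberate design point: if the global factor dominates, case-vs-cohort
contrast maps go surface-wide, the discovered "patches" approach the whole
surface, and their means collapse onto any global BMD surrogate.  With
comparable weights the patches localize and genuinely carry type-specific
information, which is the phenomenon the model-comparison analysis needs
to exhibit.

Global BMD surrogates (`bmd_dxa_like` g/cm², `bmd_qct_like` g/cm³) are
noisy monotone functions of the whole-surface CM and ECTD means — the
correlation structure is what matters for model comparison; projection
physics is out of scope.  Shape scores are small independent confounder
columns by default; the pipeline replaces them with genuine principal
shape-mode scores computed from generated per-subject meshes.

What the generator does **not** emulate: real registration error and its
spatially structured artifacts (shape scores stand in as confounders
only), acetabulum-adjacent segmentation failure (representable only as
elevated noise), scanner-specific calibration drift beyond additive site
offsets, non-proportional hazards, and any skeletal geometry beyond the
stylized landmark regions.  Passing tests therefore demonstrate that the
estimators are correct and calibrated under the stated generative model,
not that the effect sizes transfer to real cohorts.

## Surface SPM and patch discovery

At every vertex an ordinary least-squares GLM regresses the combined
(left/right averaged) field on the trimodal fracture factor (two
indicators against none), age, weight, clinical site dummies and five
shape scores; weight is a confounder here while height (not weight) is
the anthropometric covariate in the hazard and prediction models — an
asymmetry kept deliberately.  Effect sizes are reported as the indicator
coefficient in percent of the vertex-wise mean (undefined where the mean
is not positive — trabecular means can approach zero, where percentages
are flagged unstable).

Multiplicity is controlled by permutation cluster-mass FWER: vertices
with two-sided p < 0.001 form clusters on the mesh edge graph (tails kept
separate), a null of the maximum cluster |t| mass is built by permuting
fracture labels (covariates stay attached to subjects), and clusters with
permutation p < 0.05 (with the +1 correction) survive.  The patch for a
contrast is the union of its surviving clusters.  Measured level over 300
independent null replicates: 4.0%.  A Bonferroni per-vertex mode exists
as a cross-check.  When nothing survives — inevitable in small
leave-one-out folds — the patch falls back to the uncorrected p < 0.001
mask, then to the top 1% of |t| vertices, always flagged in provenance;
downstream consumers see the flag, never a silent empty patch.

Only CM and ECTD patch means are carried into the hazard and prediction
models; CTh and CBMD patches are produced for reporting, and the model
layer rejects them unless explicitly overridden.

## Case-cohort Cox with Barlow weights

The case-cohort sample is all incident cases plus a simple random
subcohort of round(α·N) drawn from the whole population (overlap
allowed).  Barlow's pseudo-likelihood is implemented by dataset
construction: non-case subcohort members contribute one record over
(0, T] with weight 1/α; cases outside the subcohort enter only at their
event (weight 1); cases inside the subcohort contribute a weighted
control record up to just before their event and a weight-1 event record.
The weighted Cox fit (Breslow ties, all subjects entering at baseline)
uses lifelines with late entry, weights and robust sandwich variance
clustered on subject.  With α = 1 the construction reproduces an ordinary
Cox fit exactly (coefficients agree to 1e-6; observed 2e-16).

Hazard ratios follow the reporting convention: per 1 SD decrease for
imaging variables (SD computed on the subcohort, the
population-representative sample; the sign flip makes deficits read as
risk ratios > 1), per 5-year increase for age and per 1 SD increase for
height, the latter two from unadjusted models; imaging variables are
adjusted for age, height and site.  Competing fracture types are handled
by censoring at the competing event.  Significance is reported at
p < 0.005 throughout (a conservative Bonferroni convention for ~10
candidate variables).  Calibration under the generative model: median
per-SD-decrease HR estimate 2.0 (band [1.85, 2.15]) at true HR 2.0,
n = 2000, α = 0.1; null-exposure 95% CI coverage 93–97%.

## Prediction models and cross-validation

Ten-year incidence is modelled by maximum-likelihood binomial (any
fracture) or trichotomous multinomial (none/trochanteric/neck, reference
none) logistic regression on base model m = age + height + site plus
imaging variables; subjects fracturing after the horizon count as
non-fractured.  Logistic fits on the analysis sample are unweighted (a
weighted variant is a one-line extension; the case-cohort over-sampling
shifts intercepts, not discrimination).  Perfect separation is flagged,
not raised; Newton with warm starts falls back to cold Newton and BFGS.

Evaluation is leave-one-out: for each subject the model — and, when it
contains patch variables, the SPM patch discovery itself — is refitted
without that subject, and the held-out probability is recorded.  The
permutation null for cluster significance is computed once per response
variable on the full sample and shared across folds (one fixed seed per
run); recomputing it per fold would multiply runtime by the fold count
while changing nothing about the held-out subject's exclusion from the
*observed* statistics.  A fold whose fit separates falls back to training
class frequencies and is recorded in fold provenance.  AUC is
Mann-Whitney (ties ½, equal to the trapezoidal ROC area) with
outcome-stratified percentile bootstrap CIs; model deviance is −2 Σ log
p(observed class) over the cross-validated probabilities, and nested
models are compared by χ² on the deviance difference (non-nested requests
raise).  A negative cross-validated deviance difference — possible
because these are out-of-sample quantities — reads as no evidence for the
larger model (p = 1).

## Precision

With zero-mean measurement error, scan1 − scan2 has twice the error
variance, so the per-vertex error SD is √(Var(differences)/2) with the
n−1 denominator (19 pairs → 18 df).  Patch-level precision averages each
scan over the patch *first*, then applies the same estimator to the patch
means, so spatially independent error shrinks by ~√(patch size).
Reported normalizations: absolute SD, SD as % of the cohort mean (CV%),
SD as % of the cohort between-subject SD (≈ half the 95% minimum
detectable difference, 1.96·√2·SD), with zero-cohort-SD columns marked
undefined.

## Pipeline

`run_pipeline` executes generate → measure → map → SPM → Cox → predict →
precision from one YAML config in which every stochastic stage carries an
explicit seed; missing required fields raise a config error naming the
dotted field.  Stages before SPM never see fracture labels (labels join
at the SPM stage by interface).  Outputs are the four reporting tables as
CSV, per-vertex effect and precision maps as CSV and ASCII PLY scalar
properties (non-significant vertices emitted as missing, not zero), ROC
point sets, a structured per-stage log, and a manifest with the config
hash and a SHA-256 per output file; identical configs reproduce identical
checksums.  Profile measurement inside the pipeline runs on a configured
subsample of vertices and subjects as a fidelity check — the per-vertex
fields consumed downstream come from the generator, whose side noise
already stands in for measurement error; fitting every vertex of every
subject would add hours for no statistical gain at desk scale.

## Problem sizes used in the checks

Chosen as the package's own desk-scale defaults: surfaces of ~1000–2000
vertices; SPM calibration with 100 null replicates × 300 permutations
(n = 250, 60 cases) and recovery over 5 replicates at n = 400, 100 cases,
500 permutations; Cox studies with 150–200 replicates at n = 1500–2000,
α = 0.1; the model-comparison analogue with 15–25 replicates of a
1200-subject population sampled at α = 8.8%, 200 permutations inside the
leave-one-out SPM.  The acceptance script reports each quantity together
with the size actually used.

## Known limitations

Registration is correspondence application, not non-rigid surface
matching; the free/constrained identifiability contrast depends on the
modelled intensity discretization; the FWER procedure is mildly
conservative (cluster-mass with a shared null across LOO folds); odds
ratios from quasi-separated small folds rely on the fallback path; and
all headline comparisons are statements about the synthetic generative
model, not about any real cohort.
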