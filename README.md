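# cbmfrax

Surface-based cortical bone mapping (CBM) analysis of hip-fracture-type
risk, as a tested, reusable Python pipeline.

Hip fracture risk is usually summarised by a single areal or volumetric
bone mineral density (BMD), which is specific but insensitive: most people
who fracture are not flagged.  Trochanteric and femoral neck fractures,
however, relate to *where* on the proximal femur cortical and trabecular
bone is deficient.  CBM measures cortical properties independently at
thousands of vertices on a femur surface from clinical CT, finds the
fracture-type-specific regions by vertex-wise statistics rather than
pre-drawn anatomical ROIs, and feeds the per-subject regional summaries
into survival and prediction models.  This package implements that whole
chain for biostatisticians and bone-imaging researchers, together with a
synthetic-cohort generator (no per-vertex QCT cohort is publicly
deposited) so every stage is testable end-to-end with known ground truth.

## What it computes

**Measurement.** A density profile along the surface normal is the
three-level step (soft tissue y₀, cortex y₁, trabecular y₂) blurred by the
scanner point-spread function:

    y(x) = y₀ + (y₁ − y₀) Φ((x − x₀)/σ) + (y₂ − y₁) Φ((x − x₁)/σ)

giving cortical thickness CTh = x₁ − x₀ (mm), cortical BMD CBMD = y₁
(mg/cm³), cortical mass surface density CM = 0.1·CTh·CBMD (mg/cm²) and
endocortical trabecular density ECTD (mg/cm³).  For cortices thinner than
the blur, thickness and density are not separately identifiable;
constraining y₁ at a subject-global cortical density keeps the *mass* CM
accurate well below the imaging resolution.

**Patch discovery.** A GLM at every vertex (fracture factor
none/trochanteric/neck + age, weight, site, five shape-mode scores), with
permutation cluster-mass familywise-error correction on the mesh graph;
surviving clusters form one patch per cortical variable and fracture type.

**Hazards.** Case-cohort Cox regression with Barlow weights (cases weight
1 at their event, subcohort controls 1/α) and robust cluster variance;
hazard ratios per 1 SD decrease, adjusted for age, height and site.

**Prediction.** Binomial and trichotomous multinomial logistic models for
10-year fracture incidence, evaluated by leave-one-out cross-validation
with the patch-discovery SPM re-run inside every fold; ROC AUC with
bootstrap CIs and nested-model deviance χ² tests.

**Precision.** Per-vertex and patch-level measurement SD from paired
repeat scans via the half-variance-of-differences estimator.

## Worked example

```python
import numpy as np
from cbmfrax.mesh import make_canonical_mesh
from cbmfrax.synth import (simulate_population, simulate_fracture_outcomes,
                           draw_case_cohort, render_profiles)
from cbmfrax.profiles import fit_profile
from cbmfrax.cox import fit_weighted_cox

# 1. a cortex thinner than the imaging blur (sigma = 1.5 mm)
profiles = render_profiles(cth=np.array([0.8]), cbmd=np.array([1100.0]),
                           ectd=np.array([170.0]), sigma_blur=1.5, seed=0)
_, free = fit_profile(profiles.profile(0), mode="free")
_, con = fit_profile(profiles.profile(0), mode="constrained_density",
                     y1_fixed=1100.0)
print(f"true CTh 0.80 mm, CM {0.1*0.8*1100:.1f} mg/cm^2")
print(f"free fit:        CTh {free.cth:.2f} mm, CM {free.cm:.1f} mg/cm^2")
print(f"constrained fit: CTh {con.cth:.2f} mm, CM {con.cm:.1f} mg/cm^2")

# 2. synthetic cohort, case-cohort sample, Barlow-weighted Cox
mesh = make_canonical_mesh(1000, seed=0)
pop = simulate_population(mesh, 1200, seed=1)
pop = simulate_fracture_outcomes(pop, seed=2)
sample = draw_case_cohort(pop, alpha=308 / 3515, seed=3)
subjects = pop.subjects.copy()
neck = mesh.region_mask("neck_superior")
subjects["ectd_neck"] = pop.combined_fields("ECTD")[:, neck].mean(axis=1)
fit = fit_weighted_cox(subjects, sample, "ectd_neck", outcome="any",
                       adjust=("age", "height", "site"))
print(f"cases {sample.n_cases}, subcohort {sample.n_subcohort}")
print(f"ECTD neck-region HR per SD decrease: {fit.hazard_ratio:.2f} "
      f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f}), p={fit.p_value:.2g}")
```

prints

```
true CTh 0.80 mm, CM 88.0 mg/cm^2
free fit:        CTh 0.49 mm, CM 84.8 mg/cm^2
constrained fit: CTh 0.80 mm, CM 88.0 mg/cm^2
cases 95, subcohort 105
ECTD neck-region HR per SD decrease: 3.47 (95% CI 1.41-8.55), p=0.0068
```

The free fit misses the sub-resolution thickness by ~40% while the
density-constrained fit recovers the cortical mass exactly; in the
synthetic case-cohort sample, one standard deviation less endocortical
trabecular density in the superior femoral neck roughly triples the
fracture hazard — the generator plants exactly this kind of regional
deficit and links fracture times to it.

## Full pipeline

```sh
cbmfrax all --config run.yaml --out results/
```

runs generate → measure → map → SPM → Cox → predict → precision from one
seeded YAML config and writes the hazard-ratio, odds-ratio, AUC and
precision tables as CSV, per-vertex effect/precision maps as CSV and
ASCII PLY, ROC curves, a structured log, and a checksum manifest
(identical config ⇒ identical checksums).  `cbmfrax measure` batch-fits
profiles from a CSV.  See `docs/methods.md` for the model details,
parameter defaults and design choices.

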