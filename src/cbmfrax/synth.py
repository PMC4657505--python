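"""Synthetic elderly-male case-cohort generator.

Everything the pipeline consumes is generated here: a canonical surface
(:mod:`cbmfrax.mesh`), per-subject cortical fields with covariate effects and
fracture-type-specific deficit geometry, competing-risks fracture outcomes
driven by those fields, case-cohort sampling, paired repeat scans, and
blurred density profiles for the measurement engine.

The generative logic is deliberately *labels-from-hazard*: regional bone
deficits are planted first (superolateral trochanter for trochanteric risk,
superior femoral neck for femoral neck risk), and fracture types then arise
from a proportional-hazards model on the resulting patch means.  Surface
statistics therefore face a realistic inverse problem -- cases differ from
the cohort only through the hazard linkage, not by construction.

Default magnitudes: baseline CTh 1.6 mm, CBMD 1100 mg/cm^3, ECTD 170
mg/cm^3 (hence CM ~ 176 mg/cm^2); regional deficits of -10% in CTh and ECTD
for high-risk subjects; ~10-year follow-up with baseline rates chosen so a
desk-scale population of ~1500 yields on the order of 100 fracture cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import truncnorm

from .errors import InvalidArgumentError
from .mesh import REGION_NAMES, SurfaceMesh
from .profiles import CorticalProfile

VARIABLES = ("CTh", "CBMD", "ECTD", "CM")
PRIMARY_VARIABLES = ("CTh", "CBMD", "ECTD")  # CM is the derived identity
FRACTURE_TYPES = ("trochanteric", "neck")


def _default_region_profiles():
    # smooth regional multipliers of the baseline level; the superior neck
    # cortex is thin and shaft cortex thick, trabecular bone is densest in
    # the head and sparse in the shaft
    return {
        "CTh": {"head": 0.75, "neck_superior": 0.55, "neck_inferior": 1.10,
                "trochanter_superolateral": 0.80, "trochanter_other": 1.00,
                "shaft": 1.60},
        "CBMD": {"head": 1.00, "neck_superior": 0.97, "neck_inferior": 1.02,
                 "trochanter_superolateral": 1.00, "trochanter_other": 1.00,
                 "shaft": 1.05},
        "ECTD": {"head": 1.30, "neck_superior": 0.90, "neck_inferior": 1.10,
                 "trochanter_superolateral": 0.90, "trochanter_other": 1.00,
                 "shaft": 0.50},
    }


@dataclass
class TrueEffectSpec:
    """Ground-truth structure of the synthetic cortical fields.

    ``effect_fraction`` is the relative deficit applied, within the
    fracture-type's patch region, to high-risk subjects (CM inherits
    CTh x CBMD, so the default -0.10 on CTh with 0 on CBMD plants a -10%
    CM deficit).  ``spatial_noise_sd`` / ``subject_sd`` are relative SDs;
    spatial noise is white noise smoothed over the ``smooth_k``-ring.
    """

    baseline: dict = field(default_factory=lambda: {"CTh": 1.6, "CBMD": 1100.0,
                                                    "ECTD": 170.0})
    region_profiles: dict = field(default_factory=_default_region_profiles)
    effect_fraction: dict = field(default_factory=lambda: {"CTh": -0.10,
                                                           "CBMD": 0.0,
                                                           "ECTD": -0.10})
    patch_region: dict = field(default_factory=lambda: {
        "trochanteric": "trochanter_superolateral", "neck": "neck_superior"})
    spatial_noise_sd: dict = field(default_factory=lambda: {"CTh": 0.10,
                                                            "CBMD": 0.05,
                                                            "ECTD": 0.10})
    smooth_k: int = 2
    subject_sd: float = 0.05
    subject_loading: dict = field(default_factory=lambda: {"CTh": 1.0,
                                                           "CBMD": 0.3,
                                                           "ECTD": 1.0})
    age_mean: float = 74.0
    age_sd: float = 6.0
    age_min: float = 65.0
    weight_mean: float = 84.0
    weight_sd: float = 14.0
    height_mean: float = 174.0
    height_sd: float = 7.0
    n_sites: int = 6
    age_slope: float = -0.004   # relative field change per year of age
    weight_slope: float = 0.001  # per kg
    site_offset_sd: float = 0.01
    high_risk_fraction: float = 0.5
    risk_correlation: float = 0.3  # latent risks vs global bone-quality factor
    side_noise_sd: float = 0.05
    shape_score_sd: float = 1.0
    bmd_noise_sd: float = 0.04

    def validate(self) -> None:
        for v, f in self.effect_fraction.items():
            if not -1.0 < f < 1.0:
                raise InvalidArgumentError(f"effect_fraction[{v}]={f} outside (-1, 1)")
        for v, b in self.baseline.items():
            if b <= 0:
                raise InvalidArgumentError(f"baseline[{v}] must be > 0")


@dataclass
class HazardSpec:
    """Competing-risks proportional-hazards generator for fracture outcomes.

    Log-hazards are linear in the standardized own-patch CM and ECTD means
    and in age; negative bone coefficients mean lower bone -> higher hazard.
    ``beta_age`` is per 5 years.  Baseline rates are per year.
    """

    lambda_troch: float = 0.0015
    lambda_neck: float = 0.0019
    beta_cm: float = -0.55
    beta_ectd: float = -0.75
    beta_age: float = 0.59  # ~ log(1.8) per 5 years

    def validate(self) -> None:
        if self.lambda_troch < 0 or self.lambda_neck < 0:
            raise InvalidArgumentError("baseline hazard rates must be >= 0")


@dataclass
class CaseCohortSample:
    """Case flags, subcohort flags and Barlow weights for one draw."""

    table: pd.DataFrame  # columns: id, is_case, in_subcohort, weight
    alpha: float

    @property
    def n_cases(self) -> int:
        return int(self.table["is_case"].sum())

    @property
    def n_subcohort(self) -> int:
        return int(self.table["in_subcohort"].sum())

    def analysis_ids(self) -> np.ndarray:
        t = self.table
        return t.loc[t.is_case | t.in_subcohort, "id"].to_numpy()


@dataclass
class Population:
    """Synthetic cohort: subject table plus per-vertex field arrays.

    ``truth`` holds the noise-free per-subject fields; ``fields[side]`` the
    two correlated per-hip measurement realisations.  All field arrays are
    (n_subjects, n_vertices) in the variable's units.
    """

    mesh: SurfaceMesh
    subjects: pd.DataFrame
    truth: dict
    fields: dict
    baseline: dict
    spec: TrueEffectSpec

    @property
    def n(self) -> int:
        return len(self.subjects)

    def combined_fields(self, variable: str) -> np.ndarray:
        """Vertex-wise mean of left and right hip fields."""
        from .mapping import average_left_right

        return average_left_right(self.fields["left"][variable],
                                  self.fields["right"][variable])


def _smooth_noise(rng, n, mesh, sd, smoother):
    """White noise smoothed on the mesh, rescaled to per-vertex SD ``sd``."""
    white = rng.normal(0.0, 1.0, size=(n, mesh.n_vertices))
    smoothed = white @ smoother.T
    shrink = np.sqrt(np.asarray(smoother.multiply(smoother).sum(axis=1)).ravel())
    return sd * smoothed / shrink[None, :]


def simulate_population(
    mesh: SurfaceMesh, n: int, spec: TrueEffectSpec | None = None, seed: int = 0
) -> Population:
    """Draw a synthetic cohort with planted fracture-type effect geometry.

    Covariates follow truncated-normal/normal defaults (age >= 65); fields
    are baseline x (1 + covariate terms + subject factor + smooth spatial
    noise) with the type-specific deficit applied to latent high-risk
    subjects; CM = 0.1 x CTh x CBMD at every vertex of every hip; global BMD
    surrogates are noisy monotone functions of whole-surface means.
    """
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    spec = spec or TrueEffectSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    V = mesh.n_vertices

    # covariates
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    age = truncnorm.rvs(a, np.inf, loc=spec.age_mean, scale=spec.age_sd,
                        size=n, random_state=rng)
    weight = rng.normal(spec.weight_mean, spec.weight_sd, n)
    height = rng.normal(spec.height_mean, spec.height_sd, n)
    site = rng.integers(0, spec.n_sites, n)
    site_offsets = rng.normal(0.0, spec.site_offset_sd, spec.n_sites)

    # latent bone quality and type-specific risks
    u = rng.normal(0.0, 1.0, n)  # global bone-quality factor (standardized)
    c = spec.risk_correlation
    risk = {}
    high = {}
    for ft in FRACTURE_TYPES:
        eps = rng.normal(0.0, 1.0, n)
        rho = -c * u + np.sqrt(max(1.0 - c**2, 0.0)) * eps  # low bone -> high risk
        risk[ft] = rho
        if n:
            thr = np.quantile(rho, 1.0 - spec.high_risk_fraction)
            high[ft] = rho > thr
        else:
            high[ft] = np.zeros(0, dtype=bool)

    # smooth spatially varying baseline maps
    smoother = mesh.smoothing_operator(spec.smooth_k)
    baseline = {}
    region_mult = {}
    for var in PRIMARY_VARIABLES:
        mult = np.ones(V)
        for region, m in spec.region_profiles.get(var, {}).items():
            mult[mesh.region_mask(region)] = m
        mult = smoother @ (smoother @ mult)
        region_mult[var] = mult
        baseline[var] = spec.baseline[var] * mult
    baseline["CM"] = 0.1 * baseline["CTh"] * baseline["CBMD"]

    # shared covariate/subject relative modifier
    cov_term = (
        spec.age_slope * (age - spec.age_mean)
        + spec.weight_slope * (weight - spec.weight_mean)
        + site_offsets[site]
    )

    truth = {}
    for var in PRIMARY_VARIABLES:
        rel = (
            1.0
            + cov_term[:, None]
            + (spec.subject_sd * spec.subject_loading[var]) * u[:, None]
            + _smooth_noise(rng, n, mesh, spec.spatial_noise_sd[var], smoother)
        )
        vals = baseline[var][None, :] * rel
        for ft in FRACTURE_TYPES:
            frac = spec.effect_fraction.get(var, 0.0)
            if frac:
                mask = mesh.region_mask(spec.patch_region[ft])
                vals[np.ix_(high[ft], mask)] *= 1.0 + frac
        truth[var] = np.clip(vals, 0.01 * spec.baseline[var], None)
    truth["CM"] = 0.1 * truth["CTh"] * truth["CBMD"]

    fields = {}
    for side in ("left", "right"):
        side_fields = {}
        for var in PRIMARY_VARIABLES:
            noise = rng.normal(0.0, spec.side_noise_sd, size=(n, V))
            side_fields[var] = np.clip(truth[var] * (1.0 + noise),
                                       0.005 * spec.baseline[var], None)
        side_fields["CM"] = 0.1 * side_fields["CTh"] * side_fields["CBMD"]
        fields[side] = side_fields

    # global BMD surrogates: noisy monotone maps of whole-surface means
    if n:
        m_cm = truth["CM"].mean(axis=1) / baseline["CM"].mean()
        m_ectd = truth["ECTD"].mean(axis=1) / baseline["ECTD"].mean()
    else:
        m_cm = m_ectd = np.zeros(0)
    bmd_dxa = 0.956 * m_cm * (1.0 + rng.normal(0.0, spec.bmd_noise_sd, n))
    bmd_qct = 0.278 * (0.5 * m_cm + 0.5 * m_ectd) * (
        1.0 + rng.normal(0.0, spec.bmd_noise_sd, n))

    subjects = pd.DataFrame({
        "id": np.arange(n),
        "age": age,
        "weight": weight,
        "height": height,
        "site": site,
        "risk_troch": risk["trochanteric"],
        "risk_neck": risk["neck"],
        "high_risk_troch": high["trochanteric"],
        "high_risk_neck": high["neck"],
        "bmd_dxa_like": bmd_dxa,
        "bmd_qct_like": bmd_qct,
        "fracture_type": pd.Categorical(["none"] * n,
                                        categories=["none", *FRACTURE_TYPES]),
        "event_time": np.full(n, np.nan),
        "censored": np.ones(n, dtype=bool),
    })
    for k in range(1, 6):
        subjects[f"shape{k}"] = rng.normal(0.0, spec.shape_score_sd, n)

    return Population(mesh=mesh, subjects=subjects, truth=truth, fields=fields,
                      baseline=baseline, spec=spec)


def simulate_fracture_outcomes(
    pop: Population,
    hazard: HazardSpec | None = None,
    horizon: float = 10.0,
    seed: int = 0,
) -> Population:
    """Fill fracture type and event/censoring time from competing hazards.

    Each fracture type has an exponential event process with subject-specific
    rate lambda_type x exp(linear predictor on standardized own-patch CM and
    ECTD truth means and age); the first event inside the horizon wins,
    otherwise the subject is censored at the horizon.
    """
    hazard = hazard or HazardSpec()
    hazard.validate()
    rng = np.random.default_rng(seed)
    if pop.n == 0:
        return pop
    return _assign_outcomes(pop, hazard, horizon, rng)


def _assign_outcomes(pop, hazard, horizon, rng):
    spec = pop.spec
    age = pop.subjects["age"].to_numpy()
    n = pop.n

    def _z(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    times = {}
    for ft, lam0 in (("trochanteric", hazard.lambda_troch),
                     ("neck", hazard.lambda_neck)):
        mask = pop.mesh.region_mask(spec.patch_region[ft])
        z_cm = _z(pop.truth["CM"][:, mask].mean(axis=1))
        z_ectd = _z(pop.truth["ECTD"][:, mask].mean(axis=1))
        eta = (hazard.beta_cm * z_cm + hazard.beta_ectd * z_ectd
               + hazard.beta_age * (age - age.mean()) / 5.0)
        lam = lam0 * np.exp(eta)
        draws = rng.exponential(1.0, size=n)
        with np.errstate(divide="ignore"):
            times[ft] = np.where(lam > 0, draws / np.where(lam > 0, lam, 1.0), np.inf)

    t_troch, t_neck = times["trochanteric"], times["neck"]
    t_first = np.minimum(t_troch, t_neck)
    fractured = t_first < horizon
    ftype = np.where(t_troch <= t_neck, "trochanteric", "neck")

    subjects = pop.subjects
    subjects["fracture_type"] = pd.Categorical(
        np.where(fractured, ftype, "none"), categories=["none", *FRACTURE_TYPES])
    subjects["event_time"] = np.where(fractured, t_first, horizon)
    subjects["censored"] = ~fractured
    return pop


def draw_case_cohort(pop: Population, alpha: float, seed: int = 0) -> CaseCohortSample:
    """All fractured subjects as cases plus a simple random subcohort.

    The subcohort of size round(alpha x N) is drawn from the *whole*
    population, so cases may also be subcohort members (overlap permitted).
    """
    if not 0 < alpha <= 1:
        raise InvalidArgumentError("alpha must be in (0, 1]")
    rng = np.random.default_rng(seed)
    subjects = pop.subjects
    n = len(subjects)
    is_case = (subjects["fracture_type"] != "none").to_numpy()
    n_sub = int(round(alpha * n))
    sub_idx = rng.choice(n, size=n_sub, replace=False)
    in_sub = np.zeros(n, dtype=bool)
    in_sub[sub_idx] = True
    weight = np.where(is_case, 1.0, np.where(in_sub, 1.0 / alpha, 0.0))
    table = pd.DataFrame({
        "id": subjects["id"].to_numpy(),
        "is_case": is_case,
        "in_subcohort": in_sub,
        "weight": weight,
    })
    return CaseCohortSample(table=table, alpha=alpha)


def simulate_repeat_scans(
    pop: Population,
    error_sd: dict,
    n_pairs: int = 19,
    ids=None,
    seed: int = 0,
) -> dict:
    """Paired repeat scans: truth + two independent zero-mean noise draws.

    ``error_sd`` maps variable name to a scalar or per-vertex SD (variable
    units).  Returns {variable: (scan1, scan2)} arrays of shape
    (n_pairs, n_vertices) plus the subject ids under key ``"ids"``.
    """
    rng = np.random.default_rng(seed)
    if ids is None:
        if n_pairs > pop.n:
            raise InvalidArgumentError("n_pairs exceeds population size")
        ids = rng.choice(pop.n, size=n_pairs, replace=False)
    ids = np.asarray(ids)
    out = {"ids": ids}
    for var, sd in error_sd.items():
        sd_arr = np.broadcast_to(np.asarray(sd, dtype=float),
                                 (pop.mesh.n_vertices,))
        if np.any(sd_arr < 0):
            raise InvalidArgumentError(f"error_sd[{var}] must be non-negative")
        base = pop.truth[var][ids]
        scan1 = base + rng.normal(0.0, 1.0, base.shape) * sd_arr[None, :]
        scan2 = base + rng.normal(0.0, 1.0, base.shape) * sd_arr[None, :]
        out[var] = (scan1, scan2)
    return out


def plant_group_deficit(values: np.ndarray, subject_mask, vertex_mask,
                        fraction: float) -> np.ndarray:
    """Label-first planted deficit for calibration studies.

    Returns a copy of ``values`` with the given relative ``fraction`` applied
    to the (subject, vertex) block -- the direct two-group construction used
    to calibrate surface statistics with known ground truth.
    """
    out = np.array(values, copy=True)
    out[np.ix_(np.asarray(subject_mask, bool), np.asarray(vertex_mask, bool))] *= (
        1.0 + fraction)
    return out


@dataclass
class ProfileSet:
    """Rendered density profiles for every vertex of one subject/side."""

    positions: np.ndarray  # (G,) mm, shared grid
    intensities: np.ndarray  # (V, G) mg/cm^3
    sigma_blur: float

    def profile(self, vertex_id: int) -> CorticalProfile:
        return CorticalProfile(self.positions, self.intensities[vertex_id],
                               sigma_blur_true=self.sigma_blur,
                               vertex_id=vertex_id)

    def iter_profiles(self, vertex_ids=None):
        ids = range(len(self.intensities)) if vertex_ids is None else vertex_ids
        for v in ids:
            yield self.profile(v)


def render_profiles(
    cth: np.ndarray,
    cbmd: np.ndarray,
    ectd: np.ndarray,
    sigma_blur: float = 1.5,
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    y0: float = 30.0,
    quantization: float = 1.0,
    seed: int = 0,
) -> ProfileSet:
    """Render blurred density profiles from per-vertex (CTh, CBMD, ECTD).

    Each profile is the three-density step (soft tissue ``y0``, cortex CBMD
    over [0, CTh], trabecular ECTD inward) convolved with a Gaussian blur of
    SD ``sigma_blur``, plus i.i.d. noise, with intensities discretized to
    ``quantization`` mg/cm^3 (the reconstruction step; 0 disables).  The grid
    must span the blurred support [-3 sigma, max(CTh) + 3 sigma].
    """
    if sigma_blur <= 0:
        raise InvalidArgumentError("sigma_blur must be > 0")
    cth = np.atleast_1d(np.asarray(cth, dtype=float))
    cbmd = np.atleast_1d(np.asarray(cbmd, dtype=float))
    ectd = np.atleast_1d(np.asarray(ectd, dtype=float))
    if grid is None:
        hi = float(cth.max()) + 6 * sigma_blur if len(cth) else 6 * sigma_blur
        grid = np.arange(-6 * sigma_blur, hi + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise InvalidArgumentError("grid must be strictly increasing")
    if grid[0] > -3 * sigma_blur or grid[-1] < cth.max() + 3 * sigma_blur:
        raise InvalidArgumentError(
            "grid must cover [x0 - 3 sigma, x1 + 3 sigma] for every vertex")
    rng = np.random.default_rng(seed)
    x = grid[None, :]
    y = (y0
         + (cbmd[:, None] - y0) * ndtr(x / sigma_blur)
         + (ectd[:, None] - cbmd[:, None]) * ndtr((x - cth[:, None]) / sigma_blur))
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    if quantization:
        y = np.round(y / quantization) * quantization
    return ProfileSet(positions=grid, intensities=y, sigma_blur=sigma_blur)


def make_subject_shapes(
    mesh: SurfaceMesh,
    n: int,
    n_modes: int = 3,
    mode_sd: float = 1.5,
    size_sd: float = 0.05,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject surface coordinates: canonical + smooth planted modes.

    Each subject's mesh is the canonical surface displaced along ``n_modes``
    smooth random displacement fields (loading SD ``mode_sd`` mm), scaled by
    a lognormal-ish size factor (SD ``size_sd``), plus small vertex noise.
    Shares topology with the canonical mesh, as required by the
    correspondence-based mapping.
    """
    rng = np.random.default_rng(seed)
    V = mesh.n_vertices
    smoother = mesh.smoothing_operator(3)
    modes = smoother @ rng.normal(0.0, 1.0, size=(V, 3, n_modes)).reshape(V, -1)
    modes = modes.reshape(V, 3, n_modes)
    modes /= np.sqrt((modes**2).sum(axis=(0, 1)))[None, None, :]
    loadings = rng.normal(0.0, mode_sd * np.sqrt(V), size=(n, n_modes))
    sizes = np.exp(rng.normal(0.0, size_sd, n))
    coords = np.empty((n, V, 3))
    for i in range(n):
        disp = (modes * loadings[i][None, None, :]).sum(axis=2)
        coords[i] = sizes[i] * (mesh.vertices + disp
                                + rng.normal(0.0, noise_sd, size=(V, 3)))
    return coords
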