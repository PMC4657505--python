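"""End-to-end pipeline: generate -> measure -> map -> SPM -> models -> precision.

One YAML config drives a fully reproducible run: every stochastic stage has
an explicit seed, all tables are written as CSV in the layouts of the
standard reporting tables (hazard ratios, odds ratios, cross-validated AUCs,
precision), per-vertex maps go out as PLY scalar properties, and a manifest
records the config hash and a checksum for every output file.  Stages before
the surface statistics never read fracture labels: measurement and mapping
operate on fields and geometry only, and labels are joined at the SPM stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cox as cox_mod
from . import mapping, precision, predict, profiles, spm, synth
from .errors import ConfigError
from .mesh import make_canonical_mesh, save_ply, save_ply_with_scalars

REQUIRED_FIELDS = (
    "synth.n", "synth.alpha", "synth.seed_population", "synth.seed_outcomes",
    "synth.seed_casecohort", "spm.n_perm", "spm.seed", "models.seed",
    "measurement.seed", "output_dir",
)

DEFAULT_MODEL_SETS = {
    "m": (),
    "m+DXA": ("bmd_dxa_like",),
    "m+QCT": ("bmd_qct_like",),
    "m+CBM": ("cm_troch_patch", "cm_neck_patch",
              "ectd_troch_patch", "ectd_neck_patch"),
    "m+DXA+CBM": ("bmd_dxa_like", "cm_troch_patch", "cm_neck_patch",
                  "ectd_troch_patch", "ectd_neck_patch"),
    "m+QCT+CBM": ("bmd_qct_like", "cm_troch_patch", "cm_neck_patch",
                  "ectd_troch_patch", "ectd_neck_patch"),
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    raw: dict

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping", field="<root>")
        for dotted in REQUIRED_FIELDS:
            node = raw
            for part in dotted.split("."):
                if not isinstance(node, dict) or part not in node:
                    raise ConfigError(f"missing config field {dotted}",
                                      field=dotted)
                node = node[part]
        return cls(raw=raw)

    def get(self, dotted: str, default=None):
        node = self.raw
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                return default
            node = node[part]
        return node

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record: config hash plus per-file checksums."""

    config_hash: str
    version: str
    files: dict
    flags: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "version": self.version,
                       "files": self.files, "flags": self.flags}, fh, indent=2,
                      sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _effect_spec(cfg: RunConfig) -> synth.TrueEffectSpec:
    spec = synth.TrueEffectSpec()
    for key, val in (cfg.get("synth.effect") or {}).items():
        if not hasattr(spec, key):
            raise ConfigError(f"unknown synth.effect field {key}",
                              field=f"synth.effect.{key}")
        setattr(spec, key, val)
    return spec


def _hazard_spec(cfg: RunConfig) -> synth.HazardSpec:
    hz = synth.HazardSpec()
    for key, val in (cfg.get("synth.hazard") or {}).items():
        if not hasattr(hz, key):
            raise ConfigError(f"unknown synth.hazard field {key}",
                              field=f"synth.hazard.{key}")
        setattr(hz, key, val)
    return hz


def run_pipeline(cfg: RunConfig, out_dir=None) -> RunManifest:
    """Execute all stages and write tables, maps, manifest and a log."""
    out = Path(out_dir or cfg.get("output_dir"))
    out.mkdir(parents=True, exist_ok=True)
    flags: list = []
    files: dict = {}
    log: list = []

    def _emit(name, obj):
        path = out / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False, float_format="%.10g")
        files[name] = _sha256(path)
        return path

    # ---- stage 1: synthesize cohort --------------------------------------
    n_vertices = int(cfg.get("synth.n_vertices", 2000))
    mesh = make_canonical_mesh(n_vertices, seed=int(cfg.get("synth.seed_mesh", 0)))
    espec = _effect_spec(cfg)
    pop = synth.simulate_population(mesh, int(cfg.get("synth.n")), spec=espec,
                                    seed=int(cfg.get("synth.seed_population")))
    pop = synth.simulate_fracture_outcomes(
        pop, _hazard_spec(cfg), horizon=float(cfg.get("synth.horizon", 10.0)),
        seed=int(cfg.get("synth.seed_outcomes")))
    sample = synth.draw_case_cohort(pop, float(cfg.get("synth.alpha")),
                                    seed=int(cfg.get("synth.seed_casecohort")))
    save_ply(mesh, out / "canonical_mesh.ply")
    files["canonical_mesh.ply"] = _sha256(out / "canonical_mesh.ply")
    _emit("case_cohort.csv", sample.table)
    log.append({"stage": "synth", "n": pop.n, "n_vertices": mesh.n_vertices,
                "n_cases": sample.n_cases, "n_subcohort": sample.n_subcohort})

    # ---- stage 2: profile measurement fidelity (blind to labels) ---------
    meas_rows = []
    rng = np.random.default_rng(int(cfg.get("measurement.seed")))
    n_ms = int(cfg.get("measurement.n_profile_subjects", 2))
    n_mv = int(cfg.get("measurement.n_profile_vertices", 100))
    sigma = float(cfg.get("measurement.sigma_blur", 1.5))
    noise = float(cfg.get("measurement.noise_sd", 15.0))
    conv = cfg.get("measurement.ectd_convention", "point")
    for si in rng.choice(pop.n, size=min(n_ms, pop.n), replace=False):
        verts = rng.choice(mesh.n_vertices, size=min(n_mv, mesh.n_vertices),
                           replace=False)
        ps = synth.render_profiles(
            pop.truth["CTh"][si, verts], pop.truth["CBMD"][si, verts],
            pop.truth["ECTD"][si, verts], sigma_blur=sigma, noise_sd=noise,
            seed=int(rng.integers(2**31)))
        y1_global = float(np.median(pop.truth["CBMD"][si, verts]))
        fits = profiles.measure_profiles(list(ps.iter_profiles()),
                                         mode=cfg.get("measurement.mode",
                                                      "constrained_density"),
                                         y1_fixed=y1_global,
                                         ectd_convention=conv)
        for v, m in zip(verts, fits):
            meas_rows.append({
                "subject": int(si), "vertex": int(v),
                "cth_true": pop.truth["CTh"][si, v], "cth_est": m.cth,
                "cm_true": pop.truth["CM"][si, v], "cm_est": m.cm,
                "ectd_true": pop.truth["ECTD"][si, v], "ectd_est": m.ectd,
                "ectd_convention": conv, "converged": m.converged,
            })
    meas = pd.DataFrame(meas_rows)
    _emit("measurement_recovery.csv", meas)
    ok = meas["converged"].mean() if len(meas) else 1.0
    if ok < 0.9:
        flags.append(f"measurement: only {ok:.0%} of profile fits converged")
    log.append({"stage": "measure", "n_profiles": len(meas),
                "converged_fraction": float(ok)})

    # ---- stage 3: map to canonical, shape modes, left/right average ------
    coords = synth.make_subject_shapes(mesh, pop.n,
                                       seed=int(cfg.get("synth.seed_population")))
    shape_model = mapping.compute_shape_modes(coords, n_modes=5)
    for k in range(5):
        pop.subjects[f"shape{k + 1}"] = shape_model.scores[:, k]
    combined = {v: pop.combined_fields(v) for v in synth.VARIABLES}
    _emit("subjects.csv", pop.subjects)
    log.append({"stage": "map",
                "variance_explained": shape_model.variance_explained.tolist()})

    # ---- stage 4: SPM patch discovery on the analysis sample -------------
    ids = sample.analysis_ids()
    arows = pop.subjects["id"].isin(ids).to_numpy()
    analysis = pop.subjects.loc[arows].reset_index(drop=True)
    spm_seed = int(cfg.get("spm.seed"))
    n_perm = int(cfg.get("spm.n_perm"))
    spm_alpha = float(cfg.get("spm.alpha", 0.05))
    cluster_p = float(cfg.get("spm.cluster_p", 0.001))
    patches = {}
    patch_rows, map_frames = [], {}
    for var in synth.VARIABLES:
        Y = combined[var][arows]
        res = spm.fit_vertex_glm(Y, analysis, spm.SpmDesign(response=var))
        null = spm.build_cluster_mass_null(res, mesh, n_perm, seed=spm_seed,
                                           cluster_p=cluster_p)
        for contrast in spm.CONTRASTS:
            patch = spm.extract_significant_patches(
                res, mesh, contrast, alpha=spm_alpha, null_masses=null,
                cluster_p=cluster_p)
            patches[(var, contrast)] = patch
            for v in patch.vertices:
                patch_rows.append({"variable": var, "contrast": contrast,
                                   "vertex": int(v),
                                   "fallback": patch.fallback or ""})
            if patch.fallback:
                flags.append(f"spm: {var}/{contrast} patch via fallback "
                             f"{patch.fallback}")
        map_frames[var] = res
    _emit("patches.csv", pd.DataFrame(patch_rows))
    report_effect_maps(map_frames, patches, mesh, out, files)
    log.append({"stage": "spm", "n_analysis": len(analysis), "n_perm": n_perm,
                "patches": {f"{v}/{c}": len(p.vertices)
                            for (v, c), p in patches.items()}})

    # patch-mean columns for the analysis sample (CM/ECTD carried forward,
    # CTh/CBMD for reporting only)
    short = {"CM": "cm", "ECTD": "ectd", "CTh": "cth", "CBMD": "cbmd"}
    ctr_short = {"trochanteric_vs_cohort": "troch", "neck_vs_cohort": "neck"}
    for (var, contrast), patch in patches.items():
        col = f"{short[var]}_{ctr_short[contrast]}_patch"
        analysis[col] = spm.patch_average(combined[var][arows], patch)

    # ---- stage 5: case-cohort Cox hazard ratios --------------------------
    imaging = ["bmd_dxa_like", "bmd_qct_like", "cm_troch_patch",
               "cm_neck_patch", "ectd_troch_patch", "ectd_neck_patch"]
    sample_analysis = synth.CaseCohortSample(
        table=sample.table[sample.table["id"].isin(ids)].reset_index(drop=True),
        alpha=sample.alpha)
    try:
        tbl2 = cox_mod.hazard_ratio_table(analysis, sample_analysis, imaging)
    except Exception as exc:
        flags.append(f"cox: {exc}")
        tbl2 = pd.DataFrame()
    _emit("table2_hazard_ratios.csv", tbl2)
    log.append({"stage": "cox", "n_rows": len(tbl2)})

    # ---- stage 6: predictive models, LOO AUC, deviance comparison --------
    models_seed = int(cfg.get("models.seed"))
    n_boot = int(cfg.get("models.n_boot", 500))
    rederive = bool(cfg.get("models.rederive_patches", True))
    model_names = list(cfg.get("models.specs", list(DEFAULT_MODEL_SETS)))
    spm_settings = {"n_perm": n_perm, "seed": spm_seed, "alpha": spm_alpha,
                    "cluster_p": cluster_p}
    fields_analysis = {v: combined[v][arows] for v in ("CM", "ECTD")}
    tbl3_rows, tbl4_rows, roc_rows = [], [], []
    results = {}
    for outcome in ("binary_any", "trichotomous"):
        for name in model_names:
            ms = predict.ModelSpec(name, imaging=DEFAULT_MODEL_SETS[name],
                                   outcome=outcome)
            res = predict.loo_predict(
                analysis, ms, fields=fields_analysis, mesh=mesh,
                rederive_patches=rederive, spm_settings=spm_settings,
                seed=models_seed)
            results[(name, outcome)] = res
            if outcome == "binary_any":
                a, lo, hi = res.auc("fracture", n_boot=n_boot, seed=models_seed)
                tbl4_rows.append({"model": name, "outcome": "all",
                                  "auc": a, "ci_low": lo, "ci_high": hi,
                                  "dev": res.deviance})
                _, _, _, curve = predict.roc_auc(
                    res.probabilities[:, 1], res.outcomes, n_boot=0,
                    return_curve=True)
                for fpr, tpr in curve:
                    roc_rows.append({"model": name, "outcome": "all",
                                     "fpr": fpr, "tpr": tpr})
            else:
                for cls in ("trochanteric", "neck"):
                    a, lo, hi = res.auc(cls, n_boot=n_boot, seed=models_seed)
                    tbl4_rows.append({"model": name, "outcome": cls,
                                      "auc": a, "ci_low": lo, "ci_high": hi,
                                      "dev": res.deviance})
    # nested deviance tests vs the base model m
    for outcome in ("binary_any", "trichotomous"):
        base = results.get(("m", outcome))
        for name in model_names:
            if name == "m" or (name, outcome) not in results:
                continue
            stat, dfree, p = predict.compare_deviance(base, results[(name, outcome)])
            tbl4_rows.append({"model": f"{name} vs m", "outcome": outcome,
                              "auc": np.nan, "ci_low": np.nan,
                              "ci_high": np.nan, "dev": stat,
                              "p_vs_m": p, "significant_0.005": p < 0.005})
    # per-variable odds ratios (base model for age/height, m+var otherwise)
    for outcome in ("binary_any", "trichotomous"):
        base_fit = predict.fit_fracture_model(
            analysis, predict.ModelSpec("m", outcome=outcome))
        tbl3_rows.extend(base_fit.odds_ratios.assign(outcome=outcome)
                         .to_dict("records"))
        for var in imaging:
            f = predict.fit_fracture_model(
                analysis, predict.ModelSpec(f"m+{var}", imaging=(var,),
                                            outcome=outcome))
            if f.separation_flag:
                flags.append(f"predict: separation in m+{var}/{outcome}")
            tbl3_rows.extend(
                f.odds_ratios[f.odds_ratios["variable"] == var]
                .assign(outcome=outcome).to_dict("records"))
    _emit("table3_odds_ratios.csv", pd.DataFrame(tbl3_rows))
    _emit("table4_auc.csv", pd.DataFrame(tbl4_rows))
    _emit("roc_curves.csv", pd.DataFrame(roc_rows))
    log.append({"stage": "predict", "n_models": len(results)})

    # ---- stage 7: precision from paired repeat scans ---------------------
    err_cfg = cfg.get("synth.error_sd", {"CTh": 0.10, "CBMD": 35.0,
                                         "ECTD": 15.0})
    n_pairs = int(cfg.get("synth.n_repeat_pairs", 19))
    scans = synth.simulate_repeat_scans(pop, {k: float(v)
                                              for k, v in err_cfg.items()},
                                        n_pairs=n_pairs,
                                        seed=int(cfg.get("synth.seed_repeat", 11)))
    tbl5 = []
    sd_maps = {}
    for var in err_cfg:
        s1, s2 = scans[var]
        rep = precision.precision_report(
            var, s1, s2, combined[var],
            patches={f"{ctr_short[c]} patch": patches[(var, c)]
                     for c in spm.CONTRASTS if (var, c) in patches})
        tbl5.append(rep.table)
        sd_maps[f"sd_{var}"] = rep.vertex_sd
    _emit("table5_precision.csv", pd.concat(tbl5, ignore_index=True))
    save_ply_with_scalars(mesh, out / "precision_maps.ply", sd_maps)
    files["precision_maps.ply"] = _sha256(out / "precision_maps.ply")
    log.append({"stage": "precision", "n_pairs": n_pairs})

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    files["run_log.json"] = _sha256(out / "run_log.json")

    from . import __version__

    manifest = RunManifest(config_hash=cfg.config_hash(), version=__version__,
                           files=files, flags=flags)
    manifest.to_json(out / "manifest.json")
    return manifest


def report_effect_maps(results: dict, patches: dict, mesh, out_dir: Path,
                       files: dict) -> None:
    """Per-vertex percentage-difference maps, masked to patch significance.

    Vertices outside the patch are emitted as missing (empty CSV cell / NaN
    property), never 0.  ECTD percentages are additionally flagged unstable
    where the vertex mean approaches zero, since a small absolute change
    then produces an arbitrarily large percentage.
    """
    rows = []
    scalars = {}
    for var, res in results.items():
        vmean = res._Y.mean(axis=0)
        near_zero = np.abs(vmean) < 0.1 * np.abs(vmean).mean()
        for contrast, short in (("trochanteric_vs_cohort", "troch"),
                                ("neck_vs_cohort", "neck")):
            eff = res.effect_pct[contrast].copy()
            patch = patches.get((var, contrast))
            mask = np.zeros(len(eff), dtype=bool)
            if patch is not None and not patch.empty and patch.fallback is None:
                mask[patch.vertices] = True
            eff_masked = np.where(mask, eff, np.nan)
            scalars[f"pct_{var}_{short}"] = np.nan_to_num(eff_masked, nan=0.0)
            for v in range(len(eff)):
                rows.append({"variable": var, "contrast": contrast,
                             "vertex": v,
                             "effect_pct": eff_masked[v],
                             "pct_unstable": bool(near_zero[v]) and var == "ECTD"})
    df = pd.DataFrame(rows)
    path = Path(out_dir) / "effect_maps.csv"
    df.to_csv(path, index=False, float_format="%.6g")
    files["effect_maps.csv"] = _sha256(path)
    ply_path = Path(out_dir) / "effect_maps.ply"
    save_ply_with_scalars(mesh, ply_path, scalars)
    files["effect_maps.ply"] = _sha256(ply_path)
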