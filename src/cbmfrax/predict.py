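"""Fracture prediction models and cross-validated evaluation.

Ten-year fracture incidence is modelled by binomial (any fracture) or
trichotomous multinomial (none / trochanteric / neck) logistic regression on
a base model m = age + height + site plus optional imaging variables.
Because the cortical patches are themselves discovered from the data, the
surface statistics are re-run inside every leave-one-out fold when a model
contains patch variables, so each subject's predicted probability never sees
that subject -- neither in the regression nor in the patch discovery.
Model quality is summarised by ROC AUC (Mann-Whitney with ties counted 1/2,
percentile bootstrap CIs) and by the deviance of the cross-validated
probabilities, with nested models compared by a chi-squared test on the
deviance difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .errors import (
    InvalidArgumentError,
    InvalidDesignError,
    NotNestedError,
    UndefinedAUCError,
)
from .spm import (
    ANALYSIS_VARIABLES,
    SpmDesign,
    build_cluster_mass_null,
    extract_significant_patches,
    fit_vertex_glm,
    patch_average,
)

OUTCOMES = ("binary_any", "trichotomous")
CLASS_ORDER = ("none", "trochanteric", "neck")

#: patch-mean column name -> (response variable, contrast)
PATCH_COLUMNS = {
    "cm_troch_patch": ("CM", "trochanteric_vs_cohort"),
    "cm_neck_patch": ("CM", "neck_vs_cohort"),
    "ectd_troch_patch": ("ECTD", "trochanteric_vs_cohort"),
    "ectd_neck_patch": ("ECTD", "neck_vs_cohort"),
    "cth_troch_patch": ("CTh", "trochanteric_vs_cohort"),
    "cth_neck_patch": ("CTh", "neck_vs_cohort"),
    "cbmd_troch_patch": ("CBMD", "trochanteric_vs_cohort"),
    "cbmd_neck_patch": ("CBMD", "neck_vs_cohort"),
}


@dataclass
class ModelSpec:
    """A predictive model: base covariates plus imaging variables.

    The base model m (age + height + site) is always included.  Patch-mean
    columns named in :data:`PATCH_COLUMNS` are treated as CBM variables and
    trigger per-fold patch re-derivation under leave-one-out evaluation.
    CTh/CBMD patches are reporting-only upstream and are rejected here
    unless ``allow_reporting_variables`` is set.
    """

    name: str
    imaging: tuple = ()
    outcome: str = "binary_any"
    allow_reporting_variables: bool = False

    def __post_init__(self):
        self.imaging = tuple(self.imaging)
        if self.outcome not in OUTCOMES:
            raise InvalidArgumentError(f"outcome must be one of {OUTCOMES}")
        for col in self.imaging:
            info = PATCH_COLUMNS.get(col)
            if info and info[0] not in ANALYSIS_VARIABLES \
                    and not self.allow_reporting_variables:
                raise InvalidArgumentError(
                    f"{col} is a reporting-only patch variable ({info[0]}); "
                    "only CM and ECTD patches enter predictive models unless "
                    "allow_reporting_variables=True")

    @property
    def cbm_columns(self) -> tuple:
        return tuple(c for c in self.imaging if c in PATCH_COLUMNS)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return (self.outcome == other.outcome
                and set(self.imaging) <= set(other.imaging))


@dataclass
class FractureModelFit:
    """Maximum-likelihood logistic/multinomial fit with per-SD odds ratios."""

    spec: ModelSpec
    params: np.ndarray
    column_names: list
    llf: float
    deviance: float
    n_params: int
    n_obs: int
    separation_flag: bool
    odds_ratios: pd.DataFrame  # per-variable OR with Wald 95% CI
    _model: object = field(repr=False, default=None)
    _result: object = field(repr=False, default=None)
    _meta: dict = field(repr=False, default=None)

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        """Class probabilities, columns ordered none/trochanteric/neck
        (binary: none/fracture)."""
        X = _design(data, self.spec, self._meta)[0]
        if self.spec.outcome == "binary_any":
            p = self._result.predict(X)
            return np.column_stack([1.0 - p, p])
        return np.asarray(self._result.predict(X))


@dataclass
class PredictionResult:
    """Leave-one-out predicted probabilities and derived summaries."""

    spec: ModelSpec
    probabilities: np.ndarray  # (n, K) LOO class probabilities
    outcomes: np.ndarray  # class codes into CLASS_ORDER (binary: 0/1)
    classes: tuple
    deviance: float  # -2 sum log p(observed class), from LOO probabilities
    n_params: int
    fold_provenance: list
    n_spm_runs: int = 0

    def auc(self, positive_class: str, n_boot: int = 0, seed: int = 0):
        """One-vs-rest AUC for the given class from the LOO probabilities."""
        k = self.classes.index(positive_class)
        y = (self.outcomes == k).astype(int)
        return roc_auc(self.probabilities[:, k], y, n_boot=n_boot, seed=seed)


def _outcome_codes(data: pd.DataFrame, outcome: str) -> np.ndarray:
    ftype = np.asarray(data["fracture_type"].astype(str))
    if outcome == "binary_any":
        return (ftype != "none").astype(int)
    codes = np.zeros(len(ftype), dtype=int)
    codes[ftype == "trochanteric"] = 1
    codes[ftype == "neck"] = 2
    return codes


def _design(data: pd.DataFrame, spec: ModelSpec, meta: dict | None = None):
    """Design matrix (intercept + base m + standardized imaging), names, meta.

    ``meta`` carries the training-sample site levels and imaging
    standardization (column -> (mean, sd)); it is computed from ``data``
    when not supplied and returned so train-fold coding can be applied
    unchanged to held-out rows.
    """
    fitting = meta is None
    if fitting:
        meta = {"site_levels": np.unique(np.asarray(data["site"]))}
        scale = {}
        for c in spec.imaging:
            x = np.asarray(data[c], dtype=float)
            sd = x.std(ddof=1)
            scale[c] = (x.mean(), sd if sd > 0 else 1.0)
        meta["scale"] = scale
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for c in ("age", "height"):
        cols.append(np.asarray(data[c], dtype=float)); names.append(c)
    site = np.asarray(data["site"])
    for lev in meta["site_levels"][1:]:
        cols.append((site == lev).astype(float)); names.append(f"site[{lev}]")
    for c in spec.imaging:
        m, sd = meta["scale"][c]
        cols.append((np.asarray(data[c], dtype=float) - m) / sd)
        names.append(c)
    X = np.column_stack(cols)
    if fitting and np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidDesignError("prediction design matrix is rank deficient",
                                 columns=names)
    return X, names, meta


def fit_fracture_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    meta: dict | None = None,
    start_params: np.ndarray | None = None,
) -> FractureModelFit:
    """Maximum-likelihood logistic (binary) or multinomial (trichotomous) fit.

    Odds ratios for imaging variables are reported per 1 SD *decrease*
    (exp(-beta) for the standardized coefficient) with Wald 95% CIs; age per
    5-year increase; deviance is -2 log-likelihood.  Perfect separation is
    flagged, not raised.
    """
    X, names, meta = _design(data, spec, meta)
    y = _outcome_codes(data, spec.outcome)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.outcome == "binary_any":
            model = sm.Logit(y, X)
        else:
            model = sm.MNLogit(y, X)
        # near-separation can derail Newton; fall back through cold starts
        res = None
        for method, sp, it in (("newton", start_params, 100),
                               ("newton", None, 100), ("bfgs", None, 1000)):
            try:
                cand = model.fit(disp=0, method=method, maxiter=it,
                                 start_params=sp)
            except Exception:
                continue
            if res is None:
                res = cand
            if np.all(np.isfinite(np.asarray(cand.params))) and \
                    np.isfinite(cand.llf):
                res = cand
                break
        if res is None:
            raise InvalidDesignError("logistic fit failed on all optimizers",
                                     columns=names)
    params = np.asarray(res.params)
    # perfect separation: divergent coefficients or an essentially perfect
    # fit (log-likelihood at the 0 boundary)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 30 \
            or not np.isfinite(res.llf) or res.llf > -1e-4 * len(y):
        separation = True
    n_params = params.size
    llf = float(res.llf)

    rows = []
    z975 = 1.959963984540054
    cov = np.asarray(res.cov_params())
    flat = params.ravel(order="F")
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    p_names = []
    if spec.outcome == "binary_any":
        p_names = [(nm, "fracture") for nm in names]
    else:
        for kclass in CLASS_ORDER[1:]:
            p_names += [(nm, kclass) for nm in names]
    for (nm, cls), b, s in zip(p_names, flat, se):
        if nm in spec.imaging:
            # per 1 SD decrease
            rows.append({"variable": nm, "class": cls,
                         "odds_ratio": float(np.exp(-b)),
                         "ci_low": float(np.exp(-b - z975 * s)),
                         "ci_high": float(np.exp(-b + z975 * s))})
        elif nm == "age":
            rows.append({"variable": "age(per5yr)", "class": cls,
                         "odds_ratio": float(np.exp(5 * b)),
                         "ci_low": float(np.exp(5 * (b - z975 * s))),
                         "ci_high": float(np.exp(5 * (b + z975 * s)))})
    or_table = pd.DataFrame(rows)
    # normalize CI orientation (sign flip for per-SD-decrease reverses order)
    if len(or_table):
        lo = or_table[["ci_low", "ci_high"]].min(axis=1)
        hi = or_table[["ci_low", "ci_high"]].max(axis=1)
        or_table["ci_low"], or_table["ci_high"] = lo, hi

    return FractureModelFit(
        spec=spec, params=params, column_names=names, llf=llf,
        deviance=-2.0 * llf, n_params=n_params, n_obs=len(y),
        separation_flag=separation, odds_ratios=or_table,
        _model=model, _result=res, _meta=meta)


def _rederive_patch_columns(data, fold_mask, fields, mesh, spm_design_covariates,
                            spm_settings, needed, nulls):
    """Patch means for every subject from patches discovered on fold_mask rows."""
    out = {}
    prov = {}
    train = data.loc[fold_mask]
    by_var = {}
    for col in needed:
        var, contrast = PATCH_COLUMNS[col]
        by_var.setdefault(var, []).append((col, contrast))
    for var, wanted in by_var.items():
        res = fit_vertex_glm(fields[var][fold_mask.to_numpy()], train,
                             SpmDesign(response=var,
                                       covariates=spm_design_covariates))
        for col, contrast in wanted:
            patch = extract_significant_patches(
                res, mesh, contrast,
                method=spm_settings.get("method", "permutation_fwer"),
                alpha=spm_settings.get("alpha", 0.05),
                cluster_p=spm_settings.get("cluster_p", 0.001),
                null_masses=nulls[var],
                provenance=spm_settings.get("provenance", "fold"))
            out[col] = patch_average(fields[var], patch)
            prov[col] = patch.fallback
    return out, prov


def loo_predict(
    data: pd.DataFrame,
    spec: ModelSpec,
    fields: dict | None = None,
    mesh=None,
    rederive_patches: bool = False,
    spm_design_covariates: tuple = ("age", "weight", "site", "shape"),
    spm_settings: dict | None = None,
    seed: int = 0,
) -> PredictionResult:
    """Leave-one-out predicted probabilities with in-loop patch discovery.

    For every subject i the model -- and, when ``rederive_patches`` is set
    and the model contains patch variables, the surface SPM defining those
    patches -- is fitted on all subjects except i, and i's class
    probabilities are predicted from that fold.  The permutation null for
    cluster significance is computed once per response variable on the full
    sample and shared across folds (fixed seed), keeping n x SPM tractable.
    """
    n = len(data)
    if n < 30:
        raise InvalidArgumentError("leave-one-out evaluation needs n >= 30")
    data = data.reset_index(drop=True)
    spm_settings = dict(spm_settings or {})
    needed = spec.cbm_columns
    do_spm = rederive_patches and len(needed) > 0
    nulls = {}
    if do_spm:
        if fields is None or mesh is None:
            raise InvalidArgumentError(
                "patch re-derivation requires fields and mesh")
        n_perm = spm_settings.get("n_perm", 1000)
        null_seed = spm_settings.get("seed", seed)
        for var in {PATCH_COLUMNS[c][0] for c in needed}:
            res_full = fit_vertex_glm(fields[var], data,
                                      SpmDesign(response=var,
                                                covariates=spm_design_covariates))
            nulls[var] = build_cluster_mass_null(
                res_full, mesh, n_perm, seed=null_seed,
                cluster_p=spm_settings.get("cluster_p", 0.001))

    # warm start from a full-sample fit (patch columns from full sample too)
    warm_data = data
    if do_spm:
        full_mask = pd.Series(True, index=data.index)
        cols, _ = _rederive_patch_columns(
            data, full_mask, fields, mesh, spm_design_covariates,
            spm_settings | {"provenance": "full_sample"}, needed, nulls)
        warm_data = data.assign(**cols)
    full_fit = fit_fracture_model(warm_data, spec)
    warm = full_fit.params.ravel(order="F")

    K = 2 if spec.outcome == "binary_any" else 3
    probs = np.zeros((n, K))
    y = _outcome_codes(data, spec.outcome)
    provenance = []
    n_spm = 0
    for i in range(n):
        fold_mask = pd.Series(True, index=data.index)
        fold_mask.iloc[i] = False
        if do_spm:
            cols, prov = _rederive_patch_columns(
                data, fold_mask, fields, mesh, spm_design_covariates,
                spm_settings | {"provenance": f"loo_fold_{i}"}, needed, nulls)
            fold_data = data.assign(**cols)
            n_spm += 1
            provenance.append(prov)
        else:
            fold_data = warm_data
            provenance.append(None)
        train = fold_data.loc[fold_mask]
        fit = fit_fracture_model(train, spec, start_params=warm)
        p_i = fit.predict_proba(fold_data.iloc[[i]])[0]
        if not np.all(np.isfinite(p_i)):
            fit = fit_fracture_model(train, spec)  # cold restart
            p_i = fit.predict_proba(fold_data.iloc[[i]])[0]
        if not np.all(np.isfinite(p_i)):
            # degenerate fold (separation): fall back to the training class
            # frequencies so the evaluation stays defined, and record it
            y_train = np.delete(y, i)
            p_i = np.bincount(y_train, minlength=K) / len(y_train)
            provenance[-1] = {**(provenance[-1] or {}), "degenerate_fold": True}
        probs[i] = p_i
    eps = 1e-12
    dev = -2.0 * float(np.sum(np.log(np.clip(probs[np.arange(n), y], eps, None))))
    classes = ("none", "fracture") if K == 2 else CLASS_ORDER
    return PredictionResult(spec=spec, probabilities=probs, outcomes=y,
                            classes=classes, deviance=dev,
                            n_params=full_fit.n_params,
                            fold_provenance=provenance, n_spm_runs=n_spm)


def roc_auc(scores, y, n_boot: int = 2000, seed: int = 0,
            return_curve: bool = False):
    """AUC = P(random positive outranks random negative), ties count 1/2.

    Equals the trapezoidal area under the empirical ROC.  Percentile
    bootstrap over subjects, stratified by outcome so every resample keeps
    both classes, gives the 95% CI.  Returns (auc, ci_low, ci_high) or, with
    ``return_curve``, additionally the ROC points (fpr, tpr).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAUCError("both outcome classes must be present")

    def _auc(p, q):
        from scipy.stats import rankdata

        r = rankdata(np.concatenate([p, q]))
        return (r[: len(p)].sum() - len(p) * (len(p) + 1) / 2) / (len(p) * len(q))

    a = float(_auc(pos, neg))
    lo = hi = np.nan
    if n_boot:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, len(pos), len(pos))]
            bn = neg[rng.integers(0, len(neg), len(neg))]
            boots[b] = _auc(bp, bn)
        lo, hi = np.percentile(boots, [2.5, 97.5])
    if return_curve:
        thr = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
        tpr = [(pos >= t).mean() for t in thr]
        fpr = [(neg >= t).mean() for t in thr]
        return a, float(lo), float(hi), np.column_stack([fpr, tpr])
    return a, float(lo), float(hi)


def compare_deviance(fit_small, fit_large):
    """Chi-squared test on the deviance difference of nested models.

    Accepts :class:`FractureModelFit` or :class:`PredictionResult` pairs;
    the small model's variables must be a subset of the large model's.
    Returns (statistic, df, p); significance is conventionally read at
    p < 0.005.
    """
    spec_s, spec_l = fit_small.spec, fit_large.spec
    if not spec_s.is_nested_in(spec_l):
        raise NotNestedError(
            f"model {spec_s.name!r} is not nested in {spec_l.name!r}")
    stat = float(fit_small.deviance - fit_large.deviance)
    df = int(fit_large.n_params - fit_small.n_params)
    if df == 0:
        return 0.0, 0, 1.0
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p
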