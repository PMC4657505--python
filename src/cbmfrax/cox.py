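"""Case-cohort Cox proportional hazards with Barlow weighting.

Under the case-cohort design only the random subcohort plus all incident
cases are analysed.  Barlow's pseudo-likelihood weights reconstruct the
full-cohort risk sets: non-case subcohort members carry weight 1/alpha over
their whole follow-up; cases carry weight 1 at their event, contribute
nothing beforehand if outside the subcohort, and count as ordinary weighted
controls (1/alpha) before their event if inside it.  This is implemented by
constructing a split-record (entry, exit] dataset and fitting a weighted
Cox model with robust (sandwich) variance clustered on subject, using
Breslow tie handling.  Hazard ratios are reported per 1 SD decrease for
imaging variables (SD taken over the subcohort, the population-representative
sample), per 5-year increase for age, and per 1 SD increase for height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .errors import InsufficientEventsError, InvalidArgumentError
from .synth import CaseCohortSample

_EPS = 1e-6  # event-record half-open interval width, years

EXPOSURE_DIRECTIONS = ("per_sd_decrease", "per_sd_increase", "per_5yr")


@dataclass
class SurvivalFit:
    """Per-SD (or per-5-year) hazard ratio for one exposure and outcome."""

    variable: str
    outcome: str  # any | trochanteric | neck
    coef: float  # log-hazard per reported unit
    robust_se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    converged: bool
    direction: str

    @property
    def significant(self) -> bool:
        """Significance at the conservative p < 0.005 reporting convention."""
        return self.p_value < 0.005


def barlow_weights(sample: CaseCohortSample) -> np.ndarray:
    """Per-subject Barlow weights: cases 1, subcohort controls 1/alpha.

    Subjects outside both groups get weight 0 (they do not enter the
    pseudo-likelihood).  The time-varying role of cases inside the subcohort
    (weighted control before the event) is handled by the split-record
    construction in :func:`build_barlow_dataset`.
    """
    if not 0 < sample.alpha <= 1:
        raise InvalidArgumentError("alpha must be in (0, 1]")
    t = sample.table
    return np.where(t["is_case"], 1.0,
                    np.where(t["in_subcohort"], 1.0 / sample.alpha, 0.0))


def build_barlow_dataset(
    subjects: pd.DataFrame,
    sample: CaseCohortSample,
    covariate_cols,
    outcome: str = "any",
) -> pd.DataFrame:
    """Split-record (entry, exit] dataset implementing Barlow weighting.

    ``outcome`` selects which fracture type counts as the event; competing
    types are censored at their event time.  Rows carry columns
    ``entry``/``time``/``event``/``weight``/``id`` plus the covariates.
    """
    if not 0 < sample.alpha <= 1:
        raise InvalidArgumentError("alpha must be in (0, 1]")
    tab = sample.table.set_index("id")
    sub = subjects.set_index("id", drop=False)
    rows = []
    inv_alpha = 1.0 / sample.alpha
    for sid in tab.index:
        is_case = bool(tab.at[sid, "is_case"])
        in_sub = bool(tab.at[sid, "in_subcohort"])
        if not (is_case or in_sub):
            continue
        s = sub.loc[sid]
        t_end = float(s["event_time"])
        ftype = str(s["fracture_type"])
        is_event = is_case and (outcome == "any" or ftype == outcome)
        cov = tuple(s[c] for c in covariate_cols)
        if is_event:
            if in_sub and t_end > _EPS:
                rows.append((sid, 0.0, t_end - _EPS, 0, inv_alpha) + cov)
            rows.append((sid, max(t_end - _EPS, 0.0), t_end, 1, 1.0) + cov)
        else:
            # censored for this outcome; cases with the competing type count
            # as at-risk controls up to their (competing) event time
            if in_sub:
                rows.append((sid, 0.0, t_end, 0, inv_alpha) + cov)
            elif is_case:
                rows.append((sid, max(t_end - _EPS, 0.0), t_end, 0, 1.0) + cov)
    return pd.DataFrame(rows, columns=["id", "entry", "time", "event",
                                       "weight", *covariate_cols])


def fit_weighted_cox(
    subjects: pd.DataFrame,
    sample: CaseCohortSample,
    exposure: str,
    outcome: str = "any",
    adjust: tuple = ("age", "height", "site"),
    exposure_direction: str = "per_sd_decrease",
    min_events: int = 10,
) -> SurvivalFit:
    """Barlow-weighted Cox fit; hazard ratio in the reporting convention.

    Imaging exposures are standardized by the subcohort SD and sign-flipped
    for ``per_sd_decrease``; ``per_5yr`` divides by 5 (for age).  Age and
    height are conventionally reported from unadjusted (marginal) models, so
    pass ``adjust=()`` for those.  Robust sandwich variance clustered on
    subject; Breslow ties.
    """
    if exposure_direction not in EXPOSURE_DIRECTIONS:
        raise InvalidArgumentError(
            f"exposure_direction must be one of {EXPOSURE_DIRECTIONS}")
    subjects = subjects.copy()
    tab = sample.table
    sub_ids = tab.loc[tab["in_subcohort"], "id"]
    subj_idx = subjects.set_index("id")
    x = subjects[exposure].to_numpy(dtype=float)
    if exposure_direction == "per_5yr":
        xt = x / 5.0
    else:
        sd = subj_idx.loc[sub_ids, exposure].std()
        if not np.isfinite(sd) or sd <= 0:
            raise InvalidArgumentError(
                f"subcohort SD of {exposure} is not positive")
        xt = x / sd
        if exposure_direction == "per_sd_decrease":
            xt = -xt
    subjects["_exposure"] = xt

    covs = ["_exposure"]
    site_cols = []
    for c in adjust:
        if c == "site":
            site = subjects["site"].astype("category")
            dummies = pd.get_dummies(site, prefix="site", drop_first=True)
            site_cols = list(dummies.columns)
            subjects[site_cols] = dummies.astype(float)
            covs.extend(site_cols)
        else:
            covs.append(c)

    data = build_barlow_dataset(subjects, sample, covs, outcome=outcome)
    n_events = int(data["event"].sum())
    if n_events < min_events:
        raise InsufficientEventsError(
            f"{n_events} events of outcome {outcome!r}; need >= {min_events}")

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data.drop(columns=["id"]).assign(id=data["id"]),
                    duration_col="time", event_col="event", entry_col="entry",
                    weights_col="weight", cluster_col="id",
                    formula=" + ".join(f"Q('{c}')" for c in covs))
        except Exception as exc:  # non-convergence is flagged, not raised
            raise InsufficientEventsError(f"Cox fit failed: {exc}") from exc
    name = f"Q('_exposure')"
    coef = float(cph.params_[name])
    se = float(cph.standard_errors_[name])
    z = coef / se if se > 0 else np.nan
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return SurvivalFit(
        variable=exposure, outcome=outcome, coef=coef, robust_se=se,
        hazard_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p_value=float(p), n_events=n_events, converged=converged,
        direction=exposure_direction)


def hazard_ratio_table(
    subjects: pd.DataFrame,
    sample: CaseCohortSample,
    imaging_variables,
    outcomes=("any", "trochanteric", "neck"),
) -> pd.DataFrame:
    """Hazard-ratio table: age and height marginal, imaging adjusted.

    Age is reported per 5-year increase from an unadjusted model; height per
    1 SD increase, unadjusted; each imaging variable per 1 SD decrease from
    a model adjusted for age, height and clinical site.
    """
    rows = []
    plan = [("age", "per_5yr", ()), ("height", "per_sd_increase", ())]
    plan += [(v, "per_sd_decrease", ("age", "height", "site"))
             for v in imaging_variables]
    for outcome in outcomes:
        for var, direction, adjust in plan:
            fit = fit_weighted_cox(subjects, sample, var, outcome=outcome,
                                   adjust=adjust, exposure_direction=direction)
            rows.append({
                "variable": var, "outcome": outcome,
                "hazard_ratio": fit.hazard_ratio,
                "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                "p": fit.p_value, "significant_0.005": fit.significant,
                "n_events": fit.n_events, "direction": direction,
            })
    return pd.DataFrame(rows)
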