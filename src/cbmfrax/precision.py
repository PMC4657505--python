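"""Measurement precision from paired repeat scans.

If measurement error is zero-mean with SD s, the difference between two
independent scans of the same subject has variance 2 s^2, so the error
variance is estimated as one-half the variance of the paired differences.
The estimator is applied per vertex (precision varies with anatomical
location) and, after averaging each scan over a patch, per patch --
aggregation before differencing, so spatially independent error shrinks by
roughly sqrt(patch size).  Precision is reported three ways: absolute SD,
SD as % of the cohort mean (coefficient of variation), and SD as % of the
cohort SD, the latter being ~ half the minimum detectable difference for a
single subject at 95% confidence (1.96 * sqrt(2) * SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .spm import PatchDefinition, patch_average


@dataclass
class PrecisionReport:
    """Per-vertex and patch-aggregated precision for one variable."""

    variable: str
    vertex_sd: np.ndarray  # (V,) error SD, variable units
    table: pd.DataFrame  # rows: point + one per patch; Table-style columns


def paired_error_sd(scan1: np.ndarray, scan2: np.ndarray) -> np.ndarray:
    """Per-vertex error SD: sqrt(Var_subjects(scan1 - scan2) / 2).

    ``scan1``/``scan2`` are (n_pairs, V); the variance uses the n-1
    denominator.  A fixed between-scan offset contributes nothing (the
    estimator sees only the variance of the differences).
    """
    scan1 = np.asarray(scan1, dtype=float)
    scan2 = np.asarray(scan2, dtype=float)
    if scan1.shape != scan2.shape:
        raise InsufficientDataError("paired scans must have matching shapes")
    if scan1.ndim == 1:
        scan1, scan2 = scan1[None, :], scan2[None, :]
    if len(scan1) < 2:
        raise InsufficientDataError("need >= 2 scan pairs")
    diff = scan1 - scan2
    return np.sqrt(diff.var(axis=0, ddof=1) / 2.0)


def precision_report(
    variable: str,
    scan1: np.ndarray,
    scan2: np.ndarray,
    cohort_fields: np.ndarray,
    patches: dict | None = None,
) -> PrecisionReport:
    """Precision in the three reporting normalizations.

    ``cohort_fields`` is the (n_subjects, V) cohort field supplying the mean
    and between-subject SD references.  ``patches`` maps a display name to a
    :class:`PatchDefinition`; patch-level SD averages each scan over the
    patch first, then applies the half-variance estimator to the patch
    means.  Zero cohort SD marks the %-of-cohort-SD column undefined (NaN).
    """
    sd_map = paired_error_sd(scan1, scan2)
    cohort_fields = np.asarray(cohort_fields, dtype=float)

    rows = []

    def _row(label, err_sd, cohort_vals):
        mean = float(np.mean(cohort_vals))
        csd = float(np.std(cohort_vals, ddof=1))
        rows.append({
            "quantity": label,
            "sd": float(err_sd),
            "cv_pct": 100.0 * err_sd / mean if mean != 0 else np.nan,
            "pct_of_cohort_sd": 100.0 * err_sd / csd if csd > 0 else np.nan,
            "min_detectable_diff": 1.959963984540054 * np.sqrt(2.0) * float(err_sd),
        })

    # point-wise row: vertex-averaged error SD against vertex-pooled cohort stats
    _row(variable, float(sd_map.mean()), cohort_fields.ravel())
    for label, patch in (patches or {}).items():
        if not isinstance(patch, PatchDefinition) or patch.empty:
            continue
        p1 = patch_average(scan1, patch)
        p2 = patch_average(scan2, patch)
        patch_sd = float(paired_error_sd(p1[:, None], p2[:, None])[0])
        _row(f"{variable} {label}", patch_sd, patch_average(cohort_fields, patch))
    return PrecisionReport(variable=variable, vertex_sd=sd_map,
                           table=pd.DataFrame(rows))
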