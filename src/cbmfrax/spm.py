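"""Surface statistical parametric mapping (SPM).

A general linear model is fitted independently at every vertex of the
canonical surface, with the trimodal fracture factor (none / trochanteric /
neck) coded as two indicator columns against none, plus confounders (age,
weight, clinical site, shape-mode scores).  The per-vertex t-statistics for
a fracture indicator form a statistical map; multiplicity over the surface
is controlled by permutation-based cluster-mass family-wise error
correction: suprathreshold clusters (cluster-forming p < 0.001, connected on
the mesh edge graph, positive and negative tails kept separate) survive if
their |t| mass exceeds the permutation null of the maximum cluster mass
obtained by permuting fracture labels.  Surviving clusters for a contrast
are united into the fracture-type patch; per-subject patch means then feed
the hazard and prediction models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

from .errors import EmptyPatchError, InvalidArgumentError, InvalidDesignError
from .mesh import SurfaceMesh

CONTRASTS = ("trochanteric_vs_cohort", "neck_vs_cohort")
_CONTRAST_TYPE = {"trochanteric_vs_cohort": "trochanteric",
                  "neck_vs_cohort": "neck"}
#: Variables whose patches are carried into hazard/odds models; CTh and CBMD
#: patches are produced for reporting only.
ANALYSIS_VARIABLES = ("CM", "ECTD")


@dataclass
class SpmDesign:
    """Design specification for the vertex-wise GLM.

    ``covariates`` may include "age", "weight", "height", "site" (dummy
    coded) and "shape" (the five shape-mode scores).  The fracture factor is
    always included as two indicator columns against none.
    """

    response: str = "CM"
    covariates: tuple = ("age", "weight", "site", "shape")


@dataclass
class SpmResult:
    """Vertex-wise GLM output for both fracture contrasts."""

    response: str
    tstat: dict          # contrast -> (V,) t-statistics
    raw_p: dict          # contrast -> (V,) two-sided p-values
    effect_pct: dict     # contrast -> (V,) coefficient as % of vertex mean
    df: int
    n: int
    columns: list
    # internal state reused by the permutation machinery
    _X: np.ndarray = field(repr=False, default=None)
    _Y: np.ndarray = field(repr=False, default=None)
    _frac_cols: dict = field(repr=False, default=None)


@dataclass
class PatchDefinition:
    """Vertex set defining one fracture-type patch for one variable."""

    variable: str
    contrast: str
    vertices: np.ndarray
    provenance: str = "full_sample"
    fallback: str | None = None  # None | "uncorrected" | "top_fraction"
    n_clusters: int = 0

    @property
    def empty(self) -> bool:
        return len(self.vertices) == 0


def build_design_matrix(subjects: pd.DataFrame, design: SpmDesign):
    """Assemble the GLM design matrix; raises naming collinear columns.

    Returns (X, column_names, fracture_column_index_by_contrast).
    """
    cols, names = [], []
    n = len(subjects)
    cols.append(np.ones(n)); names.append("intercept")
    ftype = np.asarray(subjects["fracture_type"].astype(str))
    frac_cols = {}
    for contrast in CONTRASTS:
        ft = _CONTRAST_TYPE[contrast]
        frac_cols[contrast] = len(cols)
        cols.append((ftype == ft).astype(float)); names.append(f"fracture[{ft}]")
    for cov in design.covariates:
        if cov == "site":
            site = np.asarray(subjects["site"])
            for lev in np.unique(site)[1:]:
                cols.append((site == lev).astype(float)); names.append(f"site[{lev}]")
        elif cov == "shape":
            for k in range(1, 6):
                cols.append(np.asarray(subjects[f"shape{k}"], dtype=float))
                names.append(f"shape{k}")
        else:
            cols.append(np.asarray(subjects[cov], dtype=float)); names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise InvalidDesignError(
            f"design matrix rank deficient; collinear columns: {bad}", columns=bad)
    return X, names, frac_cols


def _glm_tstats(X, Y, col_indices, yss=None):
    """Vectorized per-vertex OLS t-statistics for the given columns.

    Returns (tstats dict col->(V,), betas dict, df).  ``Y`` is (n, V).
    """
    n, p = X.shape
    G = X.T @ X
    Gi = np.linalg.inv(G)
    XtY = X.T @ Y
    B = Gi @ XtY
    if yss is None:
        yss = np.einsum("ij,ij->j", Y, Y)
    rss = yss - np.einsum("ij,ij->j", B, XtY)
    df = n - p
    sigma2 = np.maximum(rss, 0.0) / df
    # relative floor: a residual at rounding level means the response is in
    # the design span, where the contrast is exactly zero, not 0/0 noise
    floor = 1e-12 * (yss / max(df, 1))
    t_out, b_out = {}, {}
    for key, j in col_indices.items():
        se = np.sqrt(sigma2 * Gi[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_out[key] = np.where(sigma2 > floor, B[j] / np.where(se > 0, se, 1.0), 0.0)
        b_out[key] = B[j]
    return t_out, b_out, df


def fit_vertex_glm(Y: np.ndarray, subjects: pd.DataFrame,
                   design: SpmDesign) -> SpmResult:
    """Ordinary least squares at every vertex; t-maps for both contrasts.

    ``Y`` is the (n_subjects, V) combined field of the response variable.
    Effect size is the fracture-indicator coefficient as a percentage of the
    vertex-wise mean (NaN where the mean is not positive).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or len(Y) != len(subjects):
        raise InvalidArgumentError("Y must be (n_subjects, n_vertices)")
    X, names, frac_cols = build_design_matrix(subjects, design)
    if len(subjects) <= X.shape[1] + 10:
        raise InvalidArgumentError(
            f"need n > rank(design)+10 = {X.shape[1] + 10}, got {len(subjects)}")
    tstats, betas, df = _glm_tstats(X, Y, frac_cols)
    vmean = Y.mean(axis=0)
    raw_p, effect = {}, {}
    for contrast in CONTRASTS:
        raw_p[contrast] = 2.0 * t_dist.sf(np.abs(tstats[contrast]), df)
        with np.errstate(divide="ignore", invalid="ignore"):
            effect[contrast] = np.where(vmean > 0,
                                        100.0 * betas[contrast] / vmean, np.nan)
    return SpmResult(response=design.response, tstat=tstats, raw_p=raw_p,
                     effect_pct=effect, df=df, n=len(subjects), columns=names,
                     _X=X, _Y=Y, _frac_cols=frac_cols)


def _clusters(mesh: SurfaceMesh, tvals: np.ndarray, t_thresh: float):
    """Suprathreshold clusters (list of vertex index arrays) and masses.

    Positive and negative tails are clustered separately so opposite-signed
    neighbours never merge.
    """
    adj = mesh.vertex_adjacency()
    out = []
    for signed in (tvals > t_thresh, tvals < -t_thresh):
        idx = np.flatnonzero(signed)
        if len(idx) == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            verts = idx[labels == c]
            out.append((verts, float(np.abs(tvals[verts]).sum())))
    return out


def build_cluster_mass_null(result: SpmResult, mesh: SurfaceMesh,
                            n_perm: int, seed: int = 0,
                            cluster_p: float = 0.001) -> dict:
    """Permutation null of the maximum cluster mass, per contrast.

    Fracture labels are permuted across subjects (the two indicator columns
    jointly); all other covariates stay attached to their subjects.  The
    returned arrays can be reused across leave-one-out folds.
    """
    rng = np.random.default_rng(seed)
    X = result._X.copy()
    Y = result._Y
    yss = np.einsum("ij,ij->j", Y, Y)
    jt = result._frac_cols["trochanteric_vs_cohort"]
    jn = result._frac_cols["neck_vs_cohort"]
    frac_block = X[:, [jt, jn]].copy()
    n = len(X)
    t_thresh = t_dist.isf(cluster_p / 2.0, result.df)
    null = {c: np.zeros(n_perm) for c in CONTRASTS}
    for b in range(n_perm):
        perm = rng.permutation(n)
        X[:, jt] = frac_block[perm, 0]
        X[:, jn] = frac_block[perm, 1]
        tstats, _, _ = _glm_tstats(X, Y, result._frac_cols, yss=yss)
        for contrast in CONTRASTS:
            cl = _clusters(mesh, tstats[contrast], t_thresh)
            null[contrast][b] = max((m for _, m in cl), default=0.0)
    return null


def extract_significant_patches(
    result: SpmResult,
    mesh: SurfaceMesh,
    contrast: str,
    method: str = "permutation_fwer",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_p: float = 0.001,
    null_masses: dict | None = None,
    provenance: str = "full_sample",
    fallback_top_fraction: float = 0.01,
) -> PatchDefinition:
    """Fracture-type patch: union of significant clusters for the contrast.

    ``permutation_fwer`` keeps clusters whose mass exceeds the 1-alpha
    quantile of the permutation null (precomputed ``null_masses`` may be
    supplied to share one null across leave-one-out folds); ``bonferroni``
    keeps vertices with raw p below alpha / V.  When nothing survives the
    patch falls back first to the uncorrected cluster-forming mask and then
    to the top ``fallback_top_fraction`` most significant vertices, and the
    fallback is flagged -- a patch is never silently empty.
    """
    if contrast not in CONTRASTS:
        raise InvalidArgumentError(f"contrast must be one of {CONTRASTS}")
    tv = result.tstat[contrast]
    if method == "permutation_fwer":
        if null_masses is None:
            if n_perm < 500:
                raise InvalidArgumentError("n_perm must be >= 500")
            null_masses = build_cluster_mass_null(result, mesh, n_perm,
                                                  seed=seed, cluster_p=cluster_p)
        null = np.asarray(null_masses[contrast])
        t_thresh = t_dist.isf(cluster_p / 2.0, result.df)
        clusters = _clusters(mesh, tv, t_thresh)
        keep = []
        n_null = len(null)
        for verts, mass in clusters:
            # permutation p-value with the +1 correction
            p_fwer = (1.0 + np.sum(null >= mass)) / (1.0 + n_null)
            if p_fwer < alpha:
                keep.append(verts)
    elif method == "bonferroni":
        mask = result.raw_p[contrast] < alpha / len(tv)
        keep = [np.flatnonzero(mask)] if mask.any() else []
    else:
        raise InvalidArgumentError("method must be 'permutation_fwer' or 'bonferroni'")

    fallback = None
    if keep:
        verts = np.unique(np.concatenate(keep))
        n_clusters = len(keep)
    else:
        mask = result.raw_p[contrast] < cluster_p
        if mask.any():
            verts, fallback, n_clusters = np.flatnonzero(mask), "uncorrected", 0
        else:
            k = max(1, int(round(fallback_top_fraction * len(tv))))
            verts = np.argsort(np.abs(tv))[-k:]
            fallback, n_clusters = "top_fraction", 0
        verts = np.sort(verts)
    return PatchDefinition(variable=result.response, contrast=contrast,
                           vertices=verts, provenance=provenance,
                           fallback=fallback, n_clusters=n_clusters)


def patch_average(values: np.ndarray, patch: PatchDefinition) -> np.ndarray | float:
    """Unweighted mean of field values over the patch vertices.

    Accepts a single (V,) field or a stacked (n, V) array; returns a scalar
    or per-subject vector accordingly.
    """
    if patch.empty:
        raise EmptyPatchError(
            f"patch {patch.variable}/{patch.contrast} has no vertices")
    values = np.asarray(values, dtype=float)
    out = values[..., patch.vertices].mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out
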