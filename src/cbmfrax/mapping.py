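"""Mapping subject measurements onto the canonical surface.

Real cortical bone mapping registers each subject's femur surface
non-rigidly to a canonical femur and transfers the per-vertex measurements.
Here registration is an external, validated tool rather than part of the
analysis, so mapping is implemented as correspondence application: synthetic
subjects share the canonical topology and supply a (possibly partial)
vertex correspondence.  Shape-mode scores -- principal components of the
size-normalized surface coordinates -- are retained as confounders for any
systematic misregistration; size itself is excluded because it correlates
with fracture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError, MissingDataError

SIDES = ("left", "right", "combined")


@dataclass
class VertexField:
    """Per-vertex scalar map of one cortical variable for one subject/side."""

    variable: str
    values: np.ndarray
    subject_id: object = None
    side: str = "combined"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.side not in SIDES:
            raise InvalidArgumentError(f"side must be one of {SIDES}")


@dataclass
class ShapeModel:
    """Principal shape modes of size-normalized surface coordinates."""

    mean_shape: np.ndarray  # (V, 3)
    modes: np.ndarray  # (k, 3V), orthonormal rows
    scores: np.ndarray  # (n_subjects, k), zero mean columns
    variance_explained: np.ndarray  # (k,) fractions of total variance


def map_to_canonical(values: np.ndarray, correspondence: np.ndarray,
                     n_canonical: int) -> np.ndarray:
    """Reindex subject-surface values onto canonical vertex order.

    ``correspondence[j]`` gives, for canonical vertex ``j``, the index of the
    corresponding subject vertex, or -1 where no correspondence exists;
    missing canonical vertices are returned as NaN, never zero.
    """
    values = np.asarray(values, dtype=float)
    corr = np.asarray(correspondence)
    if corr.ndim != 1 or len(corr) != n_canonical:
        raise InvalidArgumentError(
            f"correspondence length {corr.shape} does not match canonical "
            f"vertex count {n_canonical}")
    if np.any(corr >= len(values)):
        raise InvalidArgumentError("correspondence indexes beyond subject field")
    out = np.full(n_canonical, np.nan)
    valid = corr >= 0
    out[valid] = values[corr[valid]]
    return out


def mirror_right_to_left(vertices: np.ndarray) -> np.ndarray:
    """Reflect right-hip coordinates about the x-axis into left-hand frame."""
    out = np.array(vertices, dtype=float, copy=True)
    out[..., 0] *= -1.0
    return out


def average_left_right(left: np.ndarray | None,
                       right: np.ndarray | None) -> np.ndarray:
    """Vertex-wise mean of the two hips; pass-through when one is absent.

    Right fields are assumed already mirrored to canonical (left-hand)
    orientation.  NaN entries on one side fall back to the other side's
    value, matching use-whichever-hip-is-available handling.
    """
    if left is None and right is None:
        raise MissingDataError("at least one of left/right must be present")
    if left is None:
        return np.array(right, dtype=float, copy=True)
    if right is None:
        return np.array(left, dtype=float, copy=True)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise InvalidArgumentError("left/right field shapes differ")
    stacked = np.stack([left, right])
    with np.errstate(invalid="ignore"):
        return np.nanmean(stacked, axis=0)


def _normalize_shapes(coords: np.ndarray) -> np.ndarray:
    """Translate each shape to zero centroid and scale to unit centroid size."""
    centered = coords - coords.mean(axis=1, keepdims=True)
    size = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(size == 0):
        raise InvalidArgumentError("degenerate shape with zero centroid size")
    return centered / size[:, None, None]


def compute_shape_modes(coords: np.ndarray, n_modes: int = 5) -> ShapeModel:
    """Principal shape modes with size excluded.

    ``coords`` is (n_subjects, V, 3); each shape is translated to zero
    centroid and scaled to unit centroid size *before* the principal
    decomposition, so uniform scaling contributes nothing to the modes.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise InvalidArgumentError("coords must be (n_subjects, V, 3)")
    n = coords.shape[0]
    if n < n_modes + 2:
        raise InsufficientDataError(
            f"need >= {n_modes + 2} subjects for {n_modes} modes, got {n}")
    flat = _normalize_shapes(coords).reshape(n, -1)
    mean = flat.mean(axis=0)
    centered = flat - mean
    # economy SVD; n << 3V in practice
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total_var = (s**2).sum()
    # shapes are unit-centroid-size, so genuine variation is far above
    # rounding level; identical inputs must not report noise as variance
    if total_var < 1e-20:
        total_var = 0.0
        s = np.zeros_like(s)
        centered = np.zeros_like(centered)
    k = min(n_modes, len(s))
    modes = vt[:k]
    scores = centered @ modes.T
    var_frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    if k < n_modes:  # pad degenerate cases to the requested mode count
        pad = n_modes - k
        modes = np.vstack([modes, np.zeros((pad, flat.shape[1]))])
        scores = np.hstack([scores, np.zeros((n, pad))])
        var_frac = np.concatenate([var_frac, np.zeros(pad)])
    return ShapeModel(mean_shape=mean.reshape(-1, 3), modes=modes,
                      scores=scores, variance_explained=var_frac)
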