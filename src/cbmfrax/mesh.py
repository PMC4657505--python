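"""Canonical proximal-femur-like surface mesh.

The canonical surface stands in for an average femur surface onto which all
per-subject measurements are mapped.  It is a closed, orientable,
sphere-topology surface of revolution (with a non-axisymmetric trochanteric
flare) built from a latitude/longitude grid plus two pole vertices, shaped
as head sphere + narrow neck + flared trochanter + shaft stub.  Every vertex
carries exactly one anatomical region label; the labels drive both the
synthetic effect geometry (where deficits are planted) and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse

from .errors import InvalidArgumentError

#: Anatomical regions, in label-code order.
REGION_NAMES = (
    "head",
    "neck_superior",
    "neck_inferior",
    "trochanter_superolateral",
    "trochanter_other",
    "shaft",
)
REGION_CODES = {name: i for i, name in enumerate(REGION_NAMES)}


@dataclass
class SurfaceMesh:
    """Triangulated closed surface with per-vertex anatomical region labels.

    Attributes
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array, 0-based vertex indices
    region_labels : (V,) int array of codes into :data:`REGION_NAMES`
    """

    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray
    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return self.n_vertices - len(edges) + self.n_faces

    def region_mask(self, region: str) -> np.ndarray:
        """Boolean mask of vertices in the named anatomical region."""
        if region not in REGION_CODES:
            raise InvalidArgumentError(
                f"unknown region {region!r}; expected one of {REGION_NAMES}"
            )
        return self.region_labels == REGION_CODES[region]

    def vertex_adjacency(self) -> sparse.csr_matrix:
        """Sparse symmetric 0/1 vertex adjacency (shared-edge neighbours)."""
        if self._adjacency is None:
            f = self.faces
            rows = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
            cols = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
            data = np.ones(len(rows), dtype=np.int8)
            adj = sparse.coo_matrix((data, (rows, cols)), shape=(self.n_vertices,) * 2)
            adj = adj.tocsr()
            adj.data[:] = 1
            self._adjacency = adj
        return self._adjacency

    def smoothing_operator(self, k: int = 2) -> sparse.csr_matrix:
        """Row-stochastic k-ring neighbourhood averaging operator.

        One application replaces each vertex value by the mean over the vertex
        and its edge neighbours; ``k`` applications widen the support to the
        k-ring.  Used to give synthetic spatial noise a short correlation
        length on the surface.
        """
        if k < 0:
            raise InvalidArgumentError("k must be >= 0")
        adj = self.vertex_adjacency().astype(np.float64)
        lap = adj + sparse.eye(self.n_vertices, format="csr")
        inv_deg = sparse.diags(1.0 / np.asarray(lap.sum(axis=1)).ravel())
        step = (inv_deg @ lap).tocsr()
        out = sparse.eye(self.n_vertices, format="csr")
        for _ in range(k):
            out = step @ out
        return out.tocsr()


def _radius_profile(t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Radius (mm) of the femur-like surface of revolution.

    ``t`` runs 0 (head apex) to 1 (distal shaft); ``phi`` is the azimuth.
    Head bulge, neck waist and a trochanteric flare with an extra
    superolateral lobe (phi near pi/2) produce the recognisable landmarks.
    """
    r = (
        10.0
        + 9.0 * np.exp(-(((t - 0.15) / 0.13) ** 2))  # femoral head
        - 4.5 * np.exp(-(((t - 0.41) / 0.10) ** 2))  # neck waist
        + 6.0 * np.exp(-(((t - 0.66) / 0.15) ** 2))  # trochanteric flare
    )
    lobe = 3.5 * np.exp(-(((t - 0.64) / 0.10) ** 2)) * np.exp(
        -((np.mod(phi - np.pi / 2, 2 * np.pi) - np.pi) ** 2) / (2 * 0.8**2)
    )
    return r + lobe


def _assign_region(t: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Region labels from parametric position (t along axis, phi azimuth).

    The superior aspect is phi in (0, pi); the superolateral trochanter is the
    superior sector of the trochanteric band, matching the planted lobe.
    """
    labels = np.full(t.shape, REGION_CODES["shaft"], dtype=np.int16)
    superior = np.sin(phi) > 0.0
    labels[t < 0.80] = REGION_CODES["trochanter_other"]
    band = (t >= 0.52) & (t < 0.80)
    labels[band & superior] = REGION_CODES["trochanter_superolateral"]
    neck = (t >= 0.30) & (t < 0.52)
    labels[neck & superior] = REGION_CODES["neck_superior"]
    labels[neck & ~superior] = REGION_CODES["neck_inferior"]
    labels[t < 0.30] = REGION_CODES["head"]
    return labels


def make_canonical_mesh(n_vertices_target: int, seed: int = 0) -> SurfaceMesh:
    """Build the canonical proximal-femur-like surface.

    Parameters
    ----------
    n_vertices_target : int
        Requested vertex count (>= 100); the constructed grid lands within
        +/-10% of it.
    seed : int
        Seeds a small (0.05 mm SD) vertex jitter so distinct seeds give
        distinct but topologically identical surfaces.

    Returns
    -------
    SurfaceMesh
        Closed orientable surface (V - E + F = 2) with a full region
        partition.
    """
    if n_vertices_target < 100:
        raise InvalidArgumentError("n_vertices_target must be >= 100")
    rng = np.random.default_rng(seed)

    # grid: n_theta rings of n_phi vertices plus two poles
    n_phi = max(8, int(round(np.sqrt(n_vertices_target))))
    n_theta = max(4, int(round((n_vertices_target - 2) / n_phi)))

    length = 110.0  # mm, head apex to distal cut
    t_rings = (np.arange(n_theta) + 1.0) / (n_theta + 1.0)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    tt, pp = np.meshgrid(t_rings, phi, indexing="ij")

    # taper radius to 0 at the poles so the caps close smoothly
    taper = np.sqrt(np.clip(4.0 * tt * (1.0 - tt), 0.0, 1.0)) ** 0.35
    rr = _radius_profile(tt, pp) * taper
    x = rr * np.cos(pp)
    y = rr * np.sin(pp)
    z = -length * tt

    ring_vertices = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    top_pole = np.array([[0.0, 0.0, 0.0]])
    bottom_pole = np.array([[0.0, 0.0, -length]])
    vertices = np.vstack([top_pole, ring_vertices, bottom_pole])
    vertices = vertices + rng.normal(0.0, 0.05, size=vertices.shape)

    def ring_idx(i: int, j: int) -> int:
        return 1 + i * n_phi + (j % n_phi)

    faces = []
    for j in range(n_phi):  # top cap (apex pole)
        faces.append([0, ring_idx(0, j + 1), ring_idx(0, j)])
    for i in range(n_theta - 1):
        for j in range(n_phi):
            a, b = ring_idx(i, j), ring_idx(i, j + 1)
            c, d = ring_idx(i + 1, j), ring_idx(i + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    last = n_theta - 1
    bottom = len(vertices) - 1
    for j in range(n_phi):  # bottom cap
        faces.append([bottom, ring_idx(last, j), ring_idx(last, j + 1)])
    faces = np.asarray(faces, dtype=np.int64)

    t_all = np.concatenate([[0.0], tt.ravel(), [1.0]])
    phi_all = np.concatenate([[np.pi / 2], pp.ravel(), [0.0]])
    labels = _assign_region(t_all, phi_all)

    return SurfaceMesh(vertices=vertices, faces=faces, region_labels=labels)


def save_ply(mesh: SurfaceMesh, path) -> None:
    """Write the mesh as ASCII PLY with a per-vertex integer ``region`` property."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    ply = tm.export(file_type="ply", encoding="ascii")
    if isinstance(ply, bytes):
        ply = ply.decode("ascii")
    # splice the region property into the header and vertex lines
    lines = ply.splitlines()
    out, in_vertex_header = [], False
    vertex_prop_end = None
    for i, line in enumerate(lines):
        if line.startswith("element vertex"):
            in_vertex_header = True
        elif in_vertex_header and not line.startswith("property"):
            vertex_prop_end = i
            in_vertex_header = False
        out.append(line)
    out.insert(vertex_prop_end, "property int region")
    header_end = out.index("end_header")
    for vi in range(mesh.n_vertices):
        li = header_end + 1 + vi
        out[li] = out[li].rstrip() + f" {int(mesh.region_labels[vi])}"
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def save_ply_with_scalars(mesh: SurfaceMesh, path, scalars: dict) -> None:
    """ASCII PLY with per-vertex float properties for external viewers.

    ``scalars`` maps property name -> (V,) array (NaN written as 0; use the
    CSV exports for missingness-aware analysis).
    """
    names = list(scalars)
    vals = np.column_stack([np.nan_to_num(np.asarray(scalars[k], dtype=float))
                            for k in names]) if names else np.zeros((mesh.n_vertices, 0))
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property int region\n")
        for k in names:
            fh.write(f"property float {k}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i in range(mesh.n_vertices):
            coords = " ".join(f"{c:.6f}" for c in mesh.vertices[i])
            extra = " ".join(f"{v:.6g}" for v in vals[i])
            fh.write(f"{coords} {int(mesh.region_labels[i])}"
                     + (f" {extra}" if names else "") + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def load_ply(path) -> SurfaceMesh:
    """Read a mesh written by :func:`save_ply` (ASCII or binary PLY accepted)."""
    with open(path, "rb") as fh:
        head = fh.read(2048).decode("ascii", errors="replace")
    if "format ascii" in head:
        mesh = _load_ascii_ply_with_region(path)
        if mesh is not None:
            return mesh
    tm = trimesh.load(path, file_type="ply", process=False)
    labels = np.zeros(len(tm.vertices), dtype=np.int16)
    for key in ("region", "ply_raw"):
        attr = tm.vertex_attributes.get(key) if hasattr(tm, "vertex_attributes") else None
        if attr is not None and np.ndim(attr) == 1:
            labels = np.asarray(attr, dtype=np.int16)
            break
    return SurfaceMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        region_labels=labels,
    )


def _load_ascii_ply_with_region(path) -> SurfaceMesh | None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        return None
    n_vert = n_face = 0
    vertex_props: list[str] = []
    current = None
    header_end = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert, current = int(parts[2]), "vertex"
        elif parts[:2] == ["element", "face"]:
            n_face, current = int(parts[2]), "face"
        elif parts and parts[0] == "property" and current == "vertex":
            vertex_props.append(parts[-1])
        elif line.strip() == "end_header":
            header_end = i
            break
    if "region" not in vertex_props:
        return None
    vdata = np.array(
        [lines[header_end + 1 + i].split() for i in range(n_vert)], dtype=float
    )
    cols = {name: j for j, name in enumerate(vertex_props)}
    vertices = vdata[:, [cols["x"], cols["y"], cols["z"]]]
    labels = vdata[:, cols["region"]].astype(np.int16)
    faces = np.array(
        [lines[header_end + 1 + n_vert + i].split()[1:4] for i in range(n_face)],
        dtype=np.int64,
    )
    return SurfaceMesh(vertices=vertices, faces=faces, region_labels=labels)
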