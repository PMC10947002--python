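"""Per-vertex principal curvatures and the two gyrification markers.

Principal curvatures κ1 ≥ κ2 (mm⁻¹) are estimated by fitting a quadric patch
h(x, y) = a·x² + b·xy + c·y² + d·x + e·y over each vertex's 2-ring
neighbourhood, expressed in the tangent frame of its area-weighted normal;
the curvatures are the eigenvalues of the Weingarten map of the fitted
patch.  The linear terms absorb small errors in the estimated normal.

Sign convention: regions that are convex with respect to the outward normal
(domes, gyral crowns) have positive curvature.  From κ1, κ2 follow

* curvedness   C  = sqrt((κ1² + κ2²) / 2)  ≥ 0   — how strongly bent,
* shape index  SI = (2/π)·arctan((κ1 + κ2)/(κ1 − κ2)) ∈ [−1, 1]
                                                  — what kind of bend,

with SI = +1 a convex dome (gyrus), −1 a concave cup (sulcus), 0 a saddle,
±0.5 convex/concave cylindrical ridges.  At umbilic points (κ1 = κ2) the
shape index is taken as sign(κ1)·1 (0 on a plane) so that summaries over
near-spherical surfaces stay well defined.

An angle-deficit Gaussian-curvature estimator is provided as an independent
internal cross-check of the quadric route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .surface_io import SurfaceMesh

_UMBILIC_RTOL = 1e-9


@dataclass
class CurvatureField:
    """Per-vertex κ1, κ2, curvedness and shape index of one mesh."""

    kappa1: np.ndarray
    kappa2: np.ndarray
    curvedness: np.ndarray
    shape_index: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.kappa1)
        if not (len(self.kappa2) == len(self.curvedness) == len(self.shape_index) == n):
            raise ValueError("curvature field components differ in length")
        if np.any(self.kappa1 < self.kappa2 - 1e-9 * np.abs(self.kappa1)):
            raise ValueError("kappa1 must dominate kappa2")

    def __len__(self) -> int:
        return len(self.kappa1)


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Outward unit vertex normals, area-weighted over incident faces."""
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*n
    normals = np.zeros_like(v)
    for i in range(3):
        np.add.at(normals, f[:, i], fn)
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    return normals / norms[:, None]


def _ring_neighbors(mesh: SurfaceMesh, rings: int) -> sparse.csr_matrix:
    """Sparse boolean matrix whose rows index each vertex's ring neighbours."""
    n = mesh.n_vertices
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    adj = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n)
    )
    reach = adj.copy()
    for _ in range(rings - 1):
        reach = (reach + reach @ adj).tocsr()
    reach.setdiag(False)
    reach.eliminate_zeros()
    return reach.tocsr()


def principal_curvatures(
    mesh: SurfaceMesh, neighborhood_rings: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex (κ1, κ2), κ1 ≥ κ2, convex-positive w.r.t. outward normals."""
    if neighborhood_rings < 1:
        raise ValueError("neighborhood_rings must be >= 1")
    v = mesh.vertices
    normals = vertex_normals(mesh)
    reach = _ring_neighbors(mesh, neighborhood_rings)

    k1 = np.empty(len(v))
    k2 = np.empty(len(v))
    indptr, indices = reach.indptr, reach.indices
    for i in range(len(v)):
        nb = indices[indptr[i]: indptr[i + 1]]
        if len(nb) < 5:
            raise ValueError(
                f"vertex {i} has only {len(nb)} ring neighbours; mesh too small "
                "for quadric fitting"
            )
        nrm = normals[i]
        # tangent basis orthogonal to the normal
        t1 = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.dot(t1, t1) < 1e-12:
            t1 = np.cross(nrm, [0.0, 1.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(nrm, t1)

        q = v[nb] - v[i]
        x = q @ t1
        y = q @ t2
        h = q @ nrm
        A = np.column_stack([x * x, x * y, y * y, x, y])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        a, b, c, d, e = coef

        # Weingarten map of z = h(x, y) at the origin
        W = np.sqrt(1.0 + d * d + e * e)
        E, F, G = 1.0 + d * d, d * e, 1.0 + e * e
        L, M, N = 2.0 * a / W, b / W, 2.0 * c / W
        det_I = E * G - F * F
        K = (L * N - M * M) / det_I
        H = (E * N + G * L - 2.0 * F * M) / (2.0 * det_I)
        disc = max(H * H - K, 0.0)
        r = np.sqrt(disc)
        # the patch height is measured along the *outward* normal, under which
        # convex surfaces curve downwards; negate to make convex positive
        ka, kb = -(H - r), -(H + r)
        k1[i], k2[i] = max(ka, kb), min(ka, kb)
    return k1, k2


def curvedness(kappa1: np.ndarray, kappa2: np.ndarray) -> np.ndarray:
    """C = sqrt((κ1² + κ2²)/2), the magnitude of surface bending (mm⁻¹)."""
    kappa1 = np.asarray(kappa1, dtype=float)
    kappa2 = np.asarray(kappa2, dtype=float)
    return np.sqrt((kappa1**2 + kappa2**2) / 2.0)


def shape_index(kappa1, kappa2) -> np.ndarray:
    """SI = (2/π)·arctan((κ1+κ2)/(κ1−κ2)) ∈ [−1, 1]; ±1 at umbilics, 0 flat."""
    k1 = np.atleast_1d(np.asarray(kappa1, dtype=float))
    k2 = np.atleast_1d(np.asarray(kappa2, dtype=float))
    if np.any(k1 < k2 - 1e-12 * np.maximum(1.0, np.abs(k1) + np.abs(k2))):
        raise ValueError("shape_index requires kappa1 >= kappa2")
    diff = k1 - k2
    scale = np.maximum(1.0, np.abs(k1) + np.abs(k2))
    umbilic = diff <= _UMBILIC_RTOL * scale
    si = np.zeros_like(k1)
    safe = ~umbilic
    si[safe] = (2.0 / np.pi) * np.arctan2(k1[safe] + k2[safe], diff[safe])
    si[umbilic] = np.sign(k1[umbilic])
    si = np.clip(si, -1.0, 1.0)
    if np.isscalar(kappa1) or np.ndim(kappa1) == 0:
        return si[0]
    return si


def curvature_field(mesh: SurfaceMesh, neighborhood_rings: int = 2) -> CurvatureField:
    k1, k2 = principal_curvatures(mesh, neighborhood_rings)
    return CurvatureField(
        kappa1=k1,
        kappa2=k2,
        curvedness=curvedness(k1, k2),
        shape_index=shape_index(k1, k2),
    )


# ---------------------------------------------------------------------------
# Independent cross-check: angle-deficit Gaussian curvature
# ---------------------------------------------------------------------------

def angle_deficit_gaussian_curvature(mesh: SurfaceMesh) -> np.ndarray:
    """Discrete Gaussian curvature K = (2π − Σ angles) / (barycentric area).

    A classical estimator independent of the quadric fit, kept as an internal
    oracle: on well-shaped meshes it should agree with κ1·κ2.
    """
    v, f = mesh.vertices, mesh.faces
    deficits = np.full(len(v), 2.0 * np.pi)
    areas = np.zeros(len(v))
    fa = mesh.face_areas()
    for i in range(3):
        p = v[f[:, i]]
        q = v[f[:, (i + 1) % 3]] - p
        r = v[f[:, (i + 2) % 3]] - p
        cosang = np.einsum("ij,ij->i", q, r) / (
            np.linalg.norm(q, axis=1) * np.linalg.norm(r, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.subtract.at(deficits, f[:, i], ang)
        np.add.at(areas, f[:, i], fa / 3.0)
    return deficits / areas


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_curvature_ply(mesh: SurfaceMesh, field: CurvatureField, path) -> None:
    """ASCII PLY with per-vertex kappa1/kappa2/curvedness/shape_index scalars."""
    if len(field) != mesh.n_vertices:
        raise ValueError("field length does not match mesh vertex count")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        for p in ("x", "y", "z", "kappa1", "kappa2", "curvedness", "shape_index"):
            fh.write(f"property float {p}\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = np.column_stack(
            [mesh.vertices, field.kappa1, field.kappa2, field.curvedness,
             field.shape_index]
        )
        for row in cols:
            fh.write(" ".join(f"{x:.6g}" for x in row) + "\n")
        for face in mesh.faces:
            fh.write("3 " + " ".join(str(int(i)) for i in face) + "\n")
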