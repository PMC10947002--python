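"""Label-volume and surface-mesh I/O plus segmentation <-> mesh conversion.

The pipeline's raw inputs are 3D integer label volumes on an isotropic grid
(NIfTI-1), with label codes 1 = unmyelinated white matter, 2 = ventricles,
3 = cerebellum.  Surfaces are closed triangle meshes in world millimetre
coordinates with outward normals.  World convention: the centre of voxel
(i, j, k) sits at ``origin + index * spacing`` (voxel-centre convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

log = logging.getLogger(__name__)

LABEL_WHITE_MATTER = 1
LABEL_VENTRICLES = 2
LABEL_CEREBELLUM = 3
KNOWN_LABELS = (LABEL_WHITE_MATTER, LABEL_VENTRICLES, LABEL_CEREBELLUM)

#: Components of the ventricular compartment smaller than this many voxels are
#: treated as segmentation noise; larger ones (e.g. the two lateral bodies)
#: are all kept.
MIN_VENTRICLE_COMPONENT_VOXELS = 50

_ISOTROPY_RTOL = 1e-3


class SurfaceExtractionError(RuntimeError):
    """A structure could not be turned into a valid closed surface."""


@dataclass
class LabelVolume:
    """3D integer segmentation grid with isotropic voxel spacing (mm)."""

    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must hold integer label codes")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float)
        extra = set(np.unique(self.data)) - ({0} | set(KNOWN_LABELS))
        if extra:
            raise ValueError(f"unknown label codes {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels_present(self) -> list[int]:
        return [int(c) for c in np.unique(self.data) if c != 0]

    def mask(self, label: int) -> np.ndarray:
        if label not in self.labels_present():
            raise ValueError(f"label {label} not present in volume")
        return self.data == label

    def voxel_centers(self, mask: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of the centres of the masked voxels."""
        idx = np.argwhere(mask)
        return self.origin + idx * self.spacing


@dataclass
class SurfaceMesh:
    """Closed triangulated surface in mm coordinates with outward normals.

    ``vertex_tags`` optionally carries a per-vertex integer identity used by
    the synthetic generator to record ground-truth correspondence across
    timepoints; ``lobe_labels`` optionally carries per-vertex lobe codes.
    """

    vertices: np.ndarray
    faces: np.ndarray
    structure_label: int | None = None
    vertex_tags: np.ndarray | None = None
    lobe_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3) vertex index triples")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")

    # -- conversions ------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, **kw) -> "SurfaceMesh":
        return cls(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces), **kw)

    # -- geometry ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def face_areas(self) -> np.ndarray:
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem (positive = outward)."""
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)

    def edge_lengths(self) -> np.ndarray:
        e = np.vstack(
            [
                self.vertices[self.faces[:, i]] - self.vertices[self.faces[:, j]]
                for i, j in ((0, 1), (1, 2), (2, 0))
            ]
        )
        return np.linalg.norm(e, axis=1)

    def is_closed_manifold(self) -> bool:
        tm = self.to_trimesh()
        return bool(tm.is_watertight and tm.is_winding_consistent)

    def validate(self) -> None:
        """Raise if the mesh violates the closed-2-manifold invariants."""
        if len(self.faces) == 0:
            raise ValueError("mesh has no faces")
        if not self.is_closed_manifold():
            raise ValueError("mesh is not a closed 2-manifold")
        if np.any(self.face_areas() <= 0):
            raise ValueError("mesh contains degenerate faces")
        if self.enclosed_volume() <= 0:
            raise ValueError("mesh normals are not outward (negative volume)")


# ---------------------------------------------------------------------------
# NIfTI label-volume I/O
# ---------------------------------------------------------------------------

def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1 integer label volume; spacing comes from the header.

    Anisotropic voxels are rejected: the pipeline assumes the isotropic grid
    produced by super-resolution reconstruction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=_ISOTROPY_RTOL):
        raise ValueError(f"anisotropic voxels {tuple(zooms)} are unsupported")
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError("volume holds non-integer data; not a label volume")
        data = np.round(data).astype(np.int16)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return LabelVolume(data=data.astype(np.int16), spacing=float(zooms[0]), origin=origin)


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    affine = np.diag([vol.spacing] * 3 + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(vol.data.astype(np.int16), affine)
    img.header.set_zooms((vol.spacing,) * 3)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Segmentation -> mesh
# ---------------------------------------------------------------------------

def _select_components(mask: np.ndarray, label: int) -> np.ndarray:
    """Largest connected component, except ventricles keep all >= 50 voxels.

    The ventricular compartment legitimately contains two lateral bodies, so
    it is treated as the union of all non-trivial components.
    """
    comp, n = ndimage.label(mask)
    if n == 0:
        raise SurfaceExtractionError("structure mask is empty")
    sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
    if label == LABEL_VENTRICLES:
        keep = np.flatnonzero(sizes >= MIN_VENTRICLE_COMPONENT_VOXELS) + 1
        if len(keep) == 0:
            keep = np.array([int(np.argmax(sizes)) + 1])
    else:
        keep = np.array([int(np.argmax(sizes)) + 1])
    return np.isin(comp, keep)


def extract_mesh(
    vol: LabelVolume,
    label: int,
    smoothing_iters: int = 10,
    step_size: int = 1,
    mask_sigma: float = 0.5,
) -> SurfaceMesh:
    """Extract a smooth closed surface of one structure.

    Marching cubes at iso-level 0.5 (sub-voxel boundary placement) on the
    binary mask after a light Gaussian anti-aliasing (``mask_sigma`` voxels;
    suppresses the voxel staircase that would otherwise bias area and
    curvature), largest connected component (ventricles: all components with
    at least 50 voxels), followed by Taubin smoothing, which avoids the
    volume shrinkage of plain Laplacian smoothing.  Raises if the mask
    touches the volume border, which signals a clipped structure.
    """
    mask = vol.mask(label)
    border = (
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
    if border:
        raise SurfaceExtractionError(
            f"label {label} touches the volume border; structure is clipped"
        )
    mask = _select_components(mask, label)

    level_set = mask.astype(np.float32)
    if mask_sigma > 0:
        level_set = ndimage.gaussian_filter(level_set, sigma=mask_sigma)
    verts, faces, _, _ = measure.marching_cubes(
        level_set, level=0.5,
        spacing=(vol.spacing,) * 3,
        step_size=int(step_size),
    )
    verts = verts + vol.origin

    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    tm.fix_normals()
    # a structure whose mask contains a cavity (e.g. white matter around the
    # carved-out ventricles) yields an inner surface as well: keep the outer
    # boundary only.  Ventricles keep every body enclosing >= 50 voxels.
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        if label == LABEL_VENTRICLES:
            min_vol = MIN_VENTRICLE_COMPONENT_VOXELS * vol.spacing**3
            keep = [p for p in parts if abs(p.volume) >= min_vol]
            if not keep:
                keep = [max(parts, key=lambda p: abs(p.volume))]
        else:
            keep = [max(parts, key=lambda p: p.area)]
        tm = trimesh.util.concatenate(keep) if len(keep) > 1 else keep[0]
        tm.fix_normals()
    if smoothing_iters > 0:
        trimesh.smoothing.filter_taubin(
            tm, lamb=0.5, nu=0.53, iterations=int(smoothing_iters)
        )
    tm.update_faces(tm.area_faces > 1e-12)
    tm.remove_unreferenced_vertices()
    if tm.volume < 0:
        tm.invert()

    mesh = SurfaceMesh.from_trimesh(tm, structure_label=label)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# Mesh -> volume (parity / scanline voxelizer)
# ---------------------------------------------------------------------------

def voxelize(
    mesh: SurfaceMesh,
    spacing: float,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
    padding: int = 2,
    label: int | None = None,
) -> LabelVolume:
    """Rasterise a closed mesh: a voxel is labelled iff its centre is inside.

    Uses an axis-aligned scanline parity test: for every (x, y) grid column a
    +z ray is cast and its transversal crossings with the triangles counted;
    a voxel centre is interior when an odd number of crossings lies above it.
    Rays are jittered by 1e-7 * spacing to dodge edge-exact hits, which
    perturbs classification only for centres within that distance of the
    surface.
    """
    tm = mesh.to_trimesh()
    if not (tm.is_watertight and tm.is_winding_consistent):
        raise ValueError("voxelize requires a closed manifold mesh")
    if label is None:
        label = mesh.structure_label if mesh.structure_label is not None else 1

    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    if origin is None:
        origin = lo - padding * spacing
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        shape = tuple(
            int(np.ceil((hi[a] - origin[a]) / spacing)) + padding + 1 for a in range(3)
        )
    nx, ny, nz = shape

    inside = points_inside_mesh_grid(mesh.vertices, mesh.faces, origin, spacing, shape)
    data = np.where(inside, np.int16(label), np.int16(0))
    return LabelVolume(data=data, spacing=float(spacing), origin=origin)


def points_inside_mesh_grid(
    vertices: np.ndarray,
    faces: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Boolean grid of voxel-centre-inside-surface tests (parity method)."""
    nx, ny, nz = shape
    eps = 1e-7 * spacing
    ox, oy, oz = origin[0] + eps, origin[1] + eps * 0.618, origin[2]

    tri = vertices[faces]  # (m, 3, 3)
    p0, p1, p2 = tri[:, 0], tri[:, 1], tri[:, 2]
    # plane normals; skip triangles parallel to the z rays
    n = np.cross(p1 - p0, p2 - p0)
    ok = np.abs(n[:, 2]) > 1e-14
    p0, p1, p2, n = p0[ok], p1[ok], p2[ok], n[ok]

    # candidate grid columns per triangle bounding box
    minx = np.minimum.reduce([p0[:, 0], p1[:, 0], p2[:, 0]])
    maxx = np.maximum.reduce([p0[:, 0], p1[:, 0], p2[:, 0]])
    miny = np.minimum.reduce([p0[:, 1], p1[:, 1], p2[:, 1]])
    maxy = np.maximum.reduce([p0[:, 1], p1[:, 1], p2[:, 1]])
    ix0 = np.clip(np.ceil((minx - ox) / spacing).astype(np.int64), 0, nx - 1)
    ix1 = np.clip(np.floor((maxx - ox) / spacing).astype(np.int64), 0, nx - 1)
    iy0 = np.clip(np.ceil((miny - oy) / spacing).astype(np.int64), 0, ny - 1)
    iy1 = np.clip(np.floor((maxy - oy) / spacing).astype(np.int64), 0, ny - 1)
    kx = np.maximum(ix1 - ix0 + 1, 0)
    ky = np.maximum(iy1 - iy0 + 1, 0)
    npts = kx * ky
    keep = npts > 0
    if not np.any(keep):
        return np.zeros(shape, dtype=bool)
    p0, p1, p2, n = p0[keep], p1[keep], p2[keep], n[keep]
    ix0, iy0, kx, ky, npts = ix0[keep], iy0[keep], kx[keep], ky[keep], npts[keep]

    t_idx = np.repeat(np.arange(len(p0)), npts)
    offs = np.concatenate([np.arange(c) for c in npts])
    ix = ix0[t_idx] + offs // ky[t_idx]
    iy = iy0[t_idx] + offs % ky[t_idx]
    cx = ox + ix * spacing
    cy = oy + iy * spacing

    # 2D barycentric test in the xy projection
    a0, a1, a2 = p0[t_idx], p1[t_idx], p2[t_idx]
    d = (a1[:, 1] - a2[:, 1]) * (a0[:, 0] - a2[:, 0]) + (
        a2[:, 0] - a1[:, 0]
    ) * (a0[:, 1] - a2[:, 1])
    w0 = (a1[:, 1] - a2[:, 1]) * (cx - a2[:, 0]) + (a2[:, 0] - a1[:, 0]) * (
        cy - a2[:, 1]
    )
    w1 = (a2[:, 1] - a0[:, 1]) * (cx - a2[:, 0]) + (a0[:, 0] - a2[:, 0]) * (
        cy - a2[:, 1]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        w0 = w0 / d
        w1 = w1 / d
    w2 = 1.0 - w0 - w1
    hit = (w0 >= 0) & (w1 >= 0) & (w2 >= 0) & np.isfinite(w0) & np.isfinite(w1)
    if not np.any(hit):
        return np.zeros(shape, dtype=bool)
    ix, iy, t_idx = ix[hit], iy[hit], t_idx[hit]
    cx, cy = cx[hit], cy[hit]

    # z of each ray-plane crossing
    nn = n[t_idx]
    pp = p0[t_idx]
    zc = pp[:, 2] + (
        nn[:, 0] * (pp[:, 0] - cx) + nn[:, 1] * (pp[:, 1] - cy)
    ) / nn[:, 2]

    # a crossing at z* toggles all voxel centres with z < z*, i.e. indices
    # k < kstar = ceil((z* - oz) / spacing)
    kstar = np.ceil((zc - oz) / spacing).astype(np.int64)
    kstar = np.clip(kstar, 0, nz)
    bins = np.zeros((nx, ny, nz + 1), dtype=np.int64)
    np.add.at(bins, (ix, iy, kstar), 1)
    above = bins[:, :, ::-1].cumsum(axis=2)[:, :, ::-1]  # crossings with kstar > k
    # crossings strictly above voxel k: those with kstar >= k+1
    inside = (above[:, :, 1:] % 2) == 1
    return inside


# ---------------------------------------------------------------------------
# Mesh file I/O
# ---------------------------------------------------------------------------

_MESH_FORMATS = ("ply", "off")


def write_mesh(mesh: SurfaceMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh as binary little-endian PLY or ASCII OFF."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; use one of {_MESH_FORMATS}")
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write a mesh with no faces")
    tm = mesh.to_trimesh()
    data = tm.export(file_type=fmt)
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)


def read_mesh(path: str | Path, structure_label: int | None = None) -> SurfaceMesh:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tm = trimesh.load(str(path), process=False, force="mesh")
    return SurfaceMesh.from_trimesh(tm, structure_label=structure_label)
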