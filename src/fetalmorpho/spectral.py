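"""Laplacian eigenmodes and joint spectral longitudinal correspondence.

Two surfaces of the same developing structure, imaged weeks apart, differ in
size, folding and triangulation, but the low-order eigenmodes of their
surface Laplacians encode comparable coarse spatial patterns.  Matching the
surfaces in that shared spectral domain gives a per-vertex longitudinal
correspondence without any volumetric registration:

1. per-mesh eigenmodes of the cotangent-weighted Laplacian (lumped vertex
   areas as the mass matrix), each mode normalised to unit magnitude;
2. sign/order alignment of the second spectrum to the first (the eigen-sign
   and near-degenerate ordering of Laplacian modes are arbitrary);
3. a dual-layered graph whose layers are the two meshes, connected by the
   initial spectral correspondence links; the eigenmodes of this combined
   graph embed both layers in one shared basis;
4. final correspondence by nearest neighbour in the joint, eigenvalue-scaled
   spectral coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.linalg import orthogonal_procrustes
from scipy.sparse import csgraph
from scipy.sparse.linalg import eigsh
from scipy.spatial import cKDTree

from .surface_io import SurfaceMesh

log = logging.getLogger(__name__)

DEFAULT_K = 5  # non-trivial modes used for matching
DEFAULT_LINK_FRACTION = 0.1


@dataclass
class SpectralEmbedding:
    """First k non-trivial Laplacian eigenpairs of one mesh.

    ``eigenvalues`` holds k+1 ascending values including the trivial ~0 first
    eigenvalue; ``modes`` is (n_vertices, k) with each column normalised to
    unit magnitude and a deterministic sign (largest-magnitude entry
    positive).
    """

    eigenvalues: np.ndarray
    modes: np.ndarray
    #: per-mode alignment confidence in [0, 1], set by align_spectra; modes
    #: of a truncated degenerate multiplet cannot be aligned and score low
    mode_confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        if np.any(np.diff(self.eigenvalues) < -1e-9):
            raise ValueError("eigenvalues must be ascending")
        if len(self.eigenvalues) != self.modes.shape[1] + 1:
            raise ValueError("expected k+1 eigenvalues for k non-trivial modes")

    @property
    def k(self) -> int:
        return self.modes.shape[1]

    def scaled_coordinates(self) -> np.ndarray:
        """Modes divided by sqrt(eigenvalue): standard spectral-matching metric."""
        lam = np.maximum(self.eigenvalues[1:], 1e-12)
        return self.modes / np.sqrt(lam)


@dataclass
class Correspondence:
    """For each vertex of mesh A, the matched vertex index on mesh B."""

    map: np.ndarray
    quality: np.ndarray  # per-vertex residual distance in joint spectral space

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.int64)
        self.quality = np.asarray(self.quality, dtype=float)
        if len(self.map) != len(self.quality):
            raise ValueError("map and quality lengths differ")


# ---------------------------------------------------------------------------
# Laplacian construction
# ---------------------------------------------------------------------------

def cotangent_laplacian(
    mesh: SurfaceMesh, weighting: str = "cotangent"
) -> tuple[sparse.csr_matrix, sparse.dia_matrix]:
    """Symmetric Laplacian L = D − W and lumped mass matrix of a mesh.

    ``weighting='cotangent'`` uses the half-cotangent edge weights of the two
    angles opposite each edge; ``'uniform'`` falls back to the unweighted
    graph Laplacian for degenerate triangulations.
    """
    n = mesh.n_vertices
    f = mesh.faces
    v = mesh.vertices

    if weighting == "uniform":
        rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
        cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
        W = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        W = W.maximum(W.T)
    elif weighting == "cotangent":
        rows, cols, vals = [], [], []
        for i in range(3):
            a = f[:, i]
            b = f[:, (i + 1) % 3]
            c = f[:, (i + 2) % 3]  # vertex opposite edge (a, b)
            u = v[a] - v[c]
            w = v[b] - v[c]
            cross = np.linalg.norm(np.cross(u, w), axis=1)
            cot = np.einsum("ij,ij->i", u, w) / np.maximum(cross, 1e-12)
            rows.append(a)
            cols.append(b)
            vals.append(0.5 * cot)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        W = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        W = W + W.T
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(deg) - W

    areas = np.zeros(n)
    fa = mesh.face_areas()
    for i in range(3):
        np.add.at(areas, f[:, i], fa / 3.0)
    M = sparse.diags(np.maximum(areas, 1e-12))
    return L.tocsr(), M


def _fix_signs(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign: the largest-|entry| component is made positive."""
    out = modes.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def laplacian_eigenmodes(
    mesh: SurfaceMesh, k: int = DEFAULT_K, weighting: str = "cotangent"
) -> SpectralEmbedding:
    """First k non-trivial eigenmodes of the mesh Laplacian, unit magnitude."""
    if k < 1:
        raise ValueError("k must be >= 1")
    L, M = cotangent_laplacian(mesh, weighting)
    n_comp = _count_components(mesh)
    if n_comp > 1:
        raise ValueError(
            f"mesh has {n_comp} connected components; eigenvalue 0 would have "
            "multiplicity > 1 (invalid input for spectral matching)"
        )
    n = mesh.n_vertices
    v0 = np.full(n, 1.0 / np.sqrt(n))
    scale = L.diagonal().mean() / M.diagonal().mean()
    vals, vecs = eigsh(L, k=k + 1, M=M, sigma=-1e-6 * scale, which="LM", v0=v0)
    order = np.argsort(vals)
    vals = np.maximum(vals[order], 0.0)
    vals[0] = max(vals[0], 0.0)
    modes = vecs[:, order][:, 1:]
    modes = modes / np.linalg.norm(modes, axis=0, keepdims=True)
    return SpectralEmbedding(eigenvalues=vals, modes=_fix_signs(modes))


def _count_components(mesh: SurfaceMesh) -> int:
    n = mesh.n_vertices
    f = mesh.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0]])
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = csgraph.connected_components(adj, directed=False)
    return int(n_comp)


# ---------------------------------------------------------------------------
# Spectrum alignment
# ---------------------------------------------------------------------------

def _degenerate_groups(eigenvalues: np.ndarray, rtol: float = 0.05) -> list[np.ndarray]:
    """Partition non-trivial mode indices into near-degenerate eigenvalue
    groups (consecutive relative gap below ``rtol``)."""
    lam = eigenvalues[1:]
    groups: list[list[int]] = [[0]]
    for i in range(1, len(lam)):
        scale = max(abs(lam[i]), abs(lam[i - 1]), 1e-12)
        if (lam[i] - lam[i - 1]) / scale < rtol:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [np.asarray(g) for g in groups]


def align_spectra(
    embA: SpectralEmbedding,
    embB: SpectralEmbedding,
    pairing: np.ndarray | None = None,
) -> tuple[SpectralEmbedding, np.ndarray]:
    """Align B's modes to A's: sign flips, swaps and in-multiplet rotations.

    ``pairing`` maps each A vertex to a coarse B counterpart (identity when
    omitted, valid for same-parameterisation meshes).  Eigen-sign and
    ordering are arbitrary per mesh, and within near-degenerate eigenvalue
    multiplets the modes are only defined up to rotation; all three
    ambiguities are resolved at once by an orthogonal Procrustes fit of B's
    modes onto A's inside each degenerate group (singleton groups reduce to
    a sign flip).  Returns the aligned embedding and the block-orthogonal
    k x k transform applied to B's mode matrix.
    """
    if embA.k != embB.k:
        raise ValueError("embeddings must have the same number of modes")
    k = embA.k
    if pairing is None:
        if embA.modes.shape[0] != embB.modes.shape[0]:
            raise ValueError("pairing required for meshes of different size")
        pairing = np.arange(embA.modes.shape[0])

    A = embA.modes
    B = embB.modes[pairing]  # B modes sampled at the A-paired vertices
    transform = np.zeros((k, k))
    for grp in _degenerate_groups(embA.eigenvalues):
        if len(grp) == 1:
            j = grp[0]
            dot = float(A[:, j] @ B[:, j])
            transform[j, j] = 1.0 if dot >= 0 else -1.0
        else:
            R, _ = orthogonal_procrustes(B[:, grp], A[:, grp])
            transform[np.ix_(grp, grp)] = R

    modes = embB.modes @ transform
    modes = modes / np.linalg.norm(modes, axis=0, keepdims=True)
    Bal = B @ transform
    Bal = Bal / np.maximum(np.linalg.norm(Bal, axis=0, keepdims=True), 1e-12)
    conf = np.abs(np.einsum("ij,ij->j", A, Bal)) / np.maximum(
        np.linalg.norm(A, axis=0), 1e-12
    )
    aligned = SpectralEmbedding(
        eigenvalues=embB.eigenvalues, modes=modes, mode_confidence=conf
    )
    return aligned, transform


# ---------------------------------------------------------------------------
# Coarse geometric pairing
# ---------------------------------------------------------------------------

def similarity_align(
    source: np.ndarray, target: np.ndarray, pairing: np.ndarray | None = None
) -> np.ndarray:
    """Similarity-transform (Procrustes) alignment of source onto target.

    With equal point counts the index pairing is used directly; otherwise
    only centroid/scale normalisation plus a rotation estimated from mutual
    nearest neighbours of the normalised clouds.
    """
    src_c = source - source.mean(axis=0)
    tgt_c = target - target.mean(axis=0)
    s_src = np.sqrt((src_c**2).sum() / len(src_c))
    s_tgt = np.sqrt((tgt_c**2).sum() / len(tgt_c))
    src_n = src_c / s_src
    if pairing is None and len(source) == len(target):
        pairing = np.arange(len(source))
    if pairing is not None:
        R, _ = orthogonal_procrustes(src_n[: len(pairing)], tgt_c[pairing] / s_tgt)
    else:
        tree = cKDTree(tgt_c / s_tgt)
        _, nn = tree.query(src_n)
        R, _ = orthogonal_procrustes(src_n, (tgt_c / s_tgt)[nn])
    return src_n @ R * s_tgt + target.mean(axis=0)


def _coarse_pairing(meshA: SurfaceMesh, meshB: SurfaceMesh) -> np.ndarray:
    """Nearest-neighbour A→B pairing after similarity alignment of B onto A."""
    if meshA.n_vertices == meshB.n_vertices:
        b_aligned = similarity_align(meshB.vertices, meshA.vertices)
    else:
        b_aligned = similarity_align(meshB.vertices, meshA.vertices, pairing=None)
    tree = cKDTree(b_aligned)
    _, nn = tree.query(meshA.vertices)
    return nn


# ---------------------------------------------------------------------------
# Joint spectral matching
# ---------------------------------------------------------------------------

def joint_spectral_match(
    meshA: SurfaceMesh,
    meshB: SurfaceMesh,
    k: int = DEFAULT_K,
    link_fraction: float = DEFAULT_LINK_FRACTION,
    weighting: str = "cotangent",
) -> Correspondence:
    """Longitudinal vertex correspondence A→B via a dual-layered graph.

    Initial links come from nearest neighbours in the aligned, eigenvalue-
    scaled per-mesh spectral coordinates; the layers joined by those links
    form one graph whose eigenmodes embed both meshes in a shared basis, in
    which each A vertex takes its nearest B vertex.
    """
    embA = laplacian_eigenmodes(meshA, k, weighting)
    embB = laplacian_eigenmodes(meshB, k, weighting)

    pairing = _coarse_pairing(meshA, meshB)
    embB_aligned, _ = align_spectra(embA, embB, pairing=pairing)

    # modes whose multiplet was truncated by k cannot be aligned between the
    # meshes; build the initial links only from trustworthy modes
    conf = embB_aligned.mode_confidence
    good = conf >= 0.8
    if good.sum() < 2:
        good = np.ones(embA.k, dtype=bool)
        log.warning("spectrum alignment quality low (best %.2f); using all modes",
                    float(conf.max()))
    inv_sqrt = 1.0 / np.sqrt(np.maximum(embA.eigenvalues[1:], 1e-12))
    coordA = (embA.modes * inv_sqrt)[:, good]
    coordB = (embB_aligned.modes * inv_sqrt)[:, good]
    _, init = cKDTree(coordB).query(coordA)

    # dual-layered graph
    LA, MA = cotangent_laplacian(meshA, weighting)
    LB, MB = cotangent_laplacian(meshB, weighting)
    WA = sparse.diags(LA.diagonal()) - LA
    WB = sparse.diags(LB.diagonal()) - LB
    nA, nB = meshA.n_vertices, meshB.n_vertices

    total_intra = 0.5 * (WA.sum() + WB.sum())
    w_link = link_fraction * total_intra / nA
    C = sparse.csr_matrix(
        (np.full(nA, w_link), (np.arange(nA), init)), shape=(nA, nB)
    )
    W = sparse.bmat([[WA, C], [C.T, WB]], format="csr")
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(deg) - W
    M = sparse.diags(np.concatenate([MA.diagonal(), MB.diagonal()]))

    n = nA + nB
    v0 = np.full(n, 1.0 / np.sqrt(n))
    scale = L.diagonal().mean() / M.diagonal().mean()
    vals, vecs = eigsh(L, k=k + 1, M=M, sigma=-1e-6 * scale, which="LM", v0=v0)
    order = np.argsort(vals)
    vals = vals[order]
    joint = vecs[:, order][:, 1:]
    joint = joint / np.sqrt(np.maximum(vals[1:], 1e-12))

    JA, JB = joint[:nA], joint[nA:]
    dist, nn = cKDTree(JB).query(JA)
    return Correspondence(map=nn, quality=dist)


def vertexwise_rate(
    fieldA: np.ndarray,
    fieldB: np.ndarray,
    corr: Correspondence,
    delta_weeks: float,
) -> np.ndarray:
    """Per-A-vertex weekly change (fieldB[corr(v)] − fieldA[v]) / Δweeks."""
    if delta_weeks <= 0:
        raise ValueError("delta_weeks must be positive")
    fieldA = np.asarray(fieldA, dtype=float)
    fieldB = np.asarray(fieldB, dtype=float)
    if len(fieldA) != len(corr.map):
        raise ValueError("fieldA length does not match correspondence")
    if corr.map.max(initial=-1) >= len(fieldB):
        raise ValueError("correspondence indexes beyond fieldB")
    return (fieldB[corr.map] - fieldA) / delta_weeks


def save_correspondence(corr: Correspondence, path) -> None:
    """Two-column integer CSV (vertex_a, vertex_b) plus the residual."""
    arr = np.column_stack([np.arange(len(corr.map)), corr.map])
    header = "vertex_a,vertex_b,residual"
    out = np.column_stack([arr, corr.quality])
    np.savetxt(path, out, fmt=("%d", "%d", "%.6g"), delimiter=",",
               header=header, comments="")
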