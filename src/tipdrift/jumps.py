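"""Mesoscopic diffusion jump coefficients from P1 finite elements.

The per-species voxel-to-voxel jump propensity coefficient is

    d_sij = D_s * max(0, -L_ij) / m_i

where L is the P1 stiffness matrix of the Laplacian assembled on the species'
compartment (volume tetrahedra for cytosolic species, boundary triangles for
membrane species) and m_i the lumped mass of voxel i (dual volume V_i or dual
area A_i).  Positive off-diagonal stiffness entries — produced by obtuse
elements on unstructured meshes — are clipped to zero, which simply reduces the
outflow on those edges; the clipped fraction of edge weight is reported and
meshes losing more than 5% are rejected.

Because the assembled stiffness matrix is exactly symmetric, the coefficients
satisfy the reciprocity m_i d_sij = m_j d_sji on every unclipped edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix

from .geometry import Mesh
from .model import SpeciesSpec

__all__ = ["JumpMatrix", "assemble_jump_matrix", "stiffness_volume", "stiffness_surface"]

_DEGENERATE_VOL = 1e-12  # relative volume below which an element is skipped


class MeshQualityError(ValueError):
    """Mesh is too distorted for a consistent mesoscopic discretization."""


def _symmetrize_assemble(rows, cols, vals, n) -> csr_matrix:
    m = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    # exact symmetry: average with transpose (entries are equal up to rounding)
    return (m + m.T) * 0.5


def stiffness_volume(mesh: Mesh) -> csr_matrix:
    """P1 stiffness matrix of the Laplacian on the tetrahedral volume mesh."""
    verts, tets = mesh.vertices, mesh.tetrahedra
    a, b, c, d = (verts[tets[:, k]] for k in range(4))
    vol = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
    keep = vol > _DEGENERATE_VOL * max(vol.max(), 1.0)
    tets, vol = tets[keep], vol[keep]
    a, b, c, d = (verts[tets[:, k]] for k in range(4))
    # gradients of barycentric basis functions: grad_k = n_k / (6 V) where n_k
    # is the inward-scaled normal of the face opposite vertex k
    g = np.empty((len(tets), 4, 3))
    g[:, 0] = np.cross(d - b, c - b)
    g[:, 1] = np.cross(c - a, d - a)
    g[:, 2] = np.cross(d - a, b - a)
    g[:, 3] = np.cross(b - a, c - a)
    g /= (6.0 * vol)[:, None, None]
    rows, cols, vals = [], [], []
    for i in range(4):
        for j in range(4):
            rows.append(tets[:, i])
            cols.append(tets[:, j])
            vals.append(np.einsum("ij,ij->i", g[:, i], g[:, j]) * vol)
    return _symmetrize_assemble(
        np.concatenate(rows), np.concatenate(cols), np.concatenate(vals), mesh.K
    )


def stiffness_surface(mesh: Mesh) -> csr_matrix:
    """P1 Laplace-Beltrami stiffness on the boundary triangulation (cotangent
    weights); rows/cols indexed by global vertex id, nonzero only on membrane."""
    verts, tris = mesh.vertices, mesh.boundary_triangles
    p = verts[tris]  # (B, 3, 3)
    rows, cols, vals = [], [], []
    idx = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    area2 = np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    keep = area2 > _DEGENERATE_VOL * max(area2.max(), 1.0)
    p, tris = p[keep], tris[keep]
    for k, i, j in idx:
        # cotangent of the angle at vertex k, opposite edge (i, j)
        u = p[:, i] - p[:, k]
        v = p[:, j] - p[:, k]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows += [tris[:, i], tris[:, j], tris[:, i], tris[:, j]]
        cols += [tris[:, j], tris[:, i], tris[:, i], tris[:, j]]
        vals += [-w, -w, w, w]
    return _symmetrize_assemble(
        np.concatenate(rows), np.concatenate(cols), np.concatenate(vals), mesh.K
    )


@dataclass
class JumpMatrix:
    """Per-species diffusion jump coefficients d_sij (one CSR matrix each).

    ``matrices[name][i, j]`` is the per-molecule jump propensity from voxel i
    to adjacent voxel j (1/s).  ``clipped_fraction[name]`` reports the edge
    weight removed by clipping positive off-diagonal stiffness entries.
    """

    matrices: dict  # species name -> csr_matrix (K x K)
    clipped_fraction: dict  # species name -> float

    def out_rates(self, name: str) -> np.ndarray:
        """Total per-molecule leave rate per voxel for one species."""
        return np.asarray(self.matrices[name].sum(axis=1)).ravel()


def _jump_from_stiffness(K_mat: csr_matrix, D: float, mass: np.ndarray):
    coo = K_mat.tocoo()
    off = coo.row != coo.col
    r, c, v = coo.row[off], coo.col[off], coo.data[off]
    neg = v < 0  # admissible (transport) entries
    total = np.abs(v).sum()
    clipped = v[~neg].sum()
    frac = float(clipped / total) if total > 0 else 0.0
    rr, cc, vv = r[neg], c[neg], -v[neg]
    with np.errstate(divide="ignore"):
        rates = D * vv / mass[rr]
    mat = coo_matrix((rates, (rr, cc)), shape=K_mat.shape).tocsr()
    return mat, frac


WARN_CLIPPED = 0.05  # clipped-weight level above which a quality warning fires


def assemble_jump_matrix(mesh: Mesh, species: list[SpeciesSpec],
                         max_clipped: float = 0.15) -> JumpMatrix:
    """Build jump coefficients for every species on ``mesh``.

    Cytosolic species hop on the tetrahedral adjacency with lumped mass V_i;
    membrane species hop on the boundary-edge adjacency with lumped mass A_i.

    A quality warning is emitted when more than 5% of the stiffness edge
    weight is clipped; meshes above ``max_clipped`` (default 15%, the level
    beyond which the mesoscopic diffusion error becomes material) are
    rejected.
    """
    K_vol = None
    K_surf = None
    matrices = {}
    clipped = {}
    for sp in species:
        if sp.compartment == "cytoplasm":
            D = sp.D_cyt
            if D == 0:
                matrices[sp.name] = csr_matrix((mesh.K, mesh.K))
                clipped[sp.name] = 0.0
                continue
            if K_vol is None:
                K_vol = stiffness_volume(mesh)
            mat, frac = _jump_from_stiffness(K_vol, D, mesh.voxel_volumes)
        else:
            D = sp.D_mem
            if D == 0:
                matrices[sp.name] = csr_matrix((mesh.K, mesh.K))
                clipped[sp.name] = 0.0
                continue
            if K_surf is None:
                K_surf = stiffness_surface(mesh)
            mass = np.where(mesh.voxel_areas > 0, mesh.voxel_areas, 1.0)
            mat, frac = _jump_from_stiffness(K_surf, D, mass)
        if frac > max_clipped:
            raise MeshQualityError(
                f"species {sp.name}: {100 * frac:.1f}% of the stiffness edge "
                f"weight was clipped (> {100 * max_clipped:.0f}%); refine the mesh"
            )
        if frac > WARN_CLIPPED:
            warnings.warn(
                f"species {sp.name}: {100 * frac:.1f}% of the stiffness edge "
                "weight clipped; mesoscopic diffusion will be slightly slowed",
                RuntimeWarning,
                stacklevel=2,
            )
        matrices[sp.name] = mat
        clipped[sp.name] = frac
    return JumpMatrix(matrices=matrices, clipped_fraction=clipped)
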