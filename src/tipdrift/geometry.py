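"""Parametric tip-shaped cell geometries and their tetrahedral meshes.

The shapes emulate a budding-yeast cell at successive stages of mating-projection
growth: a sphere, a slightly deformed sphere, and spheres carrying a tube-like
projection of increasing length.  Each geometry is axisymmetric about the x-axis
with the projection apex on the -x side, is described by a smooth implicit
surface (smooth union of a ball and a spherocylinder), and is meshed into a
vertex-centred dual-cell ("voxel") discretization: molecule counts live on mesh
vertices, cytosolic species occupy the dual volume V_i of every vertex and
membrane species the dual boundary area A_i of surface vertices.

All lengths are micrometres.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "GeometrySpec",
    "Mesh",
    "TipFrame",
    "build_sphere",
    "build_projection",
    "build_geometry",
    "canonical_specs",
    "compute_dual_volumes",
    "surface_geodesic_distances",
]

# Azimuthal point counts are forced to multiples of this, so every generated
# mesh has an exact discrete rotational symmetry about the x-axis.
SYMMETRY_ORDER = 4


class MeshingError(ValueError):
    """Raised when a geometry specification cannot be meshed."""


@dataclass(frozen=True)
class GeometrySpec:
    """Parametric description of a cell shape.

    family: 'sphere', 'slight_deform' or 'projection'.
    body_radius: radius of the spherical cell body.
    projection_length: how far the projection apex extends beyond the body
        surface along -x (0 for a sphere).
    projection_radius: radius of the projection tube.
    neck_smoothing: smoothing length of the body/tube junction.
    target_edge_length: requested mesh edge length.
    """

    family: str = "sphere"
    body_radius: float = 2.0
    projection_length: float = 0.0
    projection_radius: float = 0.0
    neck_smoothing: float = 0.25
    target_edge_length: float = 0.4

    def __post_init__(self) -> None:
        if self.family not in ("sphere", "slight_deform", "projection"):
            raise ValueError(f"unknown geometry family {self.family!r}")
        if self.body_radius <= 0:
            raise ValueError("body_radius must be positive")
        if self.projection_length < 0:
            raise ValueError("projection_length must be >= 0")
        if self.projection_length > 0 and not (
            0 < self.projection_radius < self.body_radius
        ):
            raise ValueError(
                "need 0 < projection_radius < body_radius when projection_length > 0; "
                f"got projection_radius={self.projection_radius}, "
                f"body_radius={self.body_radius}"
            )
        if not self.target_edge_length < self.body_radius / 2:
            raise MeshingError(
                f"target_edge_length={self.target_edge_length} must be smaller than "
                f"body_radius/2={self.body_radius / 2}"
            )

    def content_hash(self) -> str:
        key = (
            f"{self.family}|{self.body_radius:.12g}|{self.projection_length:.12g}|"
            f"{self.projection_radius:.12g}|{self.neck_smoothing:.12g}|"
            f"{self.target_edge_length:.12g}"
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


def canonical_specs(
    body_radius: float = 2.0, target_edge_length: float = 0.4
) -> dict[str, GeometrySpec]:
    """The four study shapes plus the long projection.

    Dimensions are this package's choices (the qualitative shape classes and the
    <=15% volume-deviation constraint are the binding requirements); see
    docs/methods.md.
    """
    r = body_radius
    h = target_edge_length
    return {
        "sphere": GeometrySpec("sphere", r, 0.0, 0.0, 0.25, h),
        "slight_deform": GeometrySpec("slight_deform", r, 0.4 * r, 0.275 * r, 0.175 * r, h),
        "projection1": GeometrySpec("projection", r, 0.65 * r, 0.3 * r, 0.15 * r, h),
        "projection2": GeometrySpec("projection", r, 1.5 * r, 0.25 * r, 0.15 * r, h),
        "long_projection": GeometrySpec("projection", r, 2.25 * r, 0.25 * r, 0.15 * r, h),
    }


@dataclass(frozen=True)
class TipFrame:
    """Coordinate frame for cap tracking.

    ``origin`` sits on the symmetry (x) axis; ``direction`` is the unit vector
    from the origin towards the projection apex (-x), so a cap centred exactly
    at the tip evaluates to (theta, phi) = (90 deg, 180 deg).
    """

    origin: np.ndarray
    direction: np.ndarray
    tip_vertex: int

    def angles_of(self, point: np.ndarray) -> tuple[float, float]:
        """Spherical angles (degrees) of ``point`` seen from the frame origin.

        theta is measured from the z-axis (0..180); phi is the angle of the
        xy-plane projection measured from +x (0..360).
        """
        v = np.asarray(point, dtype=float) - self.origin
        r = np.linalg.norm(v)
        if r == 0:
            raise ValueError("point coincides with the frame origin")
        theta = math.degrees(math.acos(np.clip(v[2] / r, -1.0, 1.0)))
        phi = math.degrees(math.atan2(v[1], v[0])) % 360.0
        return theta, phi


@dataclass
class Mesh:
    """Tetrahedral volume mesh with triangulated boundary and dual voxels."""

    vertices: np.ndarray          # (K, 3) float
    tetrahedra: np.ndarray        # (T, 4) int
    boundary_triangles: np.ndarray  # (B, 3) int
    voxel_volumes: np.ndarray = field(default=None)  # V_i, (K,)
    voxel_areas: np.ndarray = field(default=None)    # A_i, (K,); 0 off-membrane
    on_membrane: np.ndarray = field(default=None)    # (K,) bool
    provenance: Optional[GeometrySpec] = None
    symmetry_order: int = 1

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.tetrahedra = np.ascontiguousarray(self.tetrahedra, dtype=np.int64)
        self.boundary_triangles = np.ascontiguousarray(
            self.boundary_triangles, dtype=np.int64
        )
        if self.voxel_volumes is None:
            v, a = compute_dual_volumes(self)
            self.voxel_volumes, self.voxel_areas = v, a
        if self.on_membrane is None:
            flag = np.zeros(len(self.vertices), dtype=bool)
            flag[np.unique(self.boundary_triangles)] = True
            self.on_membrane = flag

    @property
    def K(self) -> int:
        return len(self.vertices)

    @property
    def volume(self) -> float:
        return float(self.voxel_volumes.sum())

    @property
    def area(self) -> float:
        return float(self.voxel_areas.sum())

    @property
    def membrane_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.on_membrane)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.tetrahedra).tobytes())
        h.update(np.ascontiguousarray(self.boundary_triangles).tobytes())
        return h.hexdigest()[:16]

    def tip_frame(self) -> TipFrame:
        """Frame with origin at the volume centroid projected on the x-axis."""
        tets = self.tetrahedra
        verts = self.vertices
        a, b, c, d = (verts[tets[:, k]] for k in range(4))
        vol = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
        centroid = ((a + b + c + d) / 4 * np.abs(vol)[:, None]).sum(0) / np.abs(vol).sum()
        origin = np.array([centroid[0], 0.0, 0.0])
        membrane = self.membrane_vertices
        tip_vertex = int(membrane[np.argmin(verts[membrane, 0])])
        return TipFrame(origin=origin, direction=np.array([-1.0, 0.0, 0.0]),
                        tip_vertex=tip_vertex)


# ---------------------------------------------------------------------------
# Implicit surface
# ---------------------------------------------------------------------------

def _implicit(spec: GeometrySpec, pts: np.ndarray) -> np.ndarray:
    """Signed distance-like field; negative inside the cell.

    Smooth union (log-sum-exp blend with length scale ``neck_smoothing``) of the
    body sphere and a spherocylinder along -x whose apex lies at
    x = -(body_radius + projection_length).
    """
    pts = np.atleast_2d(pts)
    r = np.linalg.norm(pts, axis=1)
    d_sphere = r - spec.body_radius
    if spec.projection_length <= 0:
        return d_sphere
    a = spec.projection_radius
    seg_end = spec.body_radius + spec.projection_length - a  # segment [-seg_end, 0]
    x = np.clip(pts[:, 0], -seg_end, 0.0)
    closest = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    d_caps = np.linalg.norm(pts - closest, axis=1) - a
    k = spec.neck_smoothing
    if k <= 0:
        return np.minimum(d_sphere, d_caps)
    # numerically stable smooth-min
    m = np.minimum(d_sphere, d_caps)
    return m - k * np.log(
        np.exp(-(d_sphere - m) / k) + np.exp(-(d_caps - m) / k)
    )


def _axis_extent(spec: GeometrySpec, level: float = 0.0) -> tuple[float, float]:
    """x-extent [x_lo, x_hi] of the level set {f = level} along the axis."""
    f = lambda x: _implicit(spec, np.array([[x, 0.0, 0.0]]))[0] - level
    lo_bracket = -(spec.body_radius + spec.projection_length + 1.0)
    x_lo = _bisect(f, lo_bracket, 0.0)
    x_hi = _bisect(lambda x: f(-x), -(spec.body_radius + 1.0), 0.0)
    return x_lo, -x_hi


def _bisect(f, a, b, tol=1e-12, maxit=200):
    fa, fb = f(a), f(b)
    if fa == 0:
        return a
    if fb == 0:
        return b
    if fa * fb > 0:
        raise MeshingError("bisection bracket failure in geometry construction")
    for _ in range(maxit):
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0 or (b - a) < tol:
            return m
        if fa * fm < 0:
            b, fb = m, fm
        else:
            a, fa = m, fm
    return 0.5 * (a + b)


def _profile(spec: GeometrySpec, level: float, n: int = 1200):
    """Radial profile rho(x) of the level set {f = level}, or None if empty."""
    on_axis = _implicit(spec, np.array([[0.0, 0.0, 0.0]]))[0]
    if on_axis >= level:
        return None
    x_lo, x_hi = _axis_extent(spec, level)
    xs = np.linspace(x_lo, x_hi, n)
    rho_max = spec.body_radius + spec.neck_smoothing + 1.0
    # vectorized bisection for rho(x) on all stations at once
    lo = np.zeros(n)
    hi = np.full(n, rho_max)
    zeros = np.zeros(n)
    f_axis = _implicit(spec, np.column_stack([xs, zeros, zeros])) - level
    solvable = f_axis < 0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = _implicit(spec, np.column_stack([xs, mid, zeros])) - level
        take_hi = fm < 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    rhos = np.where(solvable, 0.5 * (lo + hi), 0.0)
    rhos[0] = rhos[-1] = 0.0
    return xs, rhos


# ---------------------------------------------------------------------------
# Point placement and meshing
# ---------------------------------------------------------------------------

def _ring_points(x: float, rho: float, h: float, offset: float = 0.0) -> np.ndarray:
    """Points on a circle of radius rho at axial station x, count a multiple of
    SYMMETRY_ORDER so the discrete rotational symmetry is exact.  ``offset``
    staggers the start angle (any value preserves the 4-fold symmetry)."""
    m = SYMMETRY_ORDER
    n = m * max(1, int(round(2 * math.pi * rho / (m * h))))
    ang = 2 * math.pi * np.arange(n) / n + offset
    return np.column_stack([np.full(n, x), rho * np.cos(ang), rho * np.sin(ang)])



def _surface_and_shell(spec: GeometrySpec, h: float, level: float = 0.0,
                       layer_index: int = 0):
    """Ring points on the level set plus a congruent inward boundary layer.

    The shell repeats each surface ring (same count, same start angle) offset
    by h along the inward profile normal, so the band under the membrane
    triangulates into well-shaped prism-like elements.  Shell rings that
    collapse towards the axis (inside the projection tube) degrade to single
    axis points.
    """
    prof = _profile(spec, level)
    if prof is None:
        return np.empty((0, 3)), np.empty((0, 3))
    xs, rhos = prof
    seg = np.hypot(np.diff(xs), np.diff(rhos))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.array([[xs[0], 0.0, 0.0]]), np.empty((0, 3))
    n_st = max(2, int(round(total / h)) + 1)
    stations = np.linspace(0.0, total, n_st)
    surf_pts = [np.array([[xs[0], 0.0, 0.0]])]
    shell_pts = []
    shell_axis = []
    for k, sv in enumerate(stations[1:-1]):
        x = np.interp(sv, s, xs)
        rho = np.interp(sv, s, rhos)
        if rho < 0.35 * h:
            continue
        # stagger start angles between neighbouring stations and layers to
        # avoid aligned (degenerate, obtuse) tetrahedra
        offset = 0.5 * h / rho * ((k % 2) + 0.5 * (layer_index % 2))
        surf_pts.append(_ring_points(x, rho, h, offset))
        # profile tangent -> inward normal in the (x, rho) half-plane
        ds = max(1e-6, 0.01 * h)
        x2 = np.interp(sv + ds, s, xs)
        r2 = np.interp(sv + ds, s, rhos)
        tx, tr = (x2 - x) / ds, (r2 - rho) / ds
        nx, nr = tr, -tx  # candidate normal
        probe = np.array([[x + 0.1 * h * nx, (rho + 0.1 * h * nr), 0.0]])
        if _implicit(spec, probe)[0] - level > 0:  # pointing outward: flip
            nx, nr = -nx, -nr
        xs_in, rho_in = x + h * nx, rho + h * nr
        if rho_in < 0.3 * h:
            shell_axis.append(xs_in)
        else:
            shell_pts.append(_ring_points(xs_in, rho_in, h, offset))
    # apexes and their inward copies
    surf_pts.append(np.array([[xs[-1], 0.0, 0.0]]))
    shell_axis = [xs[0] + h] + shell_axis + [xs[-1] - h]
    axis_sorted = np.sort(np.asarray(shell_axis))
    keep_axis = [axis_sorted[0]]
    for val in axis_sorted[1:]:
        if val - keep_axis[-1] > 0.6 * h:
            keep_axis.append(val)
    ax = np.asarray(keep_axis)
    interior_ax = np.column_stack([ax, 0 * ax, 0 * ax])
    interior_ax = interior_ax[_implicit(spec, interior_ax) - level < -0.5 * h]
    shell = [p for p in shell_pts]
    shell.append(interior_ax)
    surface = np.vstack(surf_pts)
    shell_arr = np.vstack(shell) if shell else np.empty((0, 3))
    # drop shell points that drifted too close to the surface (concave necks)
    if len(shell_arr):
        shell_arr = shell_arr[_implicit(spec, shell_arr) - level < -0.55 * h]
    return surface, shell_arr


def _interior_points(spec: GeometrySpec, h: float) -> np.ndarray:
    """Interior vertices on a body-centred-cubic lattice.

    BCC point sets tetrahedralize into near-regular elements, which keeps the
    number of obtuse (clipped) stiffness edges low.  The lattice is centred so
    a rotation by 90 degrees about the x-axis maps it onto itself, preserving
    the mesh's discrete rotational symmetry.  Points closer than ~0.6 h to the
    surface are dropped to leave a clean transition band to the surface rings.
    """
    a = 1.05 * h  # cubic lattice constant; BCC edge lengths a and a*sqrt(3)/2
    x_lo, x_hi = _axis_extent(spec, 0.0)
    rmax = spec.body_radius + spec.neck_smoothing
    nx = np.arange(math.floor(x_lo / a), math.ceil(x_hi / a) + 1)
    ny = np.arange(math.floor(-rmax / a), math.ceil(rmax / a) + 1)
    gx, gy, gz = np.meshgrid(nx * a, ny * a, ny * a, indexing="ij")
    corners = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    centers = corners + 0.5 * a
    pts = np.vstack([corners, centers])
    vals = _implicit(spec, pts)
    return pts[vals < -1.55 * h]


def _dedupe(points: np.ndarray, tol: float) -> np.ndarray:
    """Merge clusters of nearly coincident points into their centroids.

    Cluster-centroid merging (rather than keep-first) is equivariant under
    the mesh's rotational symmetry, so symmetric point sets stay symmetric.
    """
    tree = cKDTree(points)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    if len(pairs) == 0:
        return points
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(len(points))])
    out = []
    for r in np.unique(roots):
        out.append(points[roots == r].mean(axis=0))
    return np.array(out)


def _rot90x(pts: np.ndarray) -> np.ndarray:
    """Exact (float-lossless) rotation by 90 degrees about the x-axis."""
    out = pts.copy()
    out[:, 1] = -pts[:, 2]
    out[:, 2] = pts[:, 1]
    return out


def _symmetrize(points: np.ndarray) -> np.ndarray:
    """Project the point set onto exact 4-fold symmetry about the x-axis.

    Orbits are identified by nearest-neighbour matching under a 90-degree
    rotation; each orbit is replaced by rotated copies of its averaged
    representative.  Because the 90-degree rotation is exact in floating
    point, the result is bitwise invariant under it.
    """
    tree = cKDTree(points)
    _, sigma = tree.query(_rot90x(points))
    out = points.copy()
    done = np.zeros(len(points), dtype=bool)

    def rotk(p, k):
        q = p[None, :]
        for _ in range(k % 4):
            q = _rot90x(q)
        return q[0]

    for i in range(len(points)):
        if done[i]:
            continue
        cycle = [i]
        j = sigma[i]
        while j != i and len(cycle) < 5:
            cycle.append(j)
            j = int(sigma[j])
        if j != i or done[cycle].any():
            done[i] = True
            continue
        if len(cycle) == 1:  # on-axis point
            out[i] = np.array([points[i, 0], 0.0, 0.0])
        elif len(cycle) == 4:
            # rotate each member back to the representative's frame, average,
            # regenerate the orbit with the exact rotation
            rep = np.mean([rotk(points[idx], 4 - k) for k, idx in enumerate(cycle)],
                          axis=0)
            for k, idx in enumerate(cycle):
                out[idx] = rotk(rep, k)
        done[cycle] = True
    return out



def _smooth_points(spec: GeometrySpec, points: np.ndarray, n_surface: int,
                   h: float, n_iter: int = 15) -> np.ndarray:
    """ODT (optimal-Delaunay) smoothing of surface and interior vertices.

    Interior vertices move to the volume-weighted average of the circumcenters
    of their incident *interior* tetrahedra (tets whose centroid lies outside
    the surface are excluded, which matters at the concave neck).  Surface
    vertices move to the area-weighted average of the circumcenters of their
    incident boundary triangles and are Newton-projected back onto the
    surface; the two apex vertices are pinned.  A final symmetrization
    restores the exact discrete rotational symmetry about the x-axis.
    """
    pts = points.astype(float).copy()
    n = len(pts)
    surf = np.arange(n_surface)
    rad0 = np.hypot(pts[surf, 1], pts[surf, 2])
    apex = surf[rad0 < 1e-9]
    for _ in range(n_iter):
        tri = Delaunay(pts)
        tets = tri.simplices
        cent = pts[tets].mean(axis=1)
        tets = tets[_implicit(spec, cent) < 0.0]
        a, b, c, d = (pts[tets[:, k]] for k in range(4))
        vol = np.abs(np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)) / 6.0
        cc = _circumcenters(a, b, c, d)
        # clamp runaway circumcenters of near-degenerate tets to the centroid
        centroid = (a + b + c + d) / 4.0
        far = np.linalg.norm(cc - centroid, axis=1) > 2.0 * h
        cc[far] = centroid[far]
        wsum = np.zeros(n)
        acc = np.zeros((n, 3))
        for k in range(4):
            np.add.at(wsum, tets[:, k], vol)
            np.add.at(acc, tets[:, k], cc * vol[:, None])
        new = pts.copy()
        free = np.arange(n_surface, n)
        ok = wsum[free] > 0
        new[free[ok]] = acc[free[ok]] / wsum[free[ok], None]
        # keep interior vertices clear of the surface
        vals = _implicit(spec, new[free])
        bad = vals > -0.45 * h
        new[free[bad]] = pts[free[bad]]
        # re-symmetrize every iteration: Delaunay tie-breaking on degenerate
        # configurations is not equivariant, and letting the asymmetry grow
        # would defeat the final orbit matching
        pts = _symmetrize(new)
    return pts


def _tet_quality(pts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Shape quality in (0, 1]: volume over longest-edge cubed, 1 = regular."""
    a, b, c, d = (pts[tets[:, k]] for k in range(4))
    vol = np.abs(np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)) / 6.0
    lmax = np.zeros(len(tets))
    for i in range(4):
        for j in range(i + 1, 4):
            lmax = np.maximum(
                lmax, np.linalg.norm(pts[tets[:, i]] - pts[tets[:, j]], axis=1)
            )
    return vol / np.maximum(lmax, 1e-300) ** 3 / 0.11785  # regular-tet norm


def _refine_bad_tets(spec: GeometrySpec, points: np.ndarray, h: float,
                     rounds: int = 4, qmin: float = 0.15) -> np.ndarray:
    """Delaunay refinement: insert circumcenters of badly shaped interior tets.

    The classic sliver remedy; insertions stay clear of the surface so the
    boundary triangulation is untouched.  Inserted points inherit the mesh's
    rotational symmetry (bad tets come in symmetric orbits)."""
    pts = points
    for _ in range(rounds):
        tri = Delaunay(pts)
        tets = tri.simplices
        cent = pts[tets].mean(axis=1)
        tets = tets[_implicit(spec, cent) < 0.0]
        q = _tet_quality(pts, tets)
        bad = tets[q < qmin]
        if len(bad) == 0:
            break
        a, b, c, d = (pts[bad[:, k]] for k in range(4))
        cand = _circumcenters(a, b, c, d)
        centroid = (a + b + c + d) / 4.0
        off = np.linalg.norm(cand - centroid, axis=1) > h
        cand[off] = centroid[off]
        # keep insertions interior and mutually separated
        cand = cand[_implicit(spec, cand) < -0.5 * h]
        if len(cand) == 0:
            break
        cand = _dedupe(cand, 0.45 * h)
        dmin, _ = cKDTree(pts).query(cand)
        cand = cand[dmin > 0.45 * h]
        if len(cand) == 0:
            break
        pts = _symmetrize(np.vstack([pts, cand]))
    return pts




def _circumcenters(a, b, c, d):
    """Circumcenters of tetrahedra given their four vertex arrays."""
    ba, ca, da = b - a, c - a, d - a
    cross_cd = np.cross(ca, da)
    cross_db = np.cross(da, ba)
    cross_bc = np.cross(ba, ca)
    denom = 2.0 * np.einsum("ij,ij->i", ba, cross_cd)
    denom = np.where(np.abs(denom) < 1e-300, 1e-300, denom)
    num = (
        np.einsum("ij,ij->i", ba, ba)[:, None] * cross_cd
        + np.einsum("ij,ij->i", ca, ca)[:, None] * cross_db
        + np.einsum("ij,ij->i", da, da)[:, None] * cross_bc
    )
    return a + num / denom[:, None]


_MESH_CACHE: dict[str, tuple["Mesh", "TipFrame"]] = {}


def _build_from_spec(spec: GeometrySpec) -> tuple[Mesh, TipFrame]:
    cached = _MESH_CACHE.get(spec.content_hash())
    if cached is not None:
        return cached
    h = spec.target_edge_length
    surface, shell = _surface_and_shell(spec, h)
    surface = _dedupe(surface, 0.3 * h)
    bcc = _interior_points(spec, h)
    if len(bcc) and len(shell):
        d, _ = cKDTree(shell).query(bcc)
        bcc = bcc[d > 0.55 * h]
    interior = np.vstack([shell, bcc]) if len(bcc) else shell
    if len(interior):
        d, _ = cKDTree(surface).query(interior)
        interior = _dedupe(interior[d > 0.45 * h], 0.3 * h)
    n_surf = len(surface)
    points = np.vstack([surface, interior]) if len(interior) else surface
    if len(points) < 10:
        raise MeshingError("too few mesh points; refine target_edge_length")
    points = _smooth_points(spec, points, n_surface=n_surf, h=h)
    points = _refine_bad_tets(spec, points, h=h)
    points = np.round(points, 12)  # deterministic, hash-stable coordinates

    tri = Delaunay(points)
    tets = tri.simplices
    cent = points[tets].mean(axis=1)
    # keep tets whose centroid is inside; zero-volume slivers (from cospherical
    # structured points) are retained so the boundary stays watertight -- they
    # carry no volume and are skipped by the FEM assembly
    tets = tets[_implicit(spec, cent) < 0.0]
    if len(tets) == 0:
        raise MeshingError("meshing produced no interior tetrahedra")
    tets = _orient_tets(points, tets)
    tets, points, old2new = _compact(points, tets)
    tris = _boundary_faces(tets)
    mesh = Mesh(
        vertices=points,
        tetrahedra=tets,
        boundary_triangles=tris,
        provenance=spec,
        symmetry_order=SYMMETRY_ORDER,
    )
    frame = mesh.tip_frame()
    _MESH_CACHE[spec.content_hash()] = (mesh, frame)
    return mesh, frame


def _orient_tets(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (points[tets[:, k]] for k in range(4))
    vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)
    flip = vol6 < 0
    tets = tets.copy()
    tets[flip, 2], tets[flip, 3] = tets[flip, 3], tets[flip, 2].copy()
    return tets


def _compact(points, tets):
    used = np.unique(tets)
    old2new = -np.ones(len(points), dtype=np.int64)
    old2new[used] = np.arange(len(used))
    return old2new[tets], points[used], old2new


def _boundary_faces(tets: np.ndarray) -> np.ndarray:
    faces = np.vstack([
        tets[:, [0, 1, 2]],
        tets[:, [0, 1, 3]],
        tets[:, [0, 2, 3]],
        tets[:, [1, 2, 3]],
    ])
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def build_sphere(spec: GeometrySpec) -> Mesh:
    """Tetrahedralized ball centred at the origin."""
    if spec.family != "sphere":
        raise ValueError("build_sphere requires family='sphere'")
    mesh, _ = _build_from_spec(spec)
    return mesh


def build_projection(spec: GeometrySpec) -> tuple[Mesh, TipFrame]:
    """Body-plus-capped-tube geometry; returns the mesh and its tip frame."""
    if spec.family not in ("slight_deform", "projection"):
        raise ValueError("build_projection requires a deformed family")
    return _build_from_spec(spec)


def build_geometry(spec: GeometrySpec) -> tuple[Mesh, TipFrame]:
    """Build any family; always returns (mesh, tip_frame)."""
    mesh, frame = _build_from_spec(spec)
    return mesh, frame


# ---------------------------------------------------------------------------
# Dual voxels and surface distances
# ---------------------------------------------------------------------------

def compute_dual_volumes(mesh: "Mesh") -> tuple[np.ndarray, np.ndarray]:
    """Barycentric dual volumes V_i and boundary areas A_i.

    Each tetrahedron contributes a quarter of its volume to each of its four
    vertices, each boundary triangle a third of its area to each of its three
    vertices, so the sums partition the total volume/area exactly.
    """
    verts, tets, tris = mesh.vertices, mesh.tetrahedra, mesh.boundary_triangles
    a, b, c, d = (verts[tets[:, k]] for k in range(4))
    vol = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0
    scale = float(np.abs(vol).max())
    bad = np.flatnonzero(vol < -1e-12 * scale)
    if len(bad):
        raise MeshingError(f"inverted tetrahedra at indices {bad[:10].tolist()}")
    vol = np.maximum(vol, 0.0)
    V = np.zeros(len(verts))
    for k in range(4):
        np.add.at(V, tets[:, k], vol / 4.0)
    A = np.zeros(len(verts))
    if len(tris):
        p, q, r = (verts[tris[:, k]] for k in range(3))
        area = 0.5 * np.linalg.norm(np.cross(q - p, r - p), axis=1)
        for k in range(3):
            np.add.at(A, tris[:, k], area / 3.0)
    return V, A


def surface_edge_graph(mesh: Mesh) -> csr_matrix:
    """Sparse symmetric graph of boundary edges weighted by Euclidean length."""
    tris = mesh.boundary_triangles
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    K = mesh.K
    g = csr_matrix((np.concatenate([w, w]),
                    (np.concatenate([e[:, 0], e[:, 1]]),
                     np.concatenate([e[:, 1], e[:, 0]]))), shape=(K, K))
    return g


_GEODESIC_CACHE: dict[tuple, np.ndarray] = {}


def surface_geodesic_distances(mesh: Mesh, source_vertex: int) -> np.ndarray:
    """Shortest-path distance along boundary edges from ``source_vertex``.

    Entries for non-membrane vertices are +inf; an unreachable membrane vertex
    (disconnected surface component) also reports +inf.  Results are cached
    per (mesh, source).
    """
    if not mesh.on_membrane[source_vertex]:
        raise ValueError(f"source vertex {source_vertex} is not on the membrane")
    key = (mesh.content_hash(), int(source_vertex))
    hit = _GEODESIC_CACHE.get(key)
    if hit is not None:
        return hit
    g = surface_edge_graph(mesh)
    dist = dijkstra(g, directed=False, indices=source_vertex)
    dist[~mesh.on_membrane] = np.inf
    if len(_GEODESIC_CACHE) > 64:
        _GEODESIC_CACHE.clear()
    _GEODESIC_CACHE[key] = dist
    return dist
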