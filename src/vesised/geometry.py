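"""Discrete differential geometry on triangle meshes (Meyer-style operators).

Per-vertex mixed (Voronoi) areas, mean and Gaussian curvature, the cotangent
Laplace-Beltrami operator, and global quantities (area, enclosed volume,
reduced volume, volume centroid).

Conventions
-----------
Normals point outward and the unit sphere has mean curvature H = +1
(H = (c1 + c2) / 2). The sign of H at a vertex follows the direction of the
discrete mean-curvature normal relative to the outward surface normal, so
locally concave patches carry H < 0. Curvature carries units 1/a, the
Laplace-Beltrami of a field f carries units [f]/a^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh

__all__ = [
    "GeometryCache", "mixed_areas", "curvatures", "laplace_beltrami",
    "enclosed_volume_area", "volume_centroid", "compute_geometry",
    "cotangent_weights",
]

# below this squared-magnitude the mean-curvature normal direction is
# considered degenerate (umbilic flat point) and face normals take over
_MCN_EPS = 1e-12


def _face_angles_cots(mesh: TriMesh):
    """Per-face corner angles and cotangents.

    Returns (angles, cots) with shape (F, 3), entry c being the angle at
    ``faces[:, c]``. Raises on degenerate (zero-area) faces.
    """
    x = mesh.vertices[mesh.faces]
    # edge vectors opposite each corner: e_c = x_{c+2} - x_{c+1}
    e = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]],
                 axis=1)
    l2 = np.einsum("fci,fci->fc", e, e)
    if np.any(l2 <= 0):
        bad = int(np.argwhere(l2.min(axis=1) <= 0)[0, 0])
        raise ValueError(f"degenerate face {bad} (zero-length edge)")
    # at corner c the adjacent edge vectors are -e_{c+1} and e_{c+2}
    u = -np.roll(e, -1, axis=1)
    v = np.roll(e, -2, axis=1)
    dots = np.einsum("fci,fci->fc", u, v)
    crosses = np.linalg.norm(np.cross(u, v), axis=2)
    if np.any(crosses <= 0):
        bad = int(np.argwhere(crosses.min(axis=1) <= 0)[0, 0])
        raise ValueError(f"degenerate face {bad} (zero area)")
    angles = np.arctan2(crosses, dots)
    cots = dots / crosses
    return angles, cots


def _mixed_areas_from(mesh, angles, cots, areas, l2):
    contrib = np.empty_like(l2)
    # Voronoi piece at corner c: (l2_{c+1} cot_{c+1} + l2_{c+2} cot_{c+2})/8
    for c in range(3):
        contrib[:, c] = (l2[:, (c + 1) % 3] * cots[:, (c + 1) % 3]
                         + l2[:, (c + 2) % 3] * cots[:, (c + 2) % 3]) / 8.0
    obtuse_corner = np.argmax(angles, axis=1)
    is_obtuse = angles.max(axis=1) > np.pi / 2
    if np.any(is_obtuse):
        rows = np.nonzero(is_obtuse)[0]
        contrib[rows] = areas[rows, None] / 4.0
        contrib[rows, obtuse_corner[rows]] = areas[rows] / 2.0

    A = np.zeros(mesh.n_vertices)
    np.add.at(A, mesh.faces.ravel(), contrib.ravel())
    return A


def mixed_areas(mesh: TriMesh):
    """Meyer 'mixed' Voronoi areas per vertex.

    For non-obtuse triangles each corner receives its circumcenter-bounded
    Voronoi piece, (|e_b|^2 cot(beta) + |e_c|^2 cot(gamma)) / 8 with the
    cotangents taken at the two opposite corners. An obtuse triangle instead
    contributes half its area at the obtuse corner and a quarter at the two
    others, which keeps every vertex area positive and the partition of the
    total area exact.
    """
    return _CotOperator(mesh).A


def cotangent_weights(mesh: TriMesh):
    """Summed cotangent weight (cot alpha_ij + cot beta_ij) per undirected edge.

    Returns (edges, w) where ``edges`` is ``mesh.edges`` and ``w[k]`` is the
    sum of the cotangents of the two angles facing edge k.
    """
    _, cots = _face_angles_cots(mesh)
    # edge opposite corner c in face f carries the cotangent at that corner
    w = np.zeros(mesh.n_edges)
    np.add.at(w, mesh.face_edge_index.ravel(), cots.ravel())
    return mesh.edges, w


class _CotOperator:
    """Shared per-configuration face quantities and the cotangent operator.

    Computes corner angles, cotangents, face normals/areas, mixed areas and
    edge weights once per mesh configuration; every geometric operator then
    reuses them.
    """

    def __init__(self, mesh: TriMesh):
        self.mesh = mesh
        x = mesh.vertices[mesh.faces]
        e = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2],
                      x[:, 1] - x[:, 0]], axis=1)
        l2 = np.einsum("fci,fci->fc", e, e)
        if np.any(l2 <= 0):
            bad = int(np.argwhere(l2.min(axis=1) <= 0)[0, 0])
            raise ValueError(f"degenerate face {bad} (zero-length edge)")
        u = -np.roll(e, -1, axis=1)
        v = np.roll(e, -2, axis=1)
        dots = np.einsum("fci,fci->fc", u, v)
        cr = np.cross(u, v)
        crn = np.sqrt(np.einsum("fci,fci->fc", cr, cr))
        if np.any(crn <= 0):
            bad = int(np.argwhere(crn.min(axis=1) <= 0)[0, 0])
            raise ValueError(f"degenerate face {bad} (zero area)")
        self.angles = np.arctan2(crn, dots)
        self.cots = dots / crn
        # cross(u, v) at corner 0 is -(e1 x e2) = -2 A n_out, so flip sign
        # to recover the outward face normal
        self.face_normal = -cr[:, 0] / crn[:, 0][:, None]
        self.face_area = 0.5 * crn[:, 0]

        # edge cotangent weights and mixed areas
        w = np.zeros(mesh.n_edges)
        np.add.at(w, mesh.face_edge_index.ravel(), self.cots.ravel())
        self.i = mesh.edges[:, 0]
        self.j = mesh.edges[:, 1]
        self.w = w
        self.A = _mixed_areas_from(mesh, self.angles, self.cots,
                                   self.face_area, l2)

    def apply(self, field):
        """(1 / 2A_i) * sum_j (cot a_ij + cot b_ij) (f_j - f_i)."""
        field = np.asarray(field, dtype=float)
        out = np.zeros_like(field)
        diff_ij = field[self.j] - field[self.i]
        if field.ndim == 1:
            np.add.at(out, self.i, self.w * diff_ij)
            np.add.at(out, self.j, -self.w * diff_ij)
            return out / (2.0 * self.A)
        np.add.at(out, self.i, self.w[:, None] * diff_ij)
        np.add.at(out, self.j, -self.w[:, None] * diff_ij)
        return out / (2.0 * self.A[:, None])


def laplace_beltrami(mesh: TriMesh, field, _op: _CotOperator | None = None):
    """Cotangent-weighted discrete Laplace-Beltrami of a per-vertex field.

    Normalised by the mixed area; a constant field maps to zero exactly and
    the spherical harmonic Y_l on the unit sphere maps approximately to
    -l(l+1) Y_l.
    """
    field = np.asarray(field, dtype=float)
    if field.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"got {field.shape[0]} values for {mesh.n_vertices} vertices")
    op = _op if _op is not None else _CotOperator(mesh)
    return op.apply(field)


def _face_normal_vertex_average(mesh: TriMesh, _op: _CotOperator | None = None):
    if _op is None:
        fn, fa = mesh.face_normals_areas()
    else:
        fn, fa = _op.face_normal, _op.face_area
    n = np.zeros((mesh.n_vertices, 3))
    np.add.at(n, mesh.faces.ravel(), np.repeat(fn * fa[:, None], 3, axis=0))
    n /= np.linalg.norm(n, axis=1)[:, None]
    return n


def curvatures(mesh: TriMesh, _op: _CotOperator | None = None):
    """Per-vertex mean curvature H, Gaussian curvature K and unit normal.

    K is the angle deficit over the mixed area. The mean-curvature normal is
    the cotangent sum over the one-ring divided by twice the mixed area; its
    magnitude is 2|H| and its direction fixes the sign of H relative to the
    outward normal. Where the mean-curvature normal is degenerate (flat or
    umbilic-flat vertices) the area-weighted face-normal average is used for
    the vertex normal instead.
    """
    op = _op if _op is not None else _CotOperator(mesh)
    A = op.A

    deficit = np.full(mesh.n_vertices, 2.0 * np.pi)
    np.add.at(deficit, mesh.faces.ravel(), -op.angles.ravel())
    K = deficit / A

    # mean-curvature normal: -Lap(x) = (1/2A) sum w_ij (x_i - x_j) = 2 H n
    mcn = -op.apply(mesh.vertices)
    mag = np.linalg.norm(mcn, axis=1)

    n_fallback = _face_normal_vertex_average(mesh, op)
    degenerate = mag * mag < _MCN_EPS
    sign = np.sign(np.einsum("vi,vi->v", mcn, n_fallback))
    sign[sign == 0] = 1.0
    H = 0.5 * mag * sign
    normal = np.where(degenerate[:, None], n_fallback,
                      mcn / np.where(mag > 0, mag, 1.0)[:, None]
                      * sign[:, None])
    H = np.where(degenerate, 0.0, H)
    return H, K, normal


def enclosed_volume_area(mesh: TriMesh):
    """Enclosed volume, surface area and reduced volume.

    Volume by the divergence theorem over flat faces (exact for the
    polyhedron); reduced volume v = 6 sqrt(pi) V / A^(3/2), equal to 1 for
    the exact sphere. Raises if the orientation is inverted (V <= 0).
    """
    x = mesh.vertices[mesh.faces]
    vol = float(np.einsum("fi,fi->f", np.cross(x[:, 0], x[:, 1]),
                          x[:, 2]).sum() / 6.0)
    if vol <= 0:
        raise ValueError("negative enclosed volume: inverted orientation")
    area = float(mesh.face_areas().sum())
    reduced = 6.0 * np.sqrt(np.pi) * vol / area ** 1.5
    return vol, area, reduced


def volume_centroid(mesh: TriMesh):
    """Centroid of the enclosed volume (tetrahedral decomposition, exact)."""
    x = mesh.vertices[mesh.faces]
    vt = np.einsum("fi,fi->f", np.cross(x[:, 0], x[:, 1]), x[:, 2]) / 6.0
    c = x.sum(axis=1) / 4.0  # tet centroid with the origin as 4th vertex
    V = vt.sum()
    return (vt[:, None] * c).sum(axis=0) / V


@dataclass
class GeometryCache:
    """All per-vertex and global geometry needed by the membrane forces."""

    normal: np.ndarray        # (V, 3) outward unit normals
    A_mixed: np.ndarray       # (V,) mixed Voronoi areas, units a^2
    H: np.ndarray             # (V,) mean curvature, units 1/a
    K: np.ndarray             # (V,) Gaussian curvature, units 1/a^2
    lapH: np.ndarray          # (V,) Laplace-Beltrami of H, units 1/a^3
    total_area: float
    volume: float
    reduced_volume: float
    centroid: np.ndarray      # (3,) volume centroid


def compute_geometry(mesh: TriMesh) -> GeometryCache:
    """Evaluate the full geometry cache for one mesh configuration."""
    op = _CotOperator(mesh)
    H, K, normal = curvatures(mesh, _op=op)
    lapH = op.apply(H)
    x = mesh.vertices[mesh.faces]
    vt = np.einsum("fi,fi->f", np.cross(x[:, 0], x[:, 1]), x[:, 2]) / 6.0
    vol = float(vt.sum())
    if vol <= 0:
        raise ValueError("negative enclosed volume: inverted orientation")
    area = float(op.face_area.sum())
    reduced = 6.0 * np.sqrt(np.pi) * vol / area ** 1.5
    centroid = (vt[:, None] * (x.sum(axis=1) / 4.0)).sum(axis=0) / vol
    return GeometryCache(normal=normal, A_mixed=op.A, H=H, K=K, lapH=lapH,
                         total_area=area, volume=vol, reduced_volume=reduced,
                         centroid=centroid)
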