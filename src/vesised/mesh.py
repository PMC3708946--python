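"""Closed triangulated surfaces: construction, adjacency and surface quadrature.

The membrane is discretised as a watertight, outward-oriented triangle mesh.
All lengths are expressed in units of the undeformed vesicle radius ``a``,
so the reference configuration is (a triangulation of) the unit sphere.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TriMesh", "build_icosphere", "make_spheroid", "vertex_quadrature"]


class TriMesh:
    """A closed, orientable, genus-0 triangle mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Node positions, in units of the undeformed radius.
    faces : (F, 3) int array
        Vertex-index triples with consistent outward (counterclockwise seen
        from outside) orientation.

    Connectivity (edges, ordered one-rings, incidence maps) is derived once
    at construction and reused; vertex positions may be updated in place
    through :meth:`with_vertices` which shares the connectivity arrays.
    """

    def __init__(self, vertices, faces, _connectivity=None):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if _connectivity is None:
            self._build_connectivity()
        else:
            (self.edges, self.one_ring, self._ring_index, self._ring_flat,
             self._vertex_faces_flat, self._vertex_faces_index,
             self.face_edge_index) = _connectivity

    # -- construction helpers -------------------------------------------------

    def _build_connectivity(self):
        V = len(self.vertices)
        F = len(self.faces)
        # undirected edges via canonical (min, max) keys
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e_sorted = np.sort(e, axis=1)
        edges, counts = np.unique(e_sorted, axis=0, return_counts=True)
        if not np.all(counts == 2):
            bad = edges[counts != 2]
            raise ValueError(f"mesh is not closed-manifold: {len(bad)} edges "
                             f"not shared by exactly 2 faces (first: {bad[:3]})")
        self.edges = edges
        E = len(edges)
        if V - E + F != 2:
            raise ValueError(f"Euler characteristic {V - E + F} != 2; "
                             "only genus-0 surfaces are supported")

        # ordered one-rings: walk around each vertex through shared faces.
        # In an outward CCW face (i, j, k) the directed boundary edge of the
        # ring at i is j -> k, so following successor links j -> k orders the
        # ring counterclockwise seen from outside.
        succ = [dict() for _ in range(V)]
        for (i, j, k) in self.faces:
            succ[i][j] = k
            succ[j][k] = i
            succ[k][i] = j
        one_ring = []
        for v in range(V):
            nxt = succ[v]
            if not nxt:
                raise ValueError(f"isolated vertex {v}")
            start = next(iter(nxt))
            ring = [start]
            cur = nxt[start]
            while cur != start:
                ring.append(cur)
                cur = nxt[cur]
                if len(ring) > len(nxt):
                    raise ValueError(f"non-manifold one-ring at vertex {v}")
            if len(ring) != len(nxt):
                raise ValueError(f"non-manifold one-ring at vertex {v}")
            one_ring.append(ring)
        self.one_ring = one_ring
        # flat CSR-style storage for vectorised consumers
        lens = np.array([len(r) for r in one_ring])
        self._ring_index = np.concatenate([[0], np.cumsum(lens)])
        self._ring_flat = np.concatenate([np.asarray(r) for r in one_ring])

        # faces incident to each vertex (CSR)
        vf = [[] for _ in range(V)]
        for fi, (i, j, k) in enumerate(self.faces):
            vf[i].append(fi)
            vf[j].append(fi)
            vf[k].append(fi)
        lens = np.array([len(x) for x in vf])
        self._vertex_faces_index = np.concatenate([[0], np.cumsum(lens)])
        self._vertex_faces_flat = np.concatenate([np.asarray(x) for x in vf])

        # index into self.edges of the edge opposite each face corner
        fe = np.empty((F, 3), dtype=np.int64)
        emap = {(int(i), int(j)): k for k, (i, j) in enumerate(edges)}
        for fi, (i, j, k) in enumerate(self.faces):
            fe[fi, 0] = emap[(j, k) if j < k else (k, j)]
            fe[fi, 1] = emap[(k, i) if k < i else (i, k)]
            fe[fi, 2] = emap[(i, j) if i < j else (j, i)]
        self.face_edge_index = fe

    def with_vertices(self, vertices) -> "TriMesh":
        """New TriMesh with the same connectivity and updated positions."""
        conn = (self.edges, self.one_ring, self._ring_index, self._ring_flat,
                self._vertex_faces_flat, self._vertex_faces_index,
                self.face_edge_index)
        return TriMesh(vertices, self.faces, _connectivity=conn)

    # -- basic quantities ------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def face_corner_vectors(self):
        """Edge vectors (x_b - x_a, x_c - x_b, x_a - x_c) per face."""
        x = self.vertices[self.faces]
        return x[:, 1] - x[:, 0], x[:, 2] - x[:, 1], x[:, 0] - x[:, 2]

    def face_normals_areas(self):
        """Outward unit face normals and face areas."""
        e0, e1, _ = self.face_corner_vectors()
        n = np.cross(e0, e1)
        nrm = np.linalg.norm(n, axis=1)
        if np.any(nrm <= 0):
            bad = int(np.argmin(nrm))
            raise ValueError(f"degenerate face {bad} with zero area")
        return n / nrm[:, None], 0.5 * nrm

    def face_areas(self):
        return self.face_normals_areas()[1]

    def vertex_weights(self):
        """Trapezoidal quadrature weights: one third of incident face area.

        Each flat triangle's area is reassigned equally to its three
        vertices, so the weights partition the total surface area.
        """
        areas = self.face_areas()
        w = np.zeros(self.n_vertices)
        np.add.at(w, self.faces.ravel(), np.repeat(areas / 3.0, 3))
        return w

    def min_edge_length(self) -> float:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).min())

    def edge_lengths(self):
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def copy(self) -> "TriMesh":
        return self.with_vertices(self.vertices.copy())


def _icosahedron():
    """Regular icosahedron inscribed in the unit sphere, outward faces."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    v /= np.linalg.norm(v[0])
    f = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    return v, f


def build_icosphere(refinements: int) -> TriMesh:
    """Recursively refined icosahedron projected onto the unit sphere.

    Each refinement splits every triangle 4-to-1 at the edge midpoints and
    projects the new vertices radially onto the sphere, giving
    ``V = 10 * 4**k + 2`` vertices and ``F = 20 * 4**k`` faces after ``k``
    refinements. Midpoint vertices are deduplicated through a canonical
    (min-index, max-index) edge key so the result is exactly watertight.
    """
    if refinements < 0:
        raise ValueError("refinements must be >= 0")
    v, f = _icosahedron()
    verts = [row for row in v]
    for _ in range(refinements):
        midpoint = {}

        def mid(i, j):
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                m = verts[i] + verts[j]
                m /= np.linalg.norm(m)
                midpoint[key] = len(verts)
                verts.append(m)
            return midpoint[key]

        new_f = np.empty((4 * len(f), 3), dtype=np.int64)
        for t, (i, j, k) in enumerate(f):
            a, b, c = mid(i, j), mid(j, k), mid(k, i)
            new_f[4 * t:4 * t + 4] = [[i, a, c], [j, b, a], [k, c, b],
                                      [a, b, c]]
        f = new_f
    return TriMesh(np.array(verts), f)


def make_spheroid(aspect_ratio: float, refinements: int) -> TriMesh:
    """Icosphere scaled along z by ``aspect_ratio`` (test fixture).

    Topology and face orientation are unchanged; useful as a surface with
    known analytic area, volume and curvature range.
    """
    if aspect_ratio <= 0:
        raise ValueError("aspect_ratio must be > 0")
    m = build_icosphere(refinements)
    v = m.vertices.copy()
    v[:, 2] *= aspect_ratio
    return m.with_vertices(v)


def vertex_quadrature(mesh: TriMesh, values):
    """Surface integral by the vertex-based trapezoidal rule.

    Integrates per-vertex scalar or vector samples against the weights in
    which each flat triangle's area is split equally among its three
    vertices: ``sum_v values[v] * (1/3) * sum_{faces at v} S_face``.
    Linear in ``values``; integrating 1 returns the total flat area exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"got {values.shape[0]} values for {mesh.n_vertices} vertices")
    w = mesh.vertex_weights()
    if values.ndim == 1:
        return float(w @ values)
    return w @ values
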