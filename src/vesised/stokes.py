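"""Wall-bounded Stokes flow: Blake's Green's function and the single layer.

The vesicle surface drives the flow through a single-layer potential

    u(x0) = (1/8 pi) \oint G(x0, x) . q(x) dS(x),

where ``q`` is the (dimensionless) force per unit area the membrane exerts
on the fluid and ``G`` is Blake's Green's function for a point force above a
plane no-slip wall at z = 0: the free-space Stokeslet plus an image system
(image Stokeslet, potential dipole and Stokeslet doublet) that cancels the
velocity identically on the wall. At viscosity ratio 1 the double-layer
integral drops out of the boundary-integral equation, so the single layer is
the whole flow solution.

The surface integral uses the vertex trapezoidal rule. The integrable
singularity at the evaluation vertex is regularised by subtracting the local
normal traction carried on the varying normal field, integrating
``G . (q - (q(x0).n(x0)) n)`` with the self node dropped. The subtraction
costs nothing because the single-layer potential of the normal field
vanishes identically (``oint G_ij(x, x0) n_j(x) dS(x) = 0``, a consequence
of incompressibility, valid for the Blake kernel as for the free Stokeslet),
and it removes the singular part of every normal force density -- which the
Helfrich, tension and gravity tractions all are. The Hadamard-Rybczynski
oracle validates the treatment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .mesh import TriMesh

__all__ = ["blake_tensor", "single_layer_velocity", "velocity_at_points",
           "oseen_tensor"]


def oseen_tensor(x, x0):
    """Free-space Stokeslet G_ij = delta_ij/r + r_i r_j / r^3."""
    d = np.asarray(x, dtype=float) - np.asarray(x0, dtype=float)
    r = np.linalg.norm(d)
    if r == 0:
        raise ValueError("coincident points")
    return np.eye(3) / r + np.outer(d, d) / r ** 3


def blake_tensor(x, x0):
    """Blake's wall Green's function, field point ``x``, source ``x0``.

    The wall occupies z = 0. The source must lie strictly above the wall;
    the field point may touch it (where the tensor contracts to zero with
    any force, the no-slip condition). Satisfies Lorentz reciprocity
    ``G_ij(x, x0) = G_ji(x0, x)`` and reduces to the Oseen tensor far from
    the wall.
    """
    x = np.asarray(x, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    h = x0[2]
    if h <= 0:
        raise ValueError("source point must be strictly above the wall")
    if x[2] < 0:
        raise ValueError("field point below the wall")
    if np.array_equal(x, x0):
        raise ValueError("coincident field and source points")

    image = np.array([x0[0], x0[1], -h])
    R = x - image
    rho = np.linalg.norm(R)
    G = oseen_tensor(x, x0) - (np.eye(3) / rho + np.outer(R, R) / rho ** 3)

    beta = np.array([1.0, 1.0, -1.0])
    delta = np.eye(3)
    e3 = np.array([0.0, 0.0, 1.0])
    # potential dipole: d/dR_j (R_i / rho^3)
    PD = delta / rho ** 3 - 3.0 * np.outer(R, R) / rho ** 5
    # Stokeslet doublet: d/dR_j (delta_i3/rho + R_i R_3 / rho^3)
    SD = (-np.outer(e3, R) / rho ** 3 + delta * R[2] / rho ** 3
          + np.outer(R, e3) / rho ** 3
          - 3.0 * R[2] * np.outer(R, R) / rho ** 5)
    G += 2.0 * h * (h * PD - SD) * beta[None, :]
    return G


@njit(cache=True, fastmath=True)
def _velocity_kernel(targets, sources, q, w, normals,
                     self_subtract):  # pragma: no cover
    M = targets.shape[0]
    N = sources.shape[0]
    u = np.zeros((M, 3))
    for m in range(M):
        x0 = targets[m, 0]
        x1 = targets[m, 1]
        x2 = targets[m, 2]
        # normal traction component at the evaluation vertex; the single
        # layer of the normal field integrates to zero exactly, so the
        # subtracted piece costs nothing and bounds the integrand
        qn = 0.0
        if self_subtract:
            qn = (q[m, 0] * normals[m, 0] + q[m, 1] * normals[m, 1]
                  + q[m, 2] * normals[m, 2])
        u0 = 0.0
        u1 = 0.0
        u2 = 0.0
        for j in range(N):
            if self_subtract and j == m:
                continue
            h = sources[j, 2]
            f0 = (q[j, 0] - qn * normals[j, 0]) * w[j]
            f1 = (q[j, 1] - qn * normals[j, 1]) * w[j]
            f2 = (q[j, 2] - qn * normals[j, 2]) * w[j]
            # free-space Stokeslet
            r0 = x0 - sources[j, 0]
            r1 = x1 - sources[j, 1]
            r2 = x2 - h
            rr = np.sqrt(r0 * r0 + r1 * r1 + r2 * r2)
            ir = 1.0 / rr
            ir3 = ir * ir * ir
            rf = r0 * f0 + r1 * f1 + r2 * f2
            u0 += f0 * ir + r0 * rf * ir3
            u1 += f1 * ir + r1 * rf * ir3
            u2 += f2 * ir + r2 * rf * ir3
            # image system at (y1, y2, -h), mirrored force p = (f1, f2, -f3)
            R2 = x2 + h
            rho = np.sqrt(r0 * r0 + r1 * r1 + R2 * R2)
            irho = 1.0 / rho
            irho3 = irho * irho * irho
            irho5 = irho3 * irho * irho
            p0 = f0
            p1 = f1
            p2 = -f2
            Rp = r0 * p0 + r1 * p1 + R2 * p2
            # minus image Stokeslet (original force)
            Rf = r0 * f0 + r1 * f1 + R2 * f2
            u0 -= f0 * irho + r0 * Rf * irho3
            u1 -= f1 * irho + r1 * Rf * irho3
            u2 -= f2 * irho + R2 * Rf * irho3
            # 2h * (h * potential dipole - Stokeslet doublet) applied to p
            pd0 = p0 * irho3 - 3.0 * r0 * Rp * irho5
            pd1 = p1 * irho3 - 3.0 * r1 * Rp * irho5
            pd2 = p2 * irho3 - 3.0 * R2 * Rp * irho5
            sd0 = p0 * R2 * irho3 + p2 * r0 * irho3 \
                - 3.0 * r0 * R2 * Rp * irho5
            sd1 = p1 * R2 * irho3 + p2 * r1 * irho3 \
                - 3.0 * r1 * R2 * Rp * irho5
            sd2 = -Rp * irho3 + p2 * R2 * irho3 + p2 * R2 * irho3 \
                - 3.0 * R2 * R2 * Rp * irho5
            u0 += 2.0 * h * (h * pd0 - sd0)
            u1 += 2.0 * h * (h * pd1 - sd1)
            u2 += 2.0 * h * (h * pd2 - sd2)
        u[m, 0] = u0 / (8.0 * np.pi)
        u[m, 1] = u1 / (8.0 * np.pi)
        u[m, 2] = u2 / (8.0 * np.pi)
    return u


def single_layer_velocity(mesh: TriMesh, traction, normals=None):
    """Velocity of every mesh vertex from the membrane force density.

    ``traction`` is the per-vertex force per unit area exerted on the fluid
    (units ``kappa_b/a^3``); the result is the dimensionless velocity
    (units ``kappa_b/(mu a^2)``). Linear in the traction. The vesicle must
    lie strictly above the wall plane z = 0.

    ``normals`` are the outward unit vertex normals used in the singularity
    subtraction; pass the ones from the geometry cache to stay consistent
    with the traction, else area-weighted face normals are used.
    """
    q = np.asarray(traction, dtype=float)
    if q.shape != (mesh.n_vertices, 3):
        raise ValueError("traction must be (V, 3) aligned with the mesh")
    if not np.all(np.isfinite(q)):
        raise ValueError("non-finite traction")
    z = mesh.vertices[:, 2]
    if np.any(z <= 0):
        raise ValueError("vertex at or below the wall plane")
    if normals is None:
        from .geometry import _face_normal_vertex_average
        normals = _face_normal_vertex_average(mesh)
    else:
        normals = np.ascontiguousarray(normals, dtype=float)
    w = mesh.vertex_weights()
    return _velocity_kernel(mesh.vertices, mesh.vertices, q, w, normals, True)


def velocity_at_points(points, mesh: TriMesh, traction):
    """Flow velocity at off-surface probe points (e.g. on the wall)."""
    q = np.asarray(traction, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(mesh.vertices[:, 2] <= 0):
        raise ValueError("vertex at or below the wall plane")
    w = mesh.vertex_weights()
    dummy = np.zeros_like(mesh.vertices)
    return _velocity_kernel(pts, mesh.vertices, q, w, dummy, False)
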