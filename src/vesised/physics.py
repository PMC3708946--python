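"""Membrane tractions, tension law, electrostatics and nondimensionalisation.

Physical model
--------------
A giant unilamellar vesicle of radius ``a`` settles through a Newtonian fluid
(viscosity ``mu``, internal/external viscosity ratio fixed at 1) toward a
charged, no-slip glass plane at z = 0. Three surface force densities act on
the membrane:

* Helfrich curvature elasticity with bending modulus ``kappa_b`` plus an
  isotropic tension ``sigma`` enforcing near-incompressibility,
* the buoyant weight from the density difference ``delta_rho`` between the
  interior (sucrose) and exterior (glucose) solutions,
* a screened electrostatic repulsion from the like-charged wall, in the
  linear Derjaguin (DLVO) approximation.

The tension is spatially uniform and follows from the instantaneous global
area strain through the Evans-Rawicz law, which superposes the entropic
smoothing of thermal undulations (logarithmic regime) and direct expansion
of the area per lipid (linear regime).

Scales and sign conventions
---------------------------
Lengths are scaled by ``a``, tractions by ``kappa_b / a^3`` and time by
``mu a^3 / kappa_b`` (velocity scale ``kappa_b / (mu a^2)``). All traction
functions return the force per unit area that the membrane exerts **on the
fluid**; the wall-bounded single-layer potential
``u = (1/8 pi) \oint G q dS`` (see :mod:`vesised.stokes`) then moves a
gravity-loaded vesicle downward and a wall-repelled one upward. In this
convention the gravity traction is ``-Bg z n`` (net force of magnitude
``Bg V`` pointing down) and the Helfrich traction is the negative
variational derivative of the curvature energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.constants import Boltzmann as K_B
from scipy.constants import elementary_charge as E_CHARGE
from scipy.constants import epsilon_0 as EPS0
from scipy.optimize import brentq

from .geometry import GeometryCache

__all__ = [
    "PhysicalParams", "DimensionlessParams", "nondimensionalize",
    "dimensionalize", "debye_length", "surface_potentials",
    "electrostatic_number", "electrostatic_traction", "gravity_traction",
    "tension_from_strain", "strain_from_tension", "helfrich_traction",
    "helfrich_energy", "K_B", "E_CHARGE", "EPS0",
]

#: Evans-Rawicz topology coefficient for quasi-spherical vesicles
DEFAULT_TOPOLOGY_COEFF = 1.0 / (24.0 * np.pi)


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants of one experiment, all in SI units."""

    a: float                 # vesicle radius, m
    mu: float                # outer viscosity, Pa s
    delta_rho: float         # density difference (inside - outside), kg/m^3
    kappa_b: float           # bending modulus, J
    K_A: float               # direct area-dilation modulus, N/m
    T: float                 # absolute temperature, K
    epsilon: float           # solvent permittivity, F/m
    n_ion: float             # monovalent ion number density, 1/m^3
    sigma_glass: float       # glass surface charge density, C/m^2
    sigma_vesicle: float     # membrane surface charge density, C/m^2
    g: float = 9.81          # gravitational acceleration, m/s^2
    lambda_visc: float = 1.0  # viscosity ratio, fixed at 1 in this model

    def __post_init__(self):
        positive = ("a", "mu", "delta_rho", "kappa_b", "K_A", "T",
                    "epsilon", "n_ion", "g")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lambda_visc != 1.0:
            raise ValueError("only viscosity ratio 1 is supported")

    # characteristic scales -------------------------------------------------
    @property
    def traction_scale(self) -> float:
        """kappa_b / a^3, Pa."""
        return self.kappa_b / self.a ** 3

    @property
    def time_scale(self) -> float:
        """mu a^3 / kappa_b, s."""
        return self.mu * self.a ** 3 / self.kappa_b

    @property
    def velocity_scale(self) -> float:
        """kappa_b / (mu a^2), m/s."""
        return self.kappa_b / (self.mu * self.a ** 2)


@dataclass
class DimensionlessParams:
    """The six dimensionless groups governing the sedimentation problem.

    ``sigma_red`` is the instantaneous reduced membrane tension
    ``sigma a^2 / kappa_b``; it is a state variable recomputed from the
    global area strain at every time step, not a constant of the run.
    """

    Bg: float                # gravitational number, delta_rho g a^4 / kappa_b
    B_el: float              # electrostatic traction scale, units kappa_b/a^3
    lambda_bar: float        # Debye length / a
    c_tilde: float           # K_A a^2 / kappa_b, direct-dilation modulus
    kappa_kT: float = 40.0   # kappa_b / (k_B T), sets the undulation strain
    lambda_visc: float = 1.0
    sigma_red: float = 0.0
    topology_coeff: float = DEFAULT_TOPOLOGY_COEFF

    def __post_init__(self):
        if self.Bg <= 0:
            raise ValueError("Bg must be > 0")
        if self.lambda_bar <= 0:
            raise ValueError("lambda_bar must be > 0")
        if self.c_tilde <= 0:
            raise ValueError("c_tilde must be > 0")
        if self.sigma_red < 0:
            raise ValueError("sigma_red must be >= 0")


def debye_length(n_ion: float, T: float, epsilon: float) -> float:
    """Debye screening length of a symmetric monovalent electrolyte.

    lambda_D = sqrt(epsilon k_B T / (2 e^2 n)) with ``n`` the number density
    of each ion species in 1/m^3. Returns metres.
    """
    if n_ion <= 0:
        raise ValueError("n_ion must be > 0")
    return float(np.sqrt(epsilon * K_B * T / (2.0 * E_CHARGE ** 2 * n_ion)))


def surface_potentials(sigma_glass: float, sigma_vesicle: float,
                       lambda_D: float, epsilon: float, T: float):
    """Glass surface potential and renormalised vesicle potential, in volts.

    The weakly charged glass follows the linear (Grahame) relation
    ``psi_g = sigma_g lambda_D / epsilon``. The membrane is too highly
    charged for linear screening theory, so beyond a Debye length its bare
    potential is replaced by the saturated renormalised value of nonlinear
    Poisson-Boltzmann theory, ``psi_eff = 4 k_B T / e`` (about 102 mV at
    296 K), carrying the sign of the membrane charge and independent of its
    magnitude. An uncharged membrane has ``psi_eff = 0``.
    """
    if lambda_D <= 0:
        raise ValueError("lambda_D must be > 0")
    psi_glass = sigma_glass * lambda_D / epsilon
    psi_eff = float(np.sign(sigma_vesicle)) * 4.0 * K_B * T / E_CHARGE
    return psi_glass, psi_eff


def electrostatic_number(p: PhysicalParams) -> float:
    """Dimensionless amplitude B_el of the wall repulsion.

    The linear Derjaguin (weak-overlap) disjoining pressure between two
    dissimilar plates at separation h is
    ``P(h) = 2 epsilon psi_g psi_eff exp(-h/lambda_D) / lambda_D^2``;
    its contact amplitude scaled by ``kappa_b / a^3`` gives
    ``B_el = 2 epsilon psi_g psi_eff a^3 / (lambda_D^2 kappa_b)``.
    Positive for like charges (repulsion).
    """
    lam = debye_length(p.n_ion, p.T, p.epsilon)
    psi_g, psi_eff = surface_potentials(p.sigma_glass, p.sigma_vesicle,
                                        lam, p.epsilon, p.T)
    return 2.0 * p.epsilon * psi_g * psi_eff / lam ** 2 * p.a ** 3 / p.kappa_b


def nondimensionalize(p: PhysicalParams) -> DimensionlessParams:
    """Collapse the physical parameters onto the dimensionless groups."""
    lam = debye_length(p.n_ion, p.T, p.epsilon)
    return DimensionlessParams(
        Bg=p.delta_rho * p.g * p.a ** 4 / p.kappa_b,
        B_el=electrostatic_number(p),
        lambda_bar=lam / p.a,
        c_tilde=p.K_A * p.a ** 2 / p.kappa_b,
        kappa_kT=p.kappa_b / (K_B * p.T),
        lambda_visc=p.lambda_visc,
    )


def dimensionalize(d: DimensionlessParams, a: float, mu: float, T: float,
                   epsilon: float, g: float = 9.81,
                   sigma_vesicle_sign: float = -1.0) -> PhysicalParams:
    """Reconstruct physical parameters from the dimensionless groups.

    Inverse of :func:`nondimensionalize` given the reference radius,
    viscosity, temperature and permittivity (the groups alone do not fix
    them). The membrane charge magnitude is not recoverable (the
    renormalised potential saturates); only its sign is restored.
    """
    kappa_b = d.kappa_kT * K_B * T
    lambda_D = d.lambda_bar * a
    n_ion = epsilon * K_B * T / (2.0 * E_CHARGE ** 2 * lambda_D ** 2)
    psi_eff = sigma_vesicle_sign * 4.0 * K_B * T / E_CHARGE
    if d.B_el == 0.0:
        sigma_glass = 0.0
        sigma_vesicle = 0.0
    else:
        psi_g = d.B_el * lambda_D ** 2 * kappa_b / (2.0 * epsilon
                                                    * psi_eff * a ** 3)
        sigma_glass = psi_g * epsilon / lambda_D
        sigma_vesicle = sigma_vesicle_sign * 1e-3  # sign only; see docstring
    return PhysicalParams(
        a=a, mu=mu, delta_rho=d.Bg * kappa_b / (g * a ** 4),
        kappa_b=kappa_b, K_A=d.c_tilde * kappa_b / a ** 2, T=T,
        epsilon=epsilon, n_ion=n_ion, sigma_glass=sigma_glass,
        sigma_vesicle=sigma_vesicle, g=g, lambda_visc=d.lambda_visc)


# -- tension-strain law -------------------------------------------------------

def strain_from_tension(sigma_red: float, kappa_kT: float = 40.0,
                        c_tilde: float = 1e8,
                        topology_coeff: float = DEFAULT_TOPOLOGY_COEFF) -> float:
    """Evans-Rawicz area strain at reduced tension ``sigma_red``.

    alpha = ln(1 + c sigma_red) / (8 pi kappa_b/k_BT) + sigma_red / c_tilde.
    The logarithmic term is the entropic smoothing of thermal undulations,
    the linear term direct dilation of the area per lipid.
    """
    if sigma_red < 0:
        raise ValueError("sigma_red must be >= 0")
    return (np.log1p(topology_coeff * sigma_red) / (8.0 * np.pi * kappa_kT)
            + sigma_red / c_tilde)


def tension_from_strain(alpha: float, kappa_kT: float = 40.0,
                        c_tilde: float = 1e8,
                        topology_coeff: float = DEFAULT_TOPOLOGY_COEFF) -> float:
    """Reduced tension carrying a given global area strain.

    Inverts the strictly increasing Evans-Rawicz relation by bracketed root
    finding; ``alpha = 0`` maps to zero tension. A (numerically) negative
    strain returns zero tension -- a slack membrane carries none in this
    quasi-static model -- with a warning when clearly below rounding.
    """
    if alpha < 0:
        if alpha < -1e-6:
            warnings.warn("negative area strain; treating the membrane "
                          "as tensionless")
        return 0.0
    if alpha == 0.0:
        return 0.0

    def f(s):
        return strain_from_tension(s, kappa_kT, c_tilde, topology_coeff) - alpha

    hi = max(1.0, c_tilde * alpha)  # linear term alone reaches alpha here
    return float(brentq(f, 0.0, hi, rtol=1e-15, maxiter=200))


# -- traction fields ----------------------------------------------------------

def gravity_traction(z, normals, Bg):
    """Buoyant-weight traction ``-Bg z n`` (force on the fluid).

    ``z`` is the dimensionless height of each membrane element above the
    wall. Written as a hydrostatic pressure jump, the closed-surface
    identity ``oint z n dS = V e_z`` makes the net force ``-Bg V e_z``:
    the buoyant weight, pointing toward the wall.
    """
    z = np.asarray(z, dtype=float)
    return -Bg * z[:, None] * np.asarray(normals, dtype=float)


def electrostatic_traction(heights, B_el, lambda_bar, direction=None):
    """Screened wall repulsion ``B_el exp(-h/lambda_bar)`` along +z.

    Derjaguin treats each membrane element as a plane segment parallel to
    the wall, so the force is perpendicular to the wall rather than along
    the local membrane normal; ``direction`` (per-vertex unit vectors)
    overrides this if a local-normal variant is wanted. Heights must be
    strictly positive: membrane-wall contact is outside the model.
    """
    h = np.asarray(heights, dtype=float)
    if np.any(h <= 0):
        raise ValueError("membrane-wall contact: all heights must be > 0")
    mag = B_el * np.exp(-h / lambda_bar)
    if direction is None:
        out = np.zeros((len(h), 3))
        out[:, 2] = mag
        return out
    return mag[:, None] * np.asarray(direction, dtype=float)


def helfrich_traction(geom: GeometryCache, sigma_red: float):
    """Curvature-elastic plus tension traction (force on the fluid).

    In units of ``kappa_b / a^3``:

        f = [2 lap H + 4 H (H^2 - K) - 2 sigma_red H] n

    the negative variational derivative of the bending energy
    ``2 oint H^2 dS + sigma_red A``. On a sphere the bending part vanishes
    identically (H^2 = K, lap H = 0), leaving the inward Laplace traction
    ``-2 sigma_red H n``.
    """
    if geom.lapH is None:
        raise ValueError("GeometryCache is missing lapH")
    H, K = geom.H, geom.K
    mag = 2.0 * geom.lapH + 4.0 * H * (H * H - K) - 2.0 * sigma_red * H
    return mag[:, None] * geom.normal


def helfrich_energy(mesh, H=None, sigma_red: float = 0.0) -> float:
    """Discrete shape energy ``2 oint H^2 dS + sigma_red A`` (kappa_b = 1).

    Evaluated with the vertex trapezoidal quadrature so that it is the
    energy whose (negative, per-unit-mixed-area) gradient the Helfrich
    traction approximates.
    """
    from .geometry import curvatures
    from .mesh import vertex_quadrature
    if H is None:
        H, _, _ = curvatures(mesh)
    w = mesh.vertex_weights()
    return float((2.0 * H * H * w).sum() + sigma_red * w.sum())
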