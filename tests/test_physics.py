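"""Membrane tractions, the tension-strain law and electrostatics."""

import numpy as np
import pytest
from scipy.constants import Avogadro

from vesised.geometry import compute_geometry
from vesised.mesh import build_icosphere, make_spheroid, vertex_quadrature
from vesised.physics import (DimensionlessParams, PhysicalParams,
                             debye_length, dimensionalize,
                             electrostatic_number, electrostatic_traction,
                             gravity_traction, helfrich_energy,
                             helfrich_traction, nondimensionalize,
                             strain_from_tension, surface_potentials,
                             tension_from_strain)

EPS_WATER = 78.5 * 8.8541878128e-12
T_LAB = 296.0


def make_params(a=10e-6, n_molar=2e-6, sigma_v=-2e-3):
    return PhysicalParams(
        a=a, mu=2.0e-3, delta_rho=35.0, kappa_b=40 * 1.380649e-23 * T_LAB,
        K_A=0.2, T=T_LAB, epsilon=EPS_WATER,
        n_ion=n_molar * 1e3 * Avogadro,
        sigma_glass=-2e-3, sigma_vesicle=sigma_v)


class TestNondimensionalization:
    def test_gravitational_number_scales_as_fourth_power(self):
        d1 = nondimensionalize(make_params(a=10e-6))
        d2 = nondimensionalize(make_params(a=20e-6))
        assert d2.Bg / d1.Bg == pytest.approx(16.0, rel=1e-12)

    def test_physical_settling_speed_goes_as_radius_squared(self):
        # dimensionless speed is proportional to Bg, so the physical speed
        # Bg * velocity_scale grows as a^2: a factor 10 in radius makes the
        # vesicle sediment a hundred times faster
        p1, p10 = make_params(a=1e-6), make_params(a=10e-6)
        u1 = nondimensionalize(p1).Bg * p1.velocity_scale
        u10 = nondimensionalize(p10).Bg * p10.velocity_scale
        assert u10 / u1 == pytest.approx(100.0, rel=1e-10)

    def test_round_trip(self):
        p = make_params()
        d = nondimensionalize(p)
        back = dimensionalize(d, a=p.a, mu=p.mu, T=p.T, epsilon=p.epsilon,
                              g=p.g)
        assert back.delta_rho == pytest.approx(p.delta_rho, rel=1e-12)
        assert back.kappa_b == pytest.approx(p.kappa_b, rel=1e-12)
        assert back.K_A == pytest.approx(p.K_A, rel=1e-12)
        assert back.n_ion == pytest.approx(p.n_ion, rel=1e-12)
        assert back.sigma_glass == pytest.approx(p.sigma_glass, rel=1e-12)
        d2 = nondimensionalize(back)
        assert d2.B_el == pytest.approx(d.B_el, rel=1e-12)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError):
            make_params(a=-1e-6)
        with pytest.raises(ValueError):
            DimensionlessParams(Bg=-1, B_el=0, lambda_bar=0.1, c_tilde=1e8)

    def test_expected_magnitudes(self):
        d = nondimensionalize(make_params(a=10e-6))
        assert d.Bg == pytest.approx(21.0, rel=0.02)
        assert 1e6 < d.c_tilde < 1e9  # "a large number"
        assert d.B_el > 0  # like charges repel


class TestDebyeLength:
    def test_three_millimolar_salt(self):
        lam = debye_length(3e-3 * 1e3 * Avogadro, T_LAB, EPS_WATER)
        assert lam == pytest.approx(5.5e-9, rel=0.02)

    def test_calcein_counterions(self):
        lam = debye_length(2e-6 * 1e3 * Avogadro, T_LAB, EPS_WATER)
        assert lam == pytest.approx(214e-9, rel=0.02)

    def test_inverse_square_root_scaling(self):
        n = 1e22
        assert debye_length(4 * n, 300, EPS_WATER) == pytest.approx(
            debye_length(n, 300, EPS_WATER) / 2, rel=1e-12)

    def test_nonpositive_concentration(self):
        with pytest.raises(ValueError):
            debye_length(0.0, 300, EPS_WATER)


class TestSurfacePotentials:
    def test_renormalized_potential_independent_of_membrane_charge(self):
        _, p1 = surface_potentials(-2e-3, -1e-3, 214e-9, EPS_WATER, T_LAB)
        _, p2 = surface_potentials(-2e-3, -2e-3, 214e-9, EPS_WATER, T_LAB)
        assert p1 == p2
        # saturation value: 4 k_B T / e, about -102 mV for a negative membrane
        assert p1 == pytest.approx(-0.102, rel=0.01)

    def test_glass_potential_linear_in_charge(self):
        g1, _ = surface_potentials(-1e-3, -2e-3, 214e-9, EPS_WATER, T_LAB)
        g2, _ = surface_potentials(-2e-3, -2e-3, 214e-9, EPS_WATER, T_LAB)
        assert g2 == pytest.approx(2 * g1, rel=1e-12)

    def test_uncharged_surfaces_give_no_repulsion(self):
        assert electrostatic_number(make_params(sigma_v=0.0)) == 0.0
        p = make_params()
        p_glass0 = PhysicalParams(**{**p.__dict__, "sigma_glass": 0.0})
        assert electrostatic_number(p_glass0) == 0.0


class TestElectrostaticTraction:
    def test_pure_exponential_decay(self):
        lb = 0.02
        f1 = electrostatic_traction(np.array([lb]), 5.0, lb)
        f2 = electrostatic_traction(np.array([2 * lb]), 5.0, lb)
        assert f1[0, 2] / f2[0, 2] == pytest.approx(np.e, rel=1e-12)

    def test_contact_limit_is_prefactor(self):
        f = electrostatic_traction(np.array([1e-12]), 7.5, 0.02)
        assert f[0, 2] == pytest.approx(7.5, rel=1e-9)
        assert f[0, 0] == f[0, 1] == 0.0

    def test_monotone_decrease_and_far_field(self):
        h = np.linspace(0.01, 3.0, 40)
        f = electrostatic_traction(h, 5.0, 0.02)[:, 2]
        assert np.all(np.diff(f) < 0)
        assert f[-1] < 1e-30

    def test_contact_is_an_error(self):
        with pytest.raises(ValueError, match="contact"):
            electrostatic_traction(np.array([0.0, 1.0]), 1.0, 0.02)


class TestGravityTraction:
    def test_closed_surface_weight_identity(self, ico3, geom3):
        # oint z n dS = V e_z, so the net traction is -Bg V e_z (downward)
        m = ico3.with_vertices(ico3.vertices + np.array([0, 0, 5.0]))
        g = compute_geometry(m)
        q = gravity_traction(m.vertices[:, 2], g.normal, 3.0)
        net = vertex_quadrature(m, q)
        assert net[2] == pytest.approx(-3.0 * g.volume, rel=0.01)
        assert abs(net[0]) < 1e-10 and abs(net[1]) < 1e-10

    def test_zero_prefactor(self, ico2):
        g = compute_geometry(ico2)
        q = gravity_traction(ico2.vertices[:, 2], g.normal, 0.0)
        assert np.all(q == 0)

    def test_linear_in_prefactor(self, ico2):
        g = compute_geometry(ico2)
        z = ico2.vertices[:, 2] + 2
        assert np.allclose(gravity_traction(z, g.normal, 4.0),
                           2 * gravity_traction(z, g.normal, 2.0))


class TestTensionStrainLaw:
    def test_zero_strain_zero_tension(self):
        assert tension_from_strain(0.0) == 0.0
        assert strain_from_tension(0.0) == 0.0

    def test_round_trip_through_closed_form(self):
        for sigma in (1e-3, 1.0, 50.0, 2e4, 3e6):
            alpha = strain_from_tension(sigma, 40.0, 1e8)
            back = tension_from_strain(alpha, 40.0, 1e8)
            assert back == pytest.approx(sigma, rel=1e-10)

    def test_strictly_increasing(self):
        sig = [tension_from_strain(a, 40.0, 1e8)
               for a in np.linspace(0, 8e-3, 30)]
        assert all(b > a for a, b in zip(sig, sig[1:]))

    def test_negative_strain_is_slack(self):
        with pytest.warns(UserWarning, match="tensionless"):
            assert tension_from_strain(-1e-3) == 0.0

    @pytest.mark.parametrize("a_um, sigma_eq", [(10, 1e2), (20, 2e3),
                                                (40, 3e4)])
    def test_undulation_term_dominates_in_experimental_regime(self, a_um,
                                                              sigma_eq):
        # at the tensions arising in sedimentation, >99% of the strain is
        # smoothing of thermal undulations, not direct dilation
        d = nondimensionalize(make_params(a=a_um * 1e-6))
        total = strain_from_tension(sigma_eq, d.kappa_kT, d.c_tilde)
        direct = sigma_eq / d.c_tilde
        assert direct / total < 0.01


class TestHelfrichTraction:
    def test_sphere_is_equilibrium_at_zero_tension(self):
        mags = []
        for k in (1, 2, 3):
            m = build_icosphere(k)
            g = compute_geometry(m)
            mags.append(np.abs(helfrich_traction(g, 0.0)).max())
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] < 0.05

    def test_laplace_law_on_unit_sphere(self, geom3):
        f = helfrich_traction(geom3, 1.0)
        fn = np.einsum("vi,vi->v", f, geom3.normal)
        # pure tension: inward traction of magnitude 2 sigma / R
        assert np.abs(fn + 2.0).max() < 0.05
        assert fn.mean() == pytest.approx(-2.0, rel=0.02)

    def test_no_self_propulsion(self, spheroid15):
        g = compute_geometry(spheroid15)
        f = helfrich_traction(g, 1.5)
        w = spheroid15.vertex_weights()
        net = np.linalg.norm((f * w[:, None]).sum(axis=0))
        scale = np.abs(f).max() * g.total_area
        assert net / scale < 1e-3

    def test_energy_gradient_weak_form(self, rng):
        # central differences of the discrete shape energy along smooth
        # normal displacement fields against -<f, d>_A
        sp = make_spheroid(1.5, 4)
        g = compute_geometry(sp)
        f = helfrich_traction(g, 0.0)
        V = sp.vertices
        rels = []
        for _ in range(6):
            c = rng.normal(size=4)
            phi = c[0] + V @ c[1:]
            d = phi[:, None] * g.normal
            eps = 1e-6
            dE = (helfrich_energy(sp.with_vertices(V + eps * d))
                  - helfrich_energy(sp.with_vertices(V - eps * d))) / (2 * eps)
            pred = -(np.einsum("vi,vi->v", f, d) * g.A_mixed).sum()
            rels.append((dE - pred) / abs(dE))
        assert np.sqrt(np.mean(np.square(rels))) < 0.05

    def test_tension_part_matches_area_gradient(self, rng):
        # the sigma * A term of the energy is differentiated almost exactly
        # by the cotangent formula: check the full traction with dominant
        # tension against the FD gradient
        sp = make_spheroid(1.2, 3)
        g = compute_geometry(sp)
        sigma = 50.0
        f = helfrich_traction(g, sigma)
        V = sp.vertices
        c = rng.normal(size=4)
        phi = c[0] + V @ c[1:]
        d = phi[:, None] * g.normal
        eps = 1e-6
        dE = (helfrich_energy(sp.with_vertices(V + eps * d), sigma_red=sigma)
              - helfrich_energy(sp.with_vertices(V - eps * d),
                                sigma_red=sigma)) / (2 * eps)
        pred = -(np.einsum("vi,vi->v", f, d) * g.A_mixed).sum()
        assert pred == pytest.approx(dE, rel=0.01)

    def test_missing_lapH_rejected(self, geom3):
        import dataclasses
        broken = dataclasses.replace(geom3, lapH=None)
        with pytest.raises(ValueError, match="lapH"):
            helfrich_traction(broken, 0.0)
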