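"""Model terms: initialization, anisotropy, driving force, field equations."""

import numpy as np
import pytest

from neurongrowth import bspline_collocation as bsc
from neurongrowth import growth_model as gm
from neurongrowth.errors import (
    ConfigurationError,
    InitializationError,
    ParameterError,
)
from neurongrowth.neurite_topology import Tip


class TestInitialization:
    def test_tubulin_profile_values(self, circle_state, grid64):
        """c_tub = (1 + tanh((r0 - r)/2))/2: 0.5 at the rim, ~1 at center."""
        X, Y = np.meshgrid(grid64.greville_u, grid64.greville_v, indexing="ij")
        r = np.hypot(X - 32.0, Y - 32.0)
        rim = np.unravel_index(np.argmin(np.abs(r - 20.0)), r.shape)
        assert abs(circle_state.c_tub[rim]
                   - 0.5 * (1 + np.tanh((20.0 - r[rim]) / 2))) < 1e-12
        center = np.unravel_index(np.argmin(r), r.shape)
        assert abs(circle_state.c_tub[center] - 1.0) < 1e-8

    def test_phi_is_one_inside_zero_outside(self, circle_state, grid64):
        X, Y = np.meshgrid(grid64.greville_u, grid64.greville_v, indexing="ij")
        r = np.hypot(X - 32.0, Y - 32.0)
        assert circle_state.phi[r < 14].min() > 0.99
        assert circle_state.phi[r > 26].max() < 0.01
        assert np.array_equal(circle_state.phi0 > 0.5, r < 20.0)

    def test_seeded_theta_reproducible(self, params, grid64):
        a = gm.initialize_state(params, [(32.0, 32.0)], grid64)
        b = gm.initialize_state(params, [(32.0, 32.0)], grid64)
        assert np.array_equal(a.theta, b.theta)

    def test_overlapping_circles_rejected(self, params, grid64):
        g = bsc.build_collocation_grid(120, 120)
        with pytest.raises(ConfigurationError):
            gm.initialize_state(params, [(40.0, 60.0), (70.0, 60.0)], g)

    def test_circle_must_fit_domain(self, params, grid64):
        with pytest.raises(ConfigurationError):
            gm.initialize_state(params, [(10.0, 32.0)], grid64)

    def test_source_needs_an_interface(self, grid64):
        with pytest.raises(InitializationError):
            gm.compute_tubulin_source(grid64, np.ones(grid64.shape), 1.0)


class TestOrientationAndAnisotropy:
    def test_axis_aligned_normals(self):
        one = np.ones((3, 3))
        zero = np.zeros((3, 3))
        assert np.allclose(gm.interface_orientation(one, zero), 0.0)
        assert np.allclose(gm.interface_orientation(zero, one), np.pi / 2)

    def test_degenerate_gradient_convention(self):
        psi = gm.interface_orientation(np.zeros((2, 2)), np.zeros((2, 2)))
        assert np.all(psi == 0.0)

    def test_isotropic_limit(self):
        aniso = gm.AnisotropyParams(a_bar=0.7, delta_aniso=0.0)
        a, dap = gm.anisotropy_coefficient(np.linspace(0, 6, 50), aniso)
        assert np.allclose(a, 0.7) and np.allclose(dap, 0.0)

    def test_cosine_extremum(self):
        aniso = gm.AnisotropyParams(a_bar=1.0, delta_aniso=0.3, j_fold=6,
                                    theta_offset=0.4)
        a, dap = gm.anisotropy_coefficient(np.array([0.4]), aniso)
        assert abs(a[0] - 1.3) < 1e-14 and abs(dap[0]) < 1e-12

    def test_analytic_derivative_matches_finite_difference(self):
        aniso = gm.AnisotropyParams(a_bar=0.8, delta_aniso=0.25, j_fold=6)
        psi = np.linspace(-2, 2, 11)
        h = 1e-6
        _, dap = gm.anisotropy_coefficient(psi, aniso)
        ap, _ = gm.anisotropy_coefficient(psi + h, aniso)
        am, _ = gm.anisotropy_coefficient(psi - h, aniso)
        assert np.abs(dap - (ap - am) / (2 * h)).max() < 1e-6

    def test_unit_anisotropy_strength_rejected(self):
        with pytest.raises(ParameterError):
            gm.anisotropy_coefficient(np.zeros(3),
                                      gm.AnisotropyParams(delta_aniso=1.0))


@pytest.mark.parametrize("c,r,s,expected", [
    (0.5, 2.0, 1.0, 0.0),      # assembly balances disassembly
    (3.0, 0.0, 0.0, 0.0),
    (3.0, 2.0, 1.0, 5.0),
])
def test_neurite_extension_rate(c, r, s, expected):
    assert gm.neurite_extension_rate(c, r, s) == pytest.approx(expected)


class TestDrivingForce:
    def _tip(self, pos, c, r, s):
        return Tip(position=pos, neuron_id=1, neurite_id=1,
                   geodesic_length=10.0, c_tub_local=c, rate_r=r, rate_s=s)

    def test_inhibited_tip_zone_is_exactly_zero(self, circle_state, params):
        tip = self._tip((30, 30), c=0.01, r=1.0, s=1.0)   # r c < s
        E = gm.compute_driving_force(circle_state, [tip], params)
        assert np.all(E == 0.0)

    def test_support_is_union_of_zones(self, circle_state, params):
        tips = [self._tip((20, 20), 0.8, 10.0, 0.1),
                self._tip((45, 40), 0.8, 10.0, 0.1)]
        E = gm.compute_driving_force(circle_state, tips, params)
        zones = np.zeros(E.shape, dtype=bool)
        for t in tips:
            i, j = t.zone_center
            zones[i - 3:i + 3, j - 3:j + 3] = True
        assert np.all(E[~zones] == 0.0)
        assert np.count_nonzero(E) == 72   # two full 6x6 zones

    def test_saturates_at_alpha_over_two(self, circle_state, params):
        big = params.with_overrides(gamma=1e9)
        tip = self._tip((30, 30), 0.8, 10.0, 0.1)
        E = gm.compute_driving_force(circle_state, [tip], big)
        assert abs(E.max() - params.alpha_E / 2) < 1e-6


class TestPhaseFieldRhs:
    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_pure_phases_are_stationary(self, grid64, params, value):
        phi = np.full(grid64.shape, value)
        gtm = np.random.default_rng(0).uniform(0.5, 1.5, grid64.shape)
        rhs = gm.phase_field_rhs(phi, grid64, params,
                                 np.zeros(grid64.shape), gtm)
        assert np.abs(rhs).max() < 1e-10

    def test_half_phase_stationary_with_uniform_theta(self, grid64, params):
        phi = np.full(grid64.shape, 0.5)
        rhs = gm.phase_field_rhs(phi, grid64, params,
                                 np.zeros(grid64.shape),
                                 np.zeros(grid64.shape))
        assert np.abs(rhs).max() < 1e-10

    def test_isotropic_rhs_matches_analytic_manufactured_solution(self):
        """Smooth manufactured phi, isotropic coefficient: the collocated
        rhs converges (second order) to the analytic expression."""
        errs = []
        for n in (24, 48):
            h = 24.0 / (n - 3)
            g = bsc.build_collocation_grid(n, n, spacing=h)
            p = gm.ModelParameters(
                anisotropy=gm.AnisotropyParams(a_bar=0.8, delta_aniso=0.0),
                H_const=0.0)
            X, Y = np.meshgrid(g.greville_u, g.greville_v, indexing="ij")
            L = 24.0
            phi = 0.25 + 0.5 * np.sin(np.pi * X / L) * np.sin(np.pi * Y / L)
            lap = -2 * (np.pi / L) ** 2 * (phi - 0.25)
            expected = p.m_phi * (0.8 ** 2 * lap
                                  + phi * (1 - phi) * (phi - 0.5))
            rhs = gm.phase_field_rhs(phi, g, p, np.zeros(g.shape),
                                     np.zeros(g.shape))
            errs.append(np.abs(rhs - expected).max())
        assert errs[1] < errs[0] / 3.5   # ~second-order decay

    def test_blowup_raises_with_iteration_context(self, grid64, params):
        phi = np.full(grid64.shape, np.nan)
        with pytest.raises(gm.NumericalBlowupError) as err:
            gm.phase_field_rhs(phi, grid64, params, np.zeros(grid64.shape),
                               np.zeros(grid64.shape), iteration=7)
        assert err.value.iteration == 7


class TestTubulinRhs:
    def test_zero_source_zero_concentration(self, grid64, circle_state):
        p = gm.ModelParameters(tubulin=gm.TubulinParams(eps0=0.0))
        rhs = gm.tubulin_rhs(circle_state.phi, np.zeros(grid64.shape),
                             grid64, p, np.zeros(grid64.shape))
        assert np.abs(rhs).max() < 1e-12

    def test_source_self_normalizes_to_eps0(self, grid64, params, rng):
        """Discrete integral of the production term equals eps0 exactly,
        whatever the initial interface looks like."""
        X, Y = np.meshgrid(grid64.greville_u, grid64.greville_v, indexing="ij")
        for k in range(3):
            cx, cy = rng.uniform(20, 40, 2)
            rad = rng.uniform(8, 15)
            phi0 = 0.5 * (1 + np.tanh((rad - np.hypot(X - cx, Y - cy)) / 2))
            src = gm.compute_tubulin_source(grid64, phi0, eps0=2.0)
            assert abs(src.sum() * grid64.spacing ** 2 - 2.0) < 1e-12

    def test_uniform_phase_reduces_to_decay_plus_source(self, grid64):
        p = gm.ModelParameters(tubulin=gm.TubulinParams(
            delta_t=3.7, beta_t=0.25, alpha_t=(0.0, 0.0), alpha_radial=0.0))
        phi = np.ones(grid64.shape)
        c = np.full(grid64.shape, 0.6)
        src = np.full(grid64.shape, 0.123)
        rhs = gm.tubulin_rhs(phi, c, grid64, p, src)
        assert np.abs(rhs - (-0.25 * 0.6 + 0.123)).max() < 1e-9


class TestUndercooling:
    def test_uniform_temperature_is_steady(self, grid64, params):
        T = np.full(grid64.shape, 0.4)
        T2 = gm.evolve_undercooling(T, np.zeros(grid64.shape), grid64, params)
        assert np.abs(T2 - 0.4).max() < 1e-9

    def test_uniform_latent_heat_shifts_temperature(self, grid64, params):
        T = np.full(grid64.shape, 0.2)
        c = 0.05
        dphi = np.full(grid64.shape, c * params.dt)
        T2 = gm.evolve_undercooling(T, dphi, grid64, params)
        expected = 0.2 + params.temperature.k_latent * c * params.dt
        assert np.abs(T2 - expected).max() < 1e-9

    def test_manufactured_heat_mode_decays(self, params):
        """Neumann-compatible cosine mode decays at the analytic rate to
        O(dt) (implicit Euler)."""
        n = 35
        h = 1.0 / (n - 3)
        g = bsc.build_collocation_grid(n, n, spacing=h)
        X, Y = np.meshgrid(g.greville_u, g.greville_v, indexing="ij")
        T0 = np.cos(np.pi * X) * np.cos(np.pi * Y)
        lam = 2 * np.pi ** 2
        T1 = gm.evolve_undercooling(T0, np.zeros(g.shape), g, params)
        exact_step = T0 / (1.0 + params.dt * lam)   # implicit Euler mode decay
        assert np.abs(T1 - exact_step).max() < 5e-3


class TestThetaNoise:
    def test_deterministic_and_in_unit_interval(self):
        u = np.linspace(0, 50, 151)
        v = np.linspace(0, 40, 121)
        U, V = np.meshgrid(u, v, indexing="ij")
        a = gm.theta_noise(7, U, V)
        b = gm.theta_noise(7, U, V)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() < 1.0
        assert not np.array_equal(a, gm.theta_noise(8, U, V))

    def test_position_keyed_subgrid_consistency(self):
        """The value at a physical point is independent of the grid window."""
        u = np.arange(0, 30, dtype=float)
        big = gm.theta_noise(3, *np.meshgrid(u, u, indexing="ij"))
        sub = gm.theta_noise(3, *np.meshgrid(u[10:], u[5:], indexing="ij"))
        assert np.array_equal(big[10:, 5:], sub)


def test_tip_tubulin_sampling_statistics(circle_state, params):
    tip = Tip(position=(32, 32), neuron_id=1, neurite_id=1,
              geodesic_length=0.0)
    c = circle_state.c_tub
    at_tip = gm.tip_tubulin(c, tip, params.with_overrides(
        tip_tubulin_stat="tip"))
    zmax = gm.tip_tubulin(c, tip, params)
    zmean = gm.tip_tubulin(c, tip, params.with_overrides(
        tip_tubulin_stat="zone_mean"))
    assert at_tip == pytest.approx(float(c[32, 32]))
    assert zmax >= zmean and zmax >= at_tip - 1e-12
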