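"""Implicit Euler stepping, domain extension, and the staged run loop."""

import numpy as np
import pytest

from neurongrowth import bspline_collocation as bsc
from neurongrowth import growth_model as gm
from neurongrowth import time_integrator as ti
from neurongrowth.config import RunConfig
from neurongrowth.errors import NonConvergenceError
from neurongrowth.growth_model import ModelParameters, StageSchedule


def make_state(grid, phi, params, c_tub=None):
    """Minimal state around a given phase field (no somas needed)."""
    shape = grid.shape
    phi0 = 0.5 * (1 + np.tanh(
        (10.0 - np.hypot(*[g - g.mean() for g in np.meshgrid(
            grid.greville_u, grid.greville_v, indexing="ij")])) / 1.5))
    return gm.SimulationState(
        phi=phi.copy(), phi0=phi0,
        theta=np.zeros(shape), grad_theta_mag=np.zeros(shape),
        c_tub=np.zeros(shape) if c_tub is None else c_tub,
        temp=np.full(shape, params.temperature.t_init),
        E_field=np.zeros(shape),
        tubulin_source=gm.compute_tubulin_source(grid, phi0,
                                                 params.tubulin.eps0),
        neuron_labels=np.zeros(shape, dtype=np.int32),
        soma_centers=np.array([[grid.greville_u.mean(),
                                grid.greville_v.mean()]]),
    )


class TestImplicitEulerStep:
    def test_uniform_phase_is_a_fixed_point(self, grid64, params):
        state = make_state(grid64, np.ones(grid64.shape), params)
        integ = ti.TimeIntegrator(grid64, params)
        out = integ.step(state)
        assert np.abs(out.phi - 1.0).max() < 1e-12
        assert integ.newton_history[-1] <= 1   # zero residual at the guess

    def test_converged_residual_below_tolerance(self, params, circle_state,
                                                grid64):
        integ = ti.TimeIntegrator(grid64, params)
        for _ in range(5):
            integ.step(circle_state)
        assert all(r < 1e-4 for r in integ.residual_history)

    def test_linear_configuration_converges_in_one_iteration(self):
        """With the reaction off and isotropic coefficients the problem is
        linear and the first Newton update solves it exactly."""
        n = 35
        g = bsc.build_collocation_grid(n, n, spacing=1.0 / (n - 3))
        p = ModelParameters(
            m_phi=1.0, reaction_scale=0.0,
            anisotropy=gm.AnisotropyParams(a_bar=1.0, delta_aniso=0.0),
            dt=0.005)
        X, Y = np.meshgrid(g.greville_u, g.greville_v, indexing="ij")
        phi = 0.5 + 0.3 * np.cos(np.pi * X) * np.cos(np.pi * Y)
        state = make_state(g, phi, p)
        integ = ti.TimeIntegrator(g, p)
        integ.step(state)
        assert integ.newton_history[-1] == 1

    def test_pure_diffusion_matches_analytic_decay_first_order(self):
        """Manufactured cosine mode: implicit Euler error shrinks ~O(dt)."""
        n = 35
        g = bsc.build_collocation_grid(n, n, spacing=1.0 / (n - 3))
        lam = 2 * np.pi ** 2
        X, Y = np.meshgrid(g.greville_u, g.greville_v, indexing="ij")
        mode = np.cos(np.pi * X) * np.cos(np.pi * Y)
        t_final = 0.02
        errs = []
        for dt in (0.005, 0.0025):
            p = ModelParameters(
                m_phi=1.0, reaction_scale=0.0,
                anisotropy=gm.AnisotropyParams(a_bar=1.0, delta_aniso=0.0),
                dt=dt)
            state = make_state(g, 0.5 + 0.3 * mode, p)
            integ = ti.TimeIntegrator(g, p)
            for _ in range(round(t_final / dt)):
                integ.step(state)
            exact = 0.5 + 0.3 * np.exp(-lam * t_final) * mode
            errs.append(np.abs(state.phi - exact).max())
        order = np.log2(errs[0] / errs[1])
        assert order >= 0.8, (errs, order)

    def test_newton_residuals_strictly_decrease(self, params, grid64,
                                                circle_state):
        """On a smooth configuration the residual sequence contracts."""
        integ = ti.TimeIntegrator(grid64, params)
        integ.step(circle_state)   # develop a smooth interface
        C = bsc.values_to_coefficients(grid64, circle_state.phi)
        frozen = None
        norms = []
        for _ in range(4):
            R, jac = integ._phi_residual(C, circle_state.phi,
                                         circle_state.E_field,
                                         circle_state.grad_theta_mag,
                                         frozen_aux=frozen)
            if frozen is None:
                frozen = (jac[0], jac[1], jac[2], None, None)
            norms.append(float(np.max(np.abs(R))))
            integ._assemble_phi_jacobian(*jac)
            C = C + integ._phi_lu.solve(-R).reshape(grid64.shape)
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_nonconvergence_raises_with_context(self, params, grid64,
                                                circle_state):
        settings = ti.SolverSettings(newton_max_iters=0)
        with pytest.raises(NonConvergenceError) as err:
            ti.implicit_euler_step(circle_state, grid64, params, settings)
        assert err.value.residual is not None

    def test_functional_wrapper_leaves_input_untouched(self, params, grid64,
                                                       circle_state):
        before = circle_state.phi.copy()
        out = ti.implicit_euler_step(circle_state, grid64, params)
        assert np.array_equal(circle_state.phi, before)
        assert out.iteration == circle_state.iteration + 1


class TestDomainExtension:
    @pytest.fixture()
    def grown(self, params):
        grid = bsc.build_collocation_grid(80, 80)
        state = gm.initialize_state(params, [(38.0, 38.0)], grid)
        integ = ti.TimeIntegrator(grid, params)
        for _ in range(10):
            integ.step(state)
        return state, grid

    @staticmethod
    def shared_indices(old_pts, new_pts):
        return ([i for i, u in enumerate(old_pts)
                 if np.any(np.abs(new_pts - u) < 1e-12)],
                [int(np.argmin(np.abs(new_pts - u))) for u in old_pts
                 if np.any(np.abs(new_pts - u) < 1e-12)])

    def test_no_flagged_side_is_identity(self, grown, params):
        state, grid = grown
        s2, g2 = ti.extend_domain(state, grid, params, sides=set())
        assert s2 is state and g2 is grid

    def test_right_extension_preserves_fields_at_shared_points(self, grown,
                                                               params):
        state, grid = grown
        s2, g2 = ti.extend_domain(state, grid, params, sides={"u_hi"})
        assert g2.nu == grid.nu + 10 and g2.nv == grid.nv
        oi, ni = self.shared_indices(grid.greville_u, g2.greville_u)
        assert len(oi) >= grid.nu - 2
        for name in ("phi", "c_tub", "temp"):
            old = getattr(state, name)[oi, :]
            new = getattr(s2, name)[ni, :]
            assert np.abs(old - new).max() < 1e-10, name

    def test_theta_reproduced_bit_for_bit(self, grown, params):
        state, grid = grown
        s2, g2 = ti.extend_domain(state, grid, params, sides={"u_lo", "v_hi"})
        oi, ni = self.shared_indices(grid.greville_u, g2.greville_u)
        oj, nj = self.shared_indices(grid.greville_v, g2.greville_v)
        assert np.array_equal(state.theta[np.ix_(oi, oj)],
                              s2.theta[np.ix_(ni, nj)])

    def test_successive_extensions_commute_with_double(self, grown, params):
        state, grid = grown
        a1, ga1 = ti.extend_domain(state, grid, params, sides={"u_hi"})
        a2, ga2 = ti.extend_domain(a1, ga1, params, sides={"u_hi"})
        b, gb = ti.extend_domain(state, grid, params, sides={"u_hi"},
                                 width=20)
        assert ga2.shape == gb.shape
        assert np.abs(a2.phi - b.phi).max() < 1e-10
        assert np.abs(a2.c_tub - b.c_tub).max() < 1e-10
        assert np.array_equal(a2.theta, b.theta)

    def test_component_count_is_conserved(self, grown, params):
        from scipy import ndimage
        state, grid = grown
        s2, _ = ti.extend_domain(state, grid, params,
                                 sides={"u_lo", "u_hi", "v_lo", "v_hi"})
        _, n_before = ndimage.label(state.phi > 0.5, np.ones((3, 3)))
        _, n_after = ndimage.label(s2.phi > 0.5, np.ones((3, 3)))
        assert n_before == n_after

    def test_sides_from_boundary_proximity(self, grown):
        from neurongrowth.neurite_topology import Tip
        _, grid = grown
        tips = [Tip(position=(grid.nu - 4, 40), neuron_id=1, neurite_id=1,
                    geodesic_length=1.0)]
        assert ti.sides_to_extend(tips, grid, margin=10) == {"u_hi"}
        assert ti.sides_to_extend(tips, grid, margin=10,
                                  all_directions=True) == \
            {"u_lo", "u_hi", "v_lo", "v_hi"}
        far = [Tip(position=(40, 40), neuron_id=1, neurite_id=1,
                   geodesic_length=1.0)]
        assert ti.sides_to_extend(far, grid, margin=10) == set()


class TestTipTracker:
    def _tip(self, pos):
        from neurongrowth.neurite_topology import Tip
        return Tip(position=pos, neuron_id=1, neurite_id=0,
                   geodesic_length=1.0)

    def test_identity_persists_across_detections(self, grid64):
        tracker = ti.TipTracker(match_radius=6.0)
        t1 = [self._tip((10, 10)), self._tip((40, 40))]
        born = tracker.update(t1, grid64)
        assert born == [1, 2]
        t2 = [self._tip((42, 41)), self._tip((11, 12))]   # shuffled, moved
        born = tracker.update(t2, grid64)
        assert born == []
        assert t2[0].neurite_id == 2 and t2[1].neurite_id == 1

    def test_distant_tip_is_a_birth(self, grid64):
        tracker = ti.TipTracker(match_radius=6.0)
        tracker.update([self._tip((10, 10))], grid64)
        born = tracker.update([self._tip((10, 10)), self._tip((50, 50))],
                              grid64)
        assert born == [2]

    def test_heading_points_along_motion(self, grid64):
        tracker = ti.TipTracker(match_radius=6.0, heading_window=5)
        tip = None
        for k in range(4):
            tip = self._tip((10 + 3 * k, 10))
            tracker.update([tip], grid64)
        assert tip.heading is not None
        np.testing.assert_allclose(tip.heading, [1.0, 0.0], atol=1e-12)


class TestRunSimulation:
    def test_zero_iterations_returns_initial_snapshot_only(self):
        cfg = RunConfig(nu=64, nv=64, centers=[[32.0, 32.0]],
                        params=ModelParameters(
                            schedule=StageSchedule(0, 0, 0, 0)))
        res = ti.run_simulation(cfg)
        assert len(res.snapshots) == 1
        assert res.snapshots[0]["iteration"] == 0

    def test_bit_identical_reruns(self):
        """Same config + seed twice: identical event logs and final fields."""
        def go():
            cfg = RunConfig(nu=64, nv=64, centers=[[32.0, 32.0]],
                            params=ModelParameters(
                                schedule=StageSchedule(15, 30, 45, 60)),
                            snapshot_every=30, retip_every=10)
            return ti.run_simulation(cfg)

        r1, r2 = go(), go()
        assert r1.event_log_json() == r2.event_log_json()
        assert np.array_equal(r1.state.phi, r2.state.phi)
        assert np.array_equal(r1.state.c_tub, r2.state.c_tub)
        assert np.array_equal(r1.state.temp, r2.state.temp)

    def test_different_seeds_diverge(self):
        def go(seed):
            cfg = RunConfig(nu=64, nv=64, centers=[[32.0, 32.0]],
                            params=ModelParameters(
                                rng_seed=seed,
                                schedule=StageSchedule(10, 20, 30, 40)),
                            snapshot_every=0, retip_every=10)
            return ti.run_simulation(cfg)

        assert not np.array_equal(go(0).state.phi, go(1).state.phi)
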