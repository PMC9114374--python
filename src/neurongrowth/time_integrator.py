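"""Implicit time integration and orchestration of the staged growth run.

The collocated strong form is advanced with implicit Euler.  Each step
solves ``R(phi_new) = phi_new - phi_old - dt * rhs(phi_new) = 0`` with a
Newton iteration whose Jacobian uses the analytic reaction derivative and
lagged anisotropy coefficients (frozen within the linear solve); the sparse
LU factorization is reused across steps and refreshed on a fixed cadence or
when convergence slows, so the exact residual always decides convergence.
Tubulin is then advanced implicitly in its linear transport terms with the
new phase field, and finally the undercooling temperature.

Boundary collocation equations are replaced by zero normal derivative
(homogeneous Neumann) rows, closing the domain to tubulin and heat flux.

The domain is extended by a fixed number of grid points per flagged
direction whenever a neurite tip approaches the boundary, transferring all
fields exactly at pre-existing collocation points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, bicgstab

from . import growth_model as gm
from . import neurite_topology as nt
from .bspline_collocation import (
    CollocationGrid,
    build_collocation_grid,
    collocation_matrix,
    coefficients_to_values,
    field_derivatives,
    values_to_coefficients,
)
from .errors import ConfigurationError, NonConvergenceError
from .growth_model import (
    ModelParameters,
    SimulationState,
    StageSchedule,  # noqa: F401  (re-exported: schedule type lives with the model)
    compute_tubulin_source,
    theta_noise,
)

__all__ = [
    "SolverSettings", "StageSchedule", "TimeIntegrator", "TipTracker",
    "implicit_euler_step", "extend_domain", "run_simulation",
    "SimulationResult", "make_heat_solver",
]


@dataclass(frozen=True)
class SolverSettings:
    """Newton / linear solver settings.

    ``newton_tol`` is the residual infinity-norm tolerance of the nonlinear
    solve (default 1e-4).  ``lagged_anisotropy`` freezes a(psi) and its
    derivative at the previous iterate inside the linear solve (the
    residual is always exact).
    """
    newton_tol: float = 1e-4
    newton_max_iters: int = 24
    lagged_anisotropy: bool = True
    jac_refresh_every: int = 1
    linear_rtol: float = 1e-10

    def __post_init__(self):
        if self.newton_tol <= 0:
            raise ConfigurationError("newton_tol must be > 0")


# --------------------------------------------------------------------------
# boundary rows
# --------------------------------------------------------------------------

def _boundary_parts(grid: CollocationGrid):
    """Boundary mask and the Neumann replacement operator.

    Edge rows in u get a d/du row, edge rows in v a d/dv row, corners the
    sum of both.  Returns ``(bmask_flat, wu, wv, B, Zi)`` where ``Zi``
    zeroes boundary rows and ``B`` holds the replacement rows.
    """
    nu, nv = grid.shape
    # outward-normal orientation: with same-sign weights the corner rows
    # (Du + Dv) cancel the corner coefficient and leave the system
    # near-singular
    wu = np.zeros((nu, nv))
    wv = np.zeros((nu, nv))
    wu[0, :], wu[-1, :] = -1.0, 1.0
    wv[:, 0], wv[:, -1] = -1.0, 1.0
    bmask = (np.abs(wu) + np.abs(wv)) > 0
    B = (sp.diags(wu.ravel()) @ grid.Du + sp.diags(wv.ravel()) @ grid.Dv)
    Zi = sp.diags((~bmask).astype(float).ravel())
    return bmask.ravel(), wu, wv, B.tocsr(), Zi.tocsr()


def make_heat_solver(grid: CollocationGrid, dt: float):
    """Prefactorized implicit Euler solver for ``dT/dt = lap T`` with
    Neumann boundaries; returns ``solve(rhs_values) -> new values``."""
    bmask, _, _, B, Zi = _boundary_parts(grid)
    Lap = grid.Duu + grid.Dvv
    A = (Zi @ (grid.N - dt * Lap) + B).tocsc()
    lu = splu(A, permc_spec="MMD_AT_PLUS_A")

    def solve(rhs_values: np.ndarray) -> np.ndarray:
        b = rhs_values.ravel().copy()
        b[bmask] = 0.0
        q = lu.solve(b).reshape(grid.shape)
        return coefficients_to_values(grid, q)

    return solve


# --------------------------------------------------------------------------
# the integrator
# --------------------------------------------------------------------------

class TimeIntegrator:
    """Advances one state through implicit Euler steps on a fixed grid."""

    def __init__(self, grid: CollocationGrid, params: ModelParameters,
                 settings: SolverSettings | None = None):
        self.grid = grid
        self.params = params
        self.settings = settings or SolverSettings()
        self.bmask, self.wu, self.wv, self.B, self.Zi = _boundary_parts(grid)
        self.Lap = (grid.Duu + grid.Dvv).tocsr()
        self._heat = make_heat_solver(grid, params.dt)
        self._phi_lu = None
        self._phi_lu_age = 0
        self._alpha_field = None   # active-transport velocity (lazy, needs somas)
        self.newton_history: list[int] = []
        self.residual_history: list[float] = []

    # -- phase field -------------------------------------------------------

    def _phi_residual(self, C: np.ndarray, phi_old: np.ndarray,
                      E: np.ndarray, gtm: np.ndarray, frozen_aux=None):
        grid, p = self.grid, self.params
        rhs, aux, (f, m) = gm.phase_field_rhs(
            None, grid, p, E, gtm, phi_coeff=C, return_aux=True,
            frozen_aux=frozen_aux)
        R = f - phi_old - p.dt * rhs
        fx = grid._dD1u @ (C @ grid._dNv.T)
        fy = grid._dNu @ (C @ grid._dD1v.T)
        Rb = self.wu * fx + self.wv * fy
        Rf = R.ravel()
        Rf[self.bmask] = Rb.ravel()[self.bmask]
        a2, cx, cy, _, _ = aux
        fp = p.reaction_scale * ((1.0 - 2.0 * f) * m + f * (1.0 - f))
        return Rf, (a2, cx, cy, fp)

    def _assemble_phi_jacobian(self, a2, cx, cy, fp):
        grid, p = self.grid, self.params
        L = (sp.diags(a2.ravel()) @ self.Lap
             + sp.diags(cx.ravel()) @ grid.Du
             + sp.diags(cy.ravel()) @ grid.Dv
             + sp.diags(fp.ravel()) @ grid.N)
        J = self.Zi @ (grid.N - p.dt * p.m_phi * L) + self.B
        self._phi_lu = splu(J.tocsc(), permc_spec="MMD_AT_PLUS_A")
        self._phi_lu_age = 0

    def _phi_step(self, state: SimulationState):
        s = self.settings
        grid = self.grid
        phi_old = state.phi
        C = values_to_coefficients(grid, phi_old)
        need_assemble = (self._phi_lu is None
                         or self._phi_lu_age >= s.jac_refresh_every)
        iters = 0
        frozen_aux = None
        while True:
            R, jac_parts = self._phi_residual(
                C, phi_old, state.E_field, state.grad_theta_mag,
                frozen_aux=frozen_aux)
            if frozen_aux is None and self.settings.lagged_anisotropy:
                # anisotropy coefficients evaluated at the start-of-step
                # field and held fixed for the rest of the step
                frozen_aux = (jac_parts[0], jac_parts[1], jac_parts[2],
                              None, None)
            rnorm = float(np.max(np.abs(R)))
            if rnorm < s.newton_tol:
                break
            if iters >= s.newton_max_iters:
                raise NonConvergenceError(
                    f"Newton stalled at residual {rnorm:.3e} after "
                    f"{iters} iterations", residual=rnorm,
                    iteration=state.iteration)
            # refresh the factorization mid-step if the chord phase drags
            if need_assemble or iters in (10, 16):
                self._assemble_phi_jacobian(*jac_parts)
                need_assemble = False
            delta = self._phi_lu.solve(-R)
            C = C + delta.reshape(grid.shape)
            iters += 1
        self._phi_lu_age += 1
        self.newton_history.append(iters)
        self.residual_history.append(rnorm)
        phi_new = coefficients_to_values(grid, C)
        return phi_new, C, iters, rnorm

    # -- tubulin -----------------------------------------------------------

    def _tubulin_step(self, state: SimulationState, phi_new: np.ndarray,
                      phi_new_coeff: np.ndarray):
        grid, p = self.grid, self.params
        tb = p.tubulin
        dt = p.dt
        f, px, py, _, _ = field_derivatives(grid, phi_new_coeff)
        pf, pxf, pyf = f.ravel(), px.ravel(), py.ravel()
        A_mass = sp.diags(pf) @ grid.N
        # sink pieces are kept separately so the conservative correction
        # below can account for them exactly as discretized
        A_sink = dt * tb.beta_t * A_mass
        A = (A_mass + A_sink
             - dt * tb.delta_t * (sp.diags(pf) @ self.Lap
                                  + sp.diags(pxf) @ grid.Du
                                  + sp.diags(pyf) @ grid.Dv))
        if self._alpha_field is None:
            ax0, ay0 = tb.alpha_t
            ax = np.full(grid.shape, float(ax0))
            ay = np.full(grid.shape, float(ay0))
            if tb.alpha_radial != 0.0:
                rx, ry = gm.radial_transport_field(grid, state.soma_centers,
                                                   tb.alpha_radial)
                ax, ay = ax + rx, ay + ry
            self._alpha_field = (ax, ay)
        ax, ay = self._alpha_field
        if np.any(ax != 0.0) or np.any(ay != 0.0):
            gate = np.clip(pf, 0.0, 1.0)   # cytoplasm-gated transport
            axf, ayf = ax.ravel() * gate, ay.ravel() * gate
            A_adv = dt * (sp.diags(axf * pf) @ grid.Du
                          + sp.diags(axf * pxf) @ grid.N
                          + sp.diags(ayf * pf) @ grid.Dv
                          + sp.diags(ayf * pyf) @ grid.N)
            A_sink = A_sink + A_adv
            A = A + A_adv
        # pin c_tub to zero in the extracellular region (keeps the system
        # nonsingular where phi vanishes; the sink this adds at the
        # interface is O(reg) and negligible against the source)
        A_reg = tb.reg * sp.diags(np.clip(1.0 - pf, 0.0, None)) @ grid.N
        A = A + A_reg   # regularization, not physics: the conservative
        #                 correction compensates its spurious sink
        A = (self.Zi @ A + self.B).tocsr()
        b = (state.phi * state.c_tub + dt * state.tubulin_source).ravel()
        b0 = b.copy()
        b[self.bmask] = 0.0
        # pin c_tub to zero outside the cell support: c = w / phi is
        # ill-posed as phi -> 0 and otherwise feeds back into the interior
        # through the smooth spline basis
        ext = None
        if tb.support_floor > 0.0:
            ext = pf < tb.support_floor
            Ze = sp.diags((~ext).astype(float))
            A = (Ze @ A + sp.diags(ext.astype(float)) @ grid.N).tocsr()
            b[ext] = 0.0
        x0 = values_to_coefficients(grid, state.c_tub).ravel()
        d = A.diagonal()
        Minv = sp.diags(1.0 / np.where(np.abs(d) > 1e-300, d, 1.0))
        x, info = bicgstab(A, b, x0=x0, rtol=self.settings.linear_rtol,
                           atol=1e-13, M=Minv, maxiter=400)
        if info != 0:
            x = splu(A.tocsc(), permc_spec="MMD_AT_PLUS_A").solve(b)
        if tb.conserve_mass:
            # global conservative correction: strong-form collocation does
            # not conserve the discrete point-sum of phi*c_tub (the
            # divergence quadrature drifts at interface scale), so the
            # solution is rescaled to satisfy the exact interior balance
            # mass_new = mass_old + dt*eps0 - (decay + advection as
            # discretized); diffusion through the closed boundary and the
            # artificial pin-down contribute nothing in the continuum
            nb = ~self.bmask
            interior = nb if ext is None else nb & ~ext
            # the target folds the mass the extracellular clamp discards
            # (initial tail, production under the clamp) back into the
            # cell: tubulin cannot live outside the support
            m_new = float((A_mass @ x)[nb].sum())
            sinks = float((A_sink @ x)[interior].sum())
            target = float(b0[nb].sum()) - sinks
            if m_new > 1e-12 and target > 0.0:
                # clamp the factor: the correction repairs slow quadrature
                # drift, it must never feed back through the advective
                # term's own grid-scale noise
                x = x * float(np.clip(target / m_new, 0.999, 1.001))
        Q = x.reshape(grid.shape)
        c_new = coefficients_to_values(grid, Q)
        # mass-neutral positivity projection: clip the small negative
        # excursions the smooth basis produces at the cell edge, then
        # rescale the positive part so the total phi-weighted mass the
        # solve produced is preserved exactly
        clipped = np.maximum(c_new, 0.0)
        added = float((f * (clipped - c_new)).sum())
        pos_mass = float((f * clipped).sum())
        if added > 0.0 and pos_mass > added:
            clipped *= 1.0 - added / pos_mass
        return clipped

    # -- one full step -----------------------------------------------------

    def step(self, state: SimulationState,
             conflict_mask: np.ndarray | None = None) -> SimulationState:
        """Advance ``state`` in place by one dt (phi, then tubulin, then
        temperature); returns the state for convenience.

        ``state.E_field`` must be current; ``conflict_mask`` (optional)
        suppresses phase growth on same-neuron merge lines.
        """
        phi_old = state.phi
        phi_new, C, iters, rnorm = self._phi_step(state)
        if conflict_mask is not None and conflict_mask.any():
            grew = conflict_mask & (phi_new > phi_old)
            if grew.any():
                phi_new = np.where(grew, phi_old, phi_new)
                C = values_to_coefficients(self.grid, phi_new)
        c_new = self._tubulin_step(state, phi_new, C)
        dphi = phi_new - phi_old
        rhs_T = state.temp + self.params.temperature.k_latent * dphi
        state.temp = self._heat(rhs_T)
        state.phi = phi_new
        state.c_tub = c_new
        state.iteration += 1
        state.last_newton_iters = iters
        state.last_newton_residual = rnorm
        return state


def implicit_euler_step(state: SimulationState, grid: CollocationGrid,
                        params: ModelParameters,
                        settings: SolverSettings | None = None) -> SimulationState:
    """Single implicit Euler step on a copy of ``state``.

    Functional convenience wrapper around :class:`TimeIntegrator` (which
    callers should use directly for long runs, to reuse factorizations).

    Raises
    ------
    NonConvergenceError
        If Newton fails to reach the residual tolerance.
    """
    integ = TimeIntegrator(grid, params, settings)
    return integ.step(state.copy())


# --------------------------------------------------------------------------
# multi-resolution domain extension
# --------------------------------------------------------------------------

def sides_to_extend(tips, grid: CollocationGrid, margin: int = 10,
                    all_directions: bool = False):
    """Directions in which a tip is within ``margin`` points of the boundary."""
    nu, nv = grid.shape
    sides = set()
    for tip in tips:
        i, j = tip.position
        if i < margin:
            sides.add("u_lo")
        if i >= nu - margin:
            sides.add("u_hi")
        if j < margin:
            sides.add("v_lo")
        if j >= nv - margin:
            sides.add("v_hi")
    if sides and all_directions:
        sides = {"u_lo", "u_hi", "v_lo", "v_hi"}
    return sides


def extend_domain(state: SimulationState, grid: CollocationGrid,
                  params: ModelParameters, sides,
                  width: int = 10):
    """Enlarge the domain by ``width`` knot spacings per flagged side.

    All fields are transferred by evaluating the old spline; values at
    pre-existing collocation points are preserved exactly (interpolation
    identity).  New points are initialized to extracellular values
    (phi = 0, c_tub = 0, temperature = t_init); theta at new points comes
    from the position-keyed seeded stream, so successive extensions commute
    with a single wider extension.

    Returns ``(state', grid')`` (the inputs unchanged if ``sides`` is empty).
    """
    sides = set(sides)
    if not sides:
        return state, grid
    h = grid.spacing
    nu, nv = grid.shape
    du_lo = width if "u_lo" in sides else 0
    du_hi = width if "u_hi" in sides else 0
    dv_lo = width if "v_lo" in sides else 0
    dv_hi = width if "v_hi" in sides else 0
    new_grid = build_collocation_grid(
        nu + du_lo + du_hi, nv + dv_lo + dv_hi, grid.degree, h,
        start_u=grid.kv_u.knots[0] - du_lo * h,
        start_v=grid.kv_v.knots[0] - dv_lo * h)

    (ulo, uhi) = grid.kv_u.domain
    (vlo, vhi) = grid.kv_v.domain
    gu, gv = new_grid.greville_u, new_grid.greville_v
    inu = (gu >= ulo - 1e-9) & (gu <= uhi + 1e-9)
    inv = (gv >= vlo - 1e-9) & (gv <= vhi + 1e-9)
    Eu = collocation_matrix(grid.kv_u, gu[inu])
    Ev = collocation_matrix(grid.kv_v, gv[inv])

    def transfer(values: np.ndarray, fill: float) -> np.ndarray:
        C = values_to_coefficients(grid, values)
        block = Eu @ (C @ Ev.T.toarray())
        out = np.full(new_grid.shape, fill)
        out[np.ix_(inu, inv)] = block
        return out

    X, Y = np.meshgrid(gu, gv, indexing="ij")
    dist = np.full(new_grid.shape, np.inf)
    labels = np.zeros(new_grid.shape, dtype=np.int32)
    for k, (cx, cy) in enumerate(state.soma_centers, start=1):
        d = np.hypot(X - cx, Y - cy)
        dist = np.minimum(dist, d)
        labels[d <= params.r0] = k
    phi0 = (dist <= params.r0).astype(float)

    theta = theta_noise(params.rng_seed, X, Y)
    tc = values_to_coefficients(new_grid, theta)
    gtm = np.hypot(coefficients_to_values(new_grid, tc, du=1),
                   coefficients_to_values(new_grid, tc, dv=1))

    new_state = SimulationState(
        phi=transfer(state.phi, 0.0),
        phi0=phi0,
        theta=theta,
        grad_theta_mag=gtm,
        c_tub=transfer(state.c_tub, 0.0),
        temp=transfer(state.temp, params.temperature.t_init),
        E_field=np.zeros(new_grid.shape),
        tubulin_source=compute_tubulin_source(new_grid, phi0,
                                              params.tubulin.eps0),
        neuron_labels=labels,
        soma_centers=state.soma_centers.copy(),
        iteration=state.iteration,
        stage=state.stage,
    )
    return new_state, new_grid


# --------------------------------------------------------------------------
# tip tracking across re-detections and extensions
# --------------------------------------------------------------------------

class TipTracker:
    """Persistent neurite identities across tip re-detections.

    Positions are tracked in physical coordinates so identities survive
    domain extensions.  A detected tip inherits the id of the nearest
    previous tip within ``match_radius``; otherwise it is a birth.  The
    heading is estimated from the last ``heading_window`` recorded
    positions.
    """

    def __init__(self, heading_window: int = 10, match_radius: float = 6.0):
        self.heading_window = heading_window
        self.match_radius = match_radius
        self._next_id = 1
        self.tracks: dict[int, dict] = {}

    def update(self, tips, grid: CollocationGrid):
        """Assign persistent neurite ids and headings; returns born ids."""
        phys = [np.array([grid.greville_u[t.position[0]],
                          grid.greville_v[t.position[1]]]) for t in tips]
        pairs = []
        for ti, tp in enumerate(tips):
            for nid, tr in self.tracks.items():
                if tr["neuron"] != tp.neuron_id:
                    continue
                d = float(np.linalg.norm(phys[ti] - tr["pos"]))
                if d <= self.match_radius:
                    pairs.append((d, ti, nid))
        pairs.sort(key=lambda x: (x[0], x[2], x[1]))
        tip_assigned: dict[int, int] = {}
        used_tracks = set()
        for d, ti, nid in pairs:
            if ti in tip_assigned or nid in used_tracks:
                continue
            tip_assigned[ti] = nid
            used_tracks.add(nid)
        born = []
        for ti, tp in enumerate(tips):
            if ti in tip_assigned:
                nid = tip_assigned[ti]
            else:
                nid = self._next_id
                self._next_id += 1
                self.tracks[nid] = {"pos": phys[ti], "history": [],
                                    "neuron": tp.neuron_id}
                born.append(nid)
            tr = self.tracks[nid]
            tr["pos"] = phys[ti]
            tr["history"].append(phys[ti])
            if len(tr["history"]) > self.heading_window:
                tr["history"] = tr["history"][-self.heading_window:]
            tp.neurite_id = nid
            hist = tr["history"]
            if len(hist) >= 2:
                v = hist[-1] - hist[0]
                n = np.linalg.norm(v)
                tp.heading = v / n if n > 1e-9 else None
            else:
                tp.heading = None
        return born


# --------------------------------------------------------------------------
# full staged run
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    params: ModelParameters
    grid: CollocationGrid
    state: SimulationState
    snapshots: list = dfield(default_factory=list)
    events: list = dfield(default_factory=list)

    def event_log_json(self) -> str:
        """JSON-lines serialization of the event log."""
        return "\n".join(json.dumps(e, sort_keys=True) for e in self.events)


def _phys_to_index(grid: CollocationGrid, pts):
    pts = np.atleast_2d(pts)
    iu = np.clip(np.searchsorted(grid.greville_u, pts[:, 0]), 0,
                 grid.nu - 1)
    iv = np.clip(np.searchsorted(grid.greville_v, pts[:, 1]), 0,
                 grid.nv - 1)
    # searchsorted gives the right neighbor; pick the closer of the two
    out = []
    for k in range(len(pts)):
        i, j = int(iu[k]), int(iv[k])
        if i > 0 and abs(grid.greville_u[i - 1] - pts[k, 0]) <= \
                abs(grid.greville_u[i] - pts[k, 0]):
            i -= 1
        if j > 0 and abs(grid.greville_v[j - 1] - pts[k, 1]) <= \
                abs(grid.greville_v[j] - pts[k, 1]):
            j -= 1
        out.append((i, j))
    return out


def _apply_stage_rates(tips, stage: int, axon_id, params: ModelParameters):
    r = params.rates
    for t in tips:
        if stage <= 2:
            t.rate_r, t.rate_s = r.r_g, r.s_g
        elif stage == 3:
            if axon_id is not None and t.neurite_id == axon_id:
                t.rate_r, t.rate_s = r.r_g_tip, r.s_g
            else:
                t.rate_r, t.rate_s = 0.0, r.s_g
        else:  # stage 4: branching-permissive, everyone grows again
            if axon_id is not None and t.neurite_id == axon_id:
                t.rate_r, t.rate_s = r.r_g_tip, r.s_g
            else:
                t.rate_r, t.rate_s = r.r_g, r.s_g


def run_simulation(config) -> SimulationResult:
    """Execute growth stages 1-4 per the schedule; fully seeded.

    ``config`` is a :class:`neurongrowth.config.RunConfig` (or anything
    with the same attributes).  Stages 1-2 use the global rates (uniform
    neurite growth), stage 3 applies per-neurite rates after axon
    selection, stage 4 re-enables growth of the remaining neurites.
    Snapshots are emitted at the configured cadence and an event log
    records tip births, axon selection, cue placements, domain extensions
    and Newton statistics.  Identical config + seed gives bit-identical
    results.
    """
    params: ModelParameters = config.params
    settings: SolverSettings = config.solver
    schedule = params.schedule
    grid = build_collocation_grid(config.nu, config.nv, spacing=1.0)
    state = gm.initialize_state(params, config.centers, grid)
    integ = TimeIntegrator(grid, params, settings)
    tracker = TipTracker(heading_window=config.heading_window,
                         match_radius=config.match_radius)
    rng_cue = np.random.default_rng([params.rng_seed, 7919])

    result = SimulationResult(params=params, grid=grid, state=state)
    result.events.append({"event": "run_start", "iteration": 0,
                          "grid": grid.metadata(),
                          "seed": int(params.rng_seed)})

    def snapshot():
        result.snapshots.append({
            "iteration": int(state.iteration), "stage": int(state.stage),
            "grid": grid.metadata(),
            "phi": state.phi.copy(), "c_tub": state.c_tub.copy(),
            "temp": state.temp.copy(), "E": state.E_field.copy(),
        })

    snapshot()
    if schedule.total == 0:
        return result

    tips: list = []
    cues: dict[int, nt.CuePlacement] = {}
    axon_id = None
    conflict = None
    n_extensions = 0
    last_stage = 0

    def soma_indices():
        return _phys_to_index(grid, state.soma_centers)

    def retip(stage: int):
        """(Re)label, detect and track tips, manage cues/zones/extension."""
        nonlocal tips, conflict, grid, state, integ, n_extensions, axon_id
        while True:
            s_idx = soma_indices()
            state.neuron_labels = nt.label_components(
                state.phi, 0.5, soma_centers=s_idx)
            tips = nt.detect_tips(
                state.phi, state.neuron_labels, soma_centers=s_idx,
                soma_radius=params.r0,
                min_separation=config.tip_min_separation)
            born = tracker.update(tips, grid)
            for nid in born:
                t = next(t for t in tips if t.neurite_id == nid)
                result.events.append({
                    "event": "tip_born", "iteration": int(state.iteration),
                    "neurite": int(nid), "neuron": int(t.neuron_id),
                    "position": [int(t.position[0]), int(t.position[1])]})
            sides = sides_to_extend(tips, grid,
                                    margin=config.extension_margin,
                                    all_directions=config.extend_all_directions)
            if not sides or n_extensions >= config.max_extensions:
                break
            state, grid = extend_domain(state, grid, params, sides,
                                        width=config.extension_width)
            integ = TimeIntegrator(grid, params, settings)
            n_extensions += 1
            result.events.append({
                "event": "domain_extended", "iteration": int(state.iteration),
                "sides": sorted(sides), "grid": grid.metadata()})
        _apply_stage_rates(tips, stage, axon_id, params)
        # cue-guided zone placement during differentiation and beyond
        if stage >= 3:
            s_idx = soma_indices()
            for t in tips:
                if stage == 3 and (axon_id is None or t.neurite_id != axon_id):
                    t.zone_center = tuple(int(round(x)) for x in t.position)
                    continue
                stale = (t.neurite_id in cues and config.cue_every > 0 and
                         state.iteration - cues[t.neurite_id][1]
                         >= config.cue_every)
                if t.neurite_id not in cues or stale:
                    center = s_idx[t.neuron_id - 1] \
                        if t.neuron_id - 1 < len(s_idx) else None
                    cue = nt.place_extracellular_cue(
                        t, params.cue, rng_cue, soma_center=center)
                    cues[t.neurite_id] = (cue, int(state.iteration))
                    result.events.append({
                        "event": "cue_placed",
                        "iteration": int(state.iteration),
                        "neurite": int(t.neurite_id),
                        "angle_deg": float(cue.angle_deg),
                        "position": [float(cue.position[0]),
                                     float(cue.position[1])]})
                cue = cues[t.neurite_id][0]
                v = np.array(cue.position) - np.array(t.position, float)
                n = np.linalg.norm(v)
                if n > 1e-9:
                    shift = params.zone_cue_shift * v / n
                    t.zone_center = (
                        int(np.clip(round(t.position[0] + shift[0]), 0,
                                    grid.nu - 1)),
                        int(np.clip(round(t.position[1] + shift[1]), 0,
                                    grid.nv - 1)))
        conflict = nt.merge_conflict_mask(
            state.phi, state.neuron_labels,
            soma_centers=soma_indices(), soma_radius=params.r0 + 2.0,
            window=config.guard_window) if config.guard_enabled else None
        result.events.append({
            "event": "tips", "iteration": int(state.iteration),
            "stage": int(stage),
            "tips": [{"neurite": int(t.neurite_id),
                      "neuron": int(t.neuron_id),
                      "position": [int(t.position[0]), int(t.position[1])],
                      "length": round(float(t.geodesic_length), 6),
                      "c_tub": round(gm.tip_tubulin(state.c_tub, t, params), 6),
                      "rates": [float(t.rate_r), float(t.rate_s)],
                      "E_zone": round(float(
                          state.E_field[nt.activation_zones(
                              [t], params.activation_zone_size,
                              state.phi.shape)].max())
                          if state.E_field.any() else 0.0, 6)}
                     for t in tips]})

    for it in range(schedule.total):
        stage = schedule.stage_of(it)
        stage_changed = stage != last_stage
        if stage_changed:
            state.stage = stage
            result.events.append({"event": "stage_start", "stage": int(stage),
                                  "iteration": int(state.iteration)})
        if stage_changed or it % config.retip_every == 0:
            retip(stage)
            if stage == 3 and axon_id is None and tips:
                axon_id, assignment = nt.select_axon(tips, params.rates)
                for t in tips:
                    t.rate_r, t.rate_s = assignment[t.neurite_id]
                result.events.append({
                    "event": "axon_selected", "iteration": int(state.iteration),
                    "neurite": int(axon_id),
                    "length": round(float(next(
                        t.geodesic_length for t in tips
                        if t.neurite_id == axon_id)), 6)})
                retip(stage)  # re-apply zones/cues with the axon known
        last_stage = stage
        for t in tips:
            t.c_tub_local = gm.tip_tubulin(state.c_tub, t, params)
        state.E_field = gm.compute_driving_force(state, tips, params)
        integ.step(state, conflict_mask=conflict)
        if config.snapshot_every and state.iteration % config.snapshot_every == 0:
            snapshot()
        if it % config.retip_every == config.retip_every - 1 \
                and integ.newton_history:
            h = integ.newton_history[-config.retip_every:]
            result.events.append({
                "event": "newton_stats", "iteration": int(state.iteration),
                "max_iters": int(max(h)),
                "mean_iters": round(float(np.mean(h)), 3)})

    if not result.snapshots or \
            result.snapshots[-1]["iteration"] != state.iteration:
        snapshot()
    result.grid = grid
    result.state = state
    return result
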