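"""Continuous model terms for multi-stage neuron growth.

The neuron is represented by a phase field ``phi`` (1 inside the cell, 0 in
the medium) evolving under a dendritic-solidification-type law with
six-fold-capable anisotropy ``a(psi)``, a static random orientation field
``theta`` whose gradient magnitude perturbs the double-well tilt, and a
localized driving force ``E`` active only in energy activation zones around
detected neurite tips:

    d(phi)/dt = M_phi [ div(a^2 grad phi)
                        - d/dx (a a' d(phi)/dy) + d/dy (a a' d(phi)/dx)
                        + phi (1 - phi)(phi - 1/2 + E + 6 H |grad theta|) ]

Intracellular tubulin ``c_tub`` is produced at the initial cell membrane,
transported by diffusion and (optionally) active transport, and decays:

    d(phi c)/dt = delta_t div(phi grad c) - alpha_t . grad(phi c)
                  - beta_t phi c + eps0 |grad phi0|^2 / int |grad phi0|^2

Neurite tips elongate at rate ``dL/dt = r_g c_tub - s_g`` and the driving
force is ``E = (alpha/pi) atan(H_eps(dL/dt) gamma DeltaT)`` with DeltaT the
undercooling evolved by a latent-heat-coupled heat equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import bspline_collocation as bsc
from .bspline_collocation import (
    CollocationGrid,
    coefficients_to_values,
    field_derivatives,
    values_to_coefficients,
)
from .errors import (
    ConfigurationError,
    InitializationError,
    NumericalBlowupError,
    ParameterError,
)

__all__ = [
    "AnisotropyParams", "TubulinParams", "RateParams", "CueParams",
    "TemperatureParams", "StageSchedule", "ModelParameters",
    "SimulationState", "initialize_state", "interface_orientation",
    "anisotropy_coefficient", "neurite_extension_rate",
    "compute_driving_force", "phase_field_rhs", "tubulin_rhs",
    "evolve_undercooling", "smoothed_heaviside", "theta_noise",
]


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnisotropyParams:
    """Kobayashi-form gradient coefficient a(psi) = a_bar (1 + delta cos(j (psi - theta0)))."""
    a_bar: float = 0.5
    delta_aniso: float = 0.2
    j_fold: int = 6
    theta_offset: float = 0.0
    grad_floor: float = 0.01      # |grad phi| scale below which the
                                  # anisotropy blends to isotropic (the
                                  # interface angle is meaningless there)


@dataclass(frozen=True)
class TubulinParams:
    delta_t: float = 6.0          # diffusion coefficient
    alpha_t: tuple = (0.0, 0.0)   # constant active-transport velocity vector
    alpha_radial: float = 5.0     # radially-outward active-transport speed
                                  # (kinesin-like soma-to-tip flux; diffusion
                                  # alone cannot supply a distant growth cone
                                  # on the simulated time scale)
    beta_t: float = 0.001         # decay coefficient
    eps0: float = 2.0             # dimensionless production coefficient
    reg: float = 1e-5             # extracellular pin-down used by the implicit solve
    conserve_mass: bool = True    # rescale each implicit solve so the global
                                  # tubulin balance (production - decay -
                                  # advection, as discretized) holds exactly;
                                  # strong-form collocation is not discretely
                                  # conservative at interface scale
    support_floor: float = 0.02   # phi below which the implicit solve pins
                                  # c_tub to zero outright: c = w / phi is
                                  # ill-posed as phi -> 0 and the advective
                                  # term otherwise pumps the tail; the
                                  # conservative correction repays the tiny
                                  # flux this absorbs


@dataclass(frozen=True)
class RateParams:
    r_g: float = 10.0             # tubulin assembly rate (global, stages 1-2)
    s_g: float = 0.1              # tubulin disassembly rate
    r_g_tip: float = 20.0         # assembly rate at the selected axon tip


@dataclass(frozen=True)
class CueParams:
    distance: float = 20.0        # cue distance from the tip, grid units
    angle_mean: float = 41.673    # mean absolute turning angle, degrees
    angle_sd: float = 32.007      # turning-angle standard deviation, degrees


@dataclass(frozen=True)
class TemperatureParams:
    k_latent: float = 0.3         # latent-heat coupling K in dT/dt = lap T + K dphi/dt
    t_eq: float = 1.0             # equilibrium temperature; DeltaT = t_eq - T
    t_init: float = 0.0           # initial uniform temperature


@dataclass(frozen=True)
class StageSchedule:
    """Cumulative iteration budgets for growth stages 1-4.

    Stage transitions are schedule-driven: the model does not detect them
    automatically.  Defaults correspond to the full-scale run
    (lamellipodia 500, outgrowth 10,500, axon differentiation 28,500,
    dendrite formation 35,000 iterations).
    """
    iters_stage1: int = 500
    iters_stage2: int = 10_500
    iters_stage3: int = 28_500
    iters_stage4: int = 35_000

    def __post_init__(self):
        b = (self.iters_stage1, self.iters_stage2,
             self.iters_stage3, self.iters_stage4)
        if any(b[i] > b[i + 1] for i in range(3)) or b[0] < 0:
            raise ConfigurationError(
                f"stage budgets must be nondecreasing and >= 0, got {b}")

    @property
    def total(self) -> int:
        return self.iters_stage4

    def stage_of(self, iteration: int) -> int:
        if iteration < self.iters_stage1:
            return 1
        if iteration < self.iters_stage2:
            return 2
        if iteration < self.iters_stage3:
            return 3
        return 4


@dataclass(frozen=True)
class ModelParameters:
    """All coefficients of the growth model.

    Values were set empirically to produce the staged growth morphology at
    the reference grid scales; every value is overridable through the flat
    config file (see :mod:`neurongrowth.config`).
    """
    m_phi: float = 60.0           # phase mobility
    alpha_E: float = 0.9          # arctan scale of the driving force
    gamma: float = 15.0           # interfacial energy constant
    H_const: float = 0.006        # orientation-penalty constant
    anisotropy: AnisotropyParams = field(default_factory=AnisotropyParams)
    tubulin: TubulinParams = field(default_factory=TubulinParams)
    rates: RateParams = field(default_factory=RateParams)
    cue: CueParams = field(default_factory=CueParams)
    temperature: TemperatureParams = field(default_factory=TemperatureParams)
    schedule: StageSchedule = field(default_factory=StageSchedule)
    heaviside_eps: float = 0.01   # smoothing width of the H_eps gate
    reaction_scale: float = 1.0   # 0 disables the double-well reaction (pure
                                  # anisotropic-diffusion limit, useful for
                                  # verification problems)
    dt: float = 0.01              # simulation time step
    r0: float = 20.0              # initial cell radius, grid units
    activation_zone_size: int = 6
    zone_cue_shift: int = 2       # zone-center shift toward the cue, points
    tip_tubulin_stat: str = "zone_max"  # how dL/dt samples c_tub at a tip:
                                  # "tip" (the single tip point),
                                  # "zone_max" or "zone_mean" over the
                                  # activation zone.  The leading edge of a
                                  # growing arm carries very little tubulin,
                                  # so the zone maximum (the trailing zone
                                  # rows) is the robust default.
    rng_seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.r0 <= 0:
            raise ParameterError(f"r0 must be > 0, got {self.r0}")
        for name in ("m_phi", "alpha_E", "gamma", "H_const",
                     "heaviside_eps"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")

    def with_overrides(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# state
# --------------------------------------------------------------------------

@dataclass
class SimulationState:
    """Fields on the collocation lattice plus bookkeeping counters.

    ``theta`` and ``phi0`` are frozen after initialization; ``E_field`` is
    nonzero only inside activation zones.
    """
    phi: np.ndarray
    phi0: np.ndarray
    theta: np.ndarray
    grad_theta_mag: np.ndarray
    c_tub: np.ndarray
    temp: np.ndarray
    E_field: np.ndarray
    tubulin_source: np.ndarray
    neuron_labels: np.ndarray
    soma_centers: np.ndarray      # (k, 2) physical coordinates
    iteration: int = 0
    stage: int = 1

    def copy(self) -> "SimulationState":
        return SimulationState(
            phi=self.phi.copy(), phi0=self.phi0.copy(),
            theta=self.theta.copy(), grad_theta_mag=self.grad_theta_mag.copy(),
            c_tub=self.c_tub.copy(), temp=self.temp.copy(),
            E_field=self.E_field.copy(),
            tubulin_source=self.tubulin_source.copy(),
            neuron_labels=self.neuron_labels.copy(),
            soma_centers=self.soma_centers.copy(),
            iteration=self.iteration, stage=self.stage)


# --------------------------------------------------------------------------
# position-keyed orientation noise
# --------------------------------------------------------------------------

_M1 = np.uint64(0x9E3779B97F4A7C15)
_M2 = np.uint64(0xC2B2AE3D27D4EB4F)
_M3 = np.uint64(0x165667B19E3779F9)


def theta_noise(seed: int, u_coords: np.ndarray,
                v_coords: np.ndarray) -> np.ndarray:
    """Uniform [0, 1) orientation noise keyed by physical position.

    The value at a lattice point depends only on ``seed`` and the point's
    physical coordinates (scaled by 3 so Greville edge points map to
    integers), never on grid shape.  Domain extension therefore reproduces
    the original theta values at pre-existing points bit-for-bit, and two
    successive extensions commute with one double extension.

    Uses a splitmix64-style integer mix; this is noise generation keyed by
    position, not a general-purpose RNG.
    """
    iu = np.rint(np.asarray(u_coords) * 3.0).astype(np.int64)
    iv = np.rint(np.asarray(v_coords) * 3.0).astype(np.int64)
    with np.errstate(over="ignore"):
        z = (iu.astype(np.uint64) + np.uint64(1 << 62)) * _M1
        z ^= (iv.astype(np.uint64) + np.uint64(1 << 62)) * _M2
        z ^= np.uint64(seed & 0xFFFFFFFFFFFFFFFF) * _M3
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z ^= z >> np.uint64(31)
    return (z >> np.uint64(11)).astype(np.float64) * (2.0 ** -53)


# --------------------------------------------------------------------------
# initialization
# --------------------------------------------------------------------------

def _grid_coords(grid: CollocationGrid):
    return np.meshgrid(grid.greville_u, grid.greville_v, indexing="ij")


def compute_tubulin_source(grid: CollocationGrid, phi0: np.ndarray,
                           eps0: float) -> np.ndarray:
    """Membrane-localized production term, self-normalized to integrate to eps0.

    Raises
    ------
    InitializationError
        If ``phi0`` has no interface (zero gradient everywhere).
    """
    c0 = values_to_coefficients(grid, phi0)
    gx = coefficients_to_values(grid, c0, du=1)
    gy = coefficients_to_values(grid, c0, dv=1)
    g2 = gx * gx + gy * gy
    total = g2.sum() * grid.spacing ** 2
    if total <= 1e-12:
        raise InitializationError("initial phase field has no interface")
    return eps0 * g2 / total


def initialize_state(params: ModelParameters, centers,
                     grid: CollocationGrid) -> SimulationState:
    """Build the initial state: circular cells, tanh tubulin profile, seeded theta.

    ``phi0 = 1`` inside each disk of radius ``r0`` and 0 outside;
    ``c_tub = (1 + tanh((r0 - r)/2)) / 2`` with r the distance to the
    nearest center.

    Raises
    ------
    ConfigurationError
        If centers is empty, circles overlap, or a circle does not fit
        inside the domain with a small margin.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise ConfigurationError("need at least one cell center")
    r0 = params.r0
    (u_lo, u_hi) = grid.kv_u.domain
    (v_lo, v_hi) = grid.kv_v.domain
    margin = 2.0 * grid.spacing
    for cx, cy in centers:
        if (cx - r0 < u_lo + margin or cx + r0 > u_hi - margin or
                cy - r0 < v_lo + margin or cy + r0 > v_hi - margin):
            raise ConfigurationError(
                f"initial circle at ({cx}, {cy}) does not fit in the domain")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) <= 2 * r0:
                raise ConfigurationError(
                    f"initial circles {i} and {j} overlap")

    X, Y = _grid_coords(grid)
    dist = np.full(grid.shape, np.inf)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for k, (cx, cy) in enumerate(centers, start=1):
        d = np.hypot(X - cx, Y - cy)
        closer = d < dist
        dist = np.where(closer, d, dist)
        labels[(d <= r0)] = k
    # diffuse equilibrium interface profile (width set by the gradient
    # coefficient): phi = 1 in the cell, 0 in the medium, 0.5 exactly at
    # r = r0.  A sharp indicator would ring under the smooth spline basis.
    w_int = 2.0 * np.sqrt(2.0) * params.anisotropy.a_bar
    phi0 = 0.5 * (1.0 + np.tanh((r0 - dist) / w_int))
    c_tub = 0.5 * (1.0 + np.tanh((r0 - dist) / 2.0))

    theta = theta_noise(params.rng_seed, X, Y)
    tc = values_to_coefficients(grid, theta)
    tx = coefficients_to_values(grid, tc, du=1)
    ty = coefficients_to_values(grid, tc, dv=1)
    grad_theta_mag = np.hypot(tx, ty)

    return SimulationState(
        phi=phi0.copy(), phi0=phi0,
        theta=theta, grad_theta_mag=grad_theta_mag,
        c_tub=c_tub,
        temp=np.full(grid.shape, params.temperature.t_init),
        E_field=np.zeros(grid.shape),
        tubulin_source=compute_tubulin_source(grid, phi0,
                                              params.tubulin.eps0),
        neuron_labels=labels,
        soma_centers=centers,
    )


# --------------------------------------------------------------------------
# model terms
# --------------------------------------------------------------------------

def interface_orientation(phi_grad_x: np.ndarray, phi_grad_y: np.ndarray,
                          tol: float = 1e-10) -> np.ndarray:
    """Angle of the interface normal; 0 by convention where the gradient degenerates.

    The convention is inert: a(psi) and its derivative multiply gradient
    components that vanish there anyway.
    """
    psi = np.arctan2(phi_grad_y, phi_grad_x)
    psi[np.hypot(phi_grad_x, phi_grad_y) < tol] = 0.0
    return psi


def anisotropy_coefficient(psi: np.ndarray, aniso: AnisotropyParams):
    """Gradient coefficient a(psi) and its analytic psi-derivative.

    Raises
    ------
    ParameterError
        If |delta_aniso| >= 1 (gradient coefficient would go nonpositive).
    """
    if abs(aniso.delta_aniso) >= 1.0:
        raise ParameterError(
            f"|delta_aniso| must be < 1, got {aniso.delta_aniso}")
    arg = aniso.j_fold * (psi - aniso.theta_offset)
    a = aniso.a_bar * (1.0 + aniso.delta_aniso * np.cos(arg))
    dadpsi = -aniso.a_bar * aniso.delta_aniso * aniso.j_fold * np.sin(arg)
    return a, dadpsi


def neurite_extension_rate(c_tub_at_tip, r, s):
    """Tubulin-driven extension rate dL/dt = r * c_tub - s."""
    return r * c_tub_at_tip - s


def smoothed_heaviside(x, eps: float):
    """H_eps(x) = (1 + tanh(x / eps)) / 2, a smooth gate with width eps."""
    return 0.5 * (1.0 + np.tanh(np.asarray(x, dtype=float) / eps))


def _zone_slices(center, zone: int, shape):
    """Axis-aligned zone x zone square around a lattice center, clipped."""
    i, j = int(center[0]), int(center[1])
    half = zone // 2
    i0, i1 = max(i - half, 0), min(i - half + zone, shape[0])
    j0, j1 = max(j - half, 0), min(j - half + zone, shape[1])
    return slice(i0, i1), slice(j0, j1)


def tip_tubulin(c_tub: np.ndarray, tip, params: ModelParameters) -> float:
    """Tubulin concentration a tip's extension rate is evaluated with.

    Per ``params.tip_tubulin_stat``: the value at the tip point, or the
    max/mean over the tip's activation zone.
    """
    if params.tip_tubulin_stat == "tip":
        return float(c_tub[tip.position])
    su, sv = _zone_slices(tip.zone_center, params.activation_zone_size,
                          c_tub.shape)
    zone = c_tub[su, sv]
    if zone.size == 0:
        return float(c_tub[tip.position])
    if params.tip_tubulin_stat == "zone_mean":
        return float(zone.mean())
    return float(zone.max())


def compute_driving_force(state: SimulationState, tips,
                          params: ModelParameters) -> np.ndarray:
    """Driving force E, nonzero only inside tip-centered activation zones.

    Within each zone ``E = (alpha/pi) atan(H_eps(dL/dt) gamma DeltaT)``
    using the tip-local tubulin concentration and the neurite's (r, s)
    rates.  Where ``r c_tub < s`` the zone is gated hard to 0 (the smooth
    Heaviside composed with a sharp sign gate), so inhibited neurites
    receive no driving force at all.
    """
    E = np.zeros(state.phi.shape)
    t_eq = params.temperature.t_eq
    scale = params.alpha_E / np.pi
    for tip in sorted(tips, key=lambda t: (t.neuron_id, t.neurite_id)):
        dldt = neurite_extension_rate(tip.c_tub_local, tip.rate_r, tip.rate_s)
        if dldt < 0.0:
            continue
        su, sv = _zone_slices(tip.zone_center, params.activation_zone_size,
                              state.phi.shape)
        h = smoothed_heaviside(dldt, params.heaviside_eps)
        dT = t_eq - state.temp[su, sv]
        E[su, sv] = scale * np.arctan(h * params.gamma * dT)
    return E


def phase_field_rhs(phi: np.ndarray, grid: CollocationGrid,
                    params: ModelParameters, E_field: np.ndarray,
                    grad_theta_mag: np.ndarray,
                    phi_coeff: np.ndarray | None = None,
                    iteration: int | None = None,
                    return_aux: bool = False,
                    frozen_aux=None):
    """Right-hand side of the phase-field evolution at all collocation points.

    All spatial derivatives go through the spline collocation operators.
    The KWC rotation terms reduce analytically to
    ``g_y phi_x - g_x phi_y`` with ``g = a da/dpsi`` (the mixed-derivative
    contributions cancel), which is the form evaluated here.

    Raises
    ------
    NumericalBlowupError
        If any term is non-finite.
    """
    if phi_coeff is None:
        phi_coeff = values_to_coefficients(grid, phi)
    f, fx, fy, fxx, fyy = field_derivatives(grid, phi_coeff)
    aniso = params.anisotropy
    lap = fxx + fyy
    m = f - 0.5 + E_field + 6.0 * params.H_const * grad_theta_mag
    reaction = params.reaction_scale * f * (1.0 - f) * m
    if frozen_aux is not None:
        # anisotropy coefficients lagged from the start-of-step field:
        # within the step the divergence terms are linear in phi
        a2, cx, cy, gx, gy = frozen_aux
        rhs = params.m_phi * (a2 * lap + cx * fx + cy * fy + reaction)
        aux = frozen_aux
    elif aniso.delta_aniso == 0.0:
        a2 = aniso.a_bar ** 2
        rhs = params.m_phi * (a2 * lap + reaction)
        aux = (np.full(grid.shape, a2), np.zeros(grid.shape),
               np.zeros(grid.shape), np.zeros(grid.shape),
               np.zeros(grid.shape))
    else:
        psi = interface_orientation(fx, fy)
        a, dap = anisotropy_coefficient(psi, aniso)
        # blend to the isotropic coefficient where |grad phi| is below the
        # floor: psi carries no information there and feeding its noise
        # through the coefficient derivatives destabilizes the solve
        g2 = fx * fx + fy * fy
        w = g2 / (g2 + aniso.grad_floor ** 2)
        a = aniso.a_bar + w * (a - aniso.a_bar)
        dap = w * dap
        a2 = a * a
        g = a * dap
        a2c = values_to_coefficients(grid, a2)
        gc = values_to_coefficients(grid, g)
        a2x = coefficients_to_values(grid, a2c, du=1)
        a2y = coefficients_to_values(grid, a2c, dv=1)
        gx = coefficients_to_values(grid, gc, du=1)
        gy = coefficients_to_values(grid, gc, dv=1)
        cx = a2x + gy
        cy = a2y - gx
        rhs = params.m_phi * (a2 * lap + cx * fx + cy * fy + reaction)
        aux = (a2, cx, cy, gx, gy)
    if not np.all(np.isfinite(rhs)):
        raise NumericalBlowupError(
            "non-finite values in phase-field right-hand side",
            iteration=iteration)
    if return_aux:
        return rhs, aux, (f, m)
    return rhs


def radial_transport_field(grid: CollocationGrid, soma_centers,
                           magnitude: float):
    """Radially-outward unit velocity field from the nearest soma, scaled.

    Models the soma-to-tip active transport of tubulin; returns the two
    velocity components on the lattice (zero at the centers themselves).
    """
    X, Y = _grid_coords(grid)
    best = np.full(grid.shape, np.inf)
    ax = np.zeros(grid.shape)
    ay = np.zeros(grid.shape)
    for cx, cy in np.atleast_2d(soma_centers):
        dx, dy = X - cx, Y - cy
        r = np.hypot(dx, dy)
        closer = r < best
        with np.errstate(invalid="ignore", divide="ignore"):
            ax = np.where(closer, np.where(r > 0, dx / r, 0.0), ax)
            ay = np.where(closer, np.where(r > 0, dy / r, 0.0), ay)
        best = np.minimum(best, r)
    return magnitude * ax, magnitude * ay


def tubulin_rhs(phi: np.ndarray, c_tub: np.ndarray, grid: CollocationGrid,
                params: ModelParameters, source: np.ndarray,
                alpha_field=None) -> np.ndarray:
    """Four-term tubulin balance d(phi c)/dt at all collocation points.

    ``div(phi grad c)`` is expanded as ``phi lap c + grad phi . grad c``;
    the advective term differentiates the product ``phi c``.  The source
    is the precomputed self-normalized production field whose discrete
    integral equals eps0 exactly.
    """
    tb = params.tubulin
    pc = values_to_coefficients(grid, phi)
    cc = values_to_coefficients(grid, c_tub)
    _, px, py, _, _ = field_derivatives(grid, pc)
    _, cx, cy, cxx, cyy = field_derivatives(grid, cc)
    diff = tb.delta_t * (phi * (cxx + cyy) + px * cx + py * cy)
    ax, ay = tb.alpha_t
    if alpha_field is not None:
        ax = ax + alpha_field[0]
        ay = ay + alpha_field[1]
    # transport machinery lives in the cytoplasm: gate the velocity by phi
    # (otherwise the advective term pumps c up in the extracellular tail
    # where phi -> 0 and the concentration is physically meaningless)
    gate = np.clip(phi, 0.0, 1.0)
    ax = ax * gate
    ay = ay * gate
    if np.any(ax != 0.0) or np.any(ay != 0.0):
        wc = values_to_coefficients(grid, phi * c_tub)
        wx = coefficients_to_values(grid, wc, du=1)
        wy = coefficients_to_values(grid, wc, dv=1)
        adv = ax * wx + ay * wy
    else:
        adv = 0.0
    return diff - adv - tb.beta_t * (phi * c_tub) + source


def evolve_undercooling(temp: np.ndarray, dphi: np.ndarray,
                        grid: CollocationGrid, params: ModelParameters,
                        heat_solver=None) -> np.ndarray:
    """Advance the temperature one implicit Euler step of
    ``dT/dt = lap T + K dphi/dt`` and return the new temperature field.

    ``dphi`` is the phase increment over the step (``K dphi`` is the latent
    heat released).  The undercooling entering the driving force is
    ``DeltaT = t_eq - T``.  A prefactorized solver from
    :func:`neurongrowth.time_integrator.make_heat_solver` may be supplied;
    otherwise one is assembled on the fly.
    """
    if heat_solver is None:
        from .time_integrator import make_heat_solver
        heat_solver = make_heat_solver(grid, params.dt)
    rhs = temp + params.temperature.k_latent * dphi
    return heat_solver(rhs)
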