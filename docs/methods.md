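# Methods

This note records the model equations as implemented, the numerical scheme,
the default parameter values and why they were chosen, what the synthetic
fixtures emulate, and the known limitations.

## Phase-field model

The cell is a phase field φ on a two-dimensional lattice, 1 in the
cytoplasm and 0 in the medium, with a diffuse interface. Its evolution law
is of the anisotropic dendritic-solidification family:

∂φ/∂t = M_φ [ ∇·(a²∇φ) − ∂x(a a_Ψ φ_y) + ∂y(a a_Ψ φ_x)
              + φ(1−φ)(φ − ½ + E + 6H|∇θ|) ]

* a(Ψ) = ā(1 + δ cos j(Ψ − θ₀)) is the orientation-dependent gradient
  coefficient (Kobayashi form), Ψ the interface-normal angle from ∇φ. The
  two rotation terms reduce analytically to g_y φ_x − g_x φ_y with
  g = a·a_Ψ (the mixed-derivative parts cancel); that reduced form is what
  the code evaluates. Where |∇φ| falls below a floor (0.01) the
  coefficient blends to the isotropic ā: the interface angle carries no
  information at the gradient noise floor, and feeding its noise through
  the coefficient derivatives destabilizes the solve.
* θ is a static uniform-[0,1) noise field, frozen for the whole run. It is
  generated by a position-keyed integer hash of the physical coordinates,
  so domain extension reproduces it bit-for-bit at pre-existing points and
  successive extensions commute. Its spline-gradient magnitude |∇θ|
  (median ≈ 0.44 at unit spacing) perturbs the double-well tilt; this is
  both the symmetry-breaking noise that forms lamellipodia and the reason
  the model is grid-dependent (a finer lattice resamples θ).
* E is the growth-cone driving force, nonzero only inside the 6×6
  activation zones centered at detected neurite tips:
  E = (α/π)·atan(H_ε(dL/dt)·γ·ΔT), dL/dt = r_g c_tub − s_g, with
  H_ε(x) = (1 + tanh(x/ε))/2 and a hard gate E = 0 whenever
  r_g c_tub < s_g (the smooth Heaviside alone would leave ~1e-80 residues
  rather than the exact zero the gating semantics require).
* ΔT = T_eq − T is the undercooling; T follows the latent-heat-coupled
  heat equation ∂T/∂t = ∇²T + K ∂φ/∂t with homogeneous Neumann walls.

### Interface balance and calibration

At interior-knot spacing 1 the equilibrium interface profile is
φ = ½(1 + tanh(x/(2√2 ā))). With the default ā = 0.5 the profile width
parameter is ≈1.4 lattice units — deliberately thin, because neurite
competition relies on curvature pinning:

* the flat double-well tilt from the noise term, m₀ = 6H|∇θ|
  (mean ≈ 0.016 at H = 0.006), sits just below the disk-scale curvature
  threshold ā·κ/√2 ≈ 0.021 for the initial r₀ = 20 cell, so the rim
  roughens slowly where |∇θ| is locally large (lamellipodia) without
  uniform expansion;
* a thin arm tip has κ ≈ 0.3–0.5, far beyond the noise tail, so arms
  extend only where the activation-zone force E ≈ 0.43 acts; an inhibited
  tip retracts slowly or pins.

All remaining coefficients were set empirically to produce the four-stage
morphology at the reduced reference scales and are recorded below; every
value is overridable through the flat config file.

| parameter | default | meaning |
|---|---|---|
| M_φ | 60 | phase mobility (M_φ·dt = 0.6 per step) |
| α (alpha_E) | 0.9 | arctan scale of E (E saturates at α/2) |
| γ | 15 | interfacial energy constant inside the atan |
| H | 0.006 | orientation-noise coupling |
| ā, δ, j | 0.5, 0.2, 6 | anisotropy mean, strength, mode number |
| δ_t | 6 | tubulin diffusion coefficient |
| α_radial | 5 | radially-outward active-transport speed |
| β_t | 0.001 | tubulin decay |
| ε₀ | 2 | total membrane production rate |
| r_g, s_g, r_g^tip | 10, 0.1, 20 | assembly/disassembly/axon-tip rates |
| K, T_eq | 0.3, 1.0 | latent heat and equilibrium temperature |
| dt, r₀ | 0.01, 20 | time step, initial cell radius |

The initial φ uses the diffuse equilibrium tanh profile (φ = ½ exactly at
r = r₀) rather than a sharp indicator: a step function rings under the
smooth spline basis and stalls the first nonlinear solves. The initial
tubulin profile is c = ½(1 + tanh((r₀ − r)/2)) and the production source
|∇φ₀|², normalized by its own discrete integral so it injects exactly ε₀
per unit time.

## Tubulin transport

The balance is solved for c with the new φ, implicitly in all linear
terms. Three numerical safeguards address the fact that c = w/φ is
ill-posed as φ → 0:

1. the transport velocity is gated by clip(φ,0,1) (motors live in the
   cytoplasm) and c is pinned to zero outright where φ < 0.02 — without
   the pin the advective term pumps the extracellular tail at rate
   |α·∇φ| and c runs away exponentially;
2. active transport defaults to a radially-outward unit field scaled by
   α_radial. Pure diffusion cannot supply a growth cone 50+ units from
   the soma within the simulated time (t ≈ L²/2δ_t); the radial flux
   models kinesin-driven soma-to-tip transport and keeps the supply
   frontier ahead of the axon tip;
3. a global conservative correction: strong-form collocation does not
   conserve the discrete point-sum of φc (the divergence quadrature
   drifts by ~10–20 % per unit time at interface scale), so each solve is
   rescaled — by at most 0.1 % per step — to satisfy the exact interior
   balance (mass_old + dt·ε₀ − decay − advection as discretized), with
   the mass the extracellular pin absorbs folded back into the cell. The
   positivity projection that clips the small negative excursions at the
   support edge is likewise mass-neutral.

The tip extension rate samples c_tub as the maximum over the tip's
activation zone ("zone_max"): the extreme leading-edge point always
carries near-zero tubulin, and sampling it alone would gate E off
permanently. The single-point and zone-mean variants remain available.

## Discretization and solver

Fields live on the tensor-product Greville lattice of an open uniform
cubic B-spline space (degree configurable ≥ 2); all spatial derivatives
are exact spline derivatives through sparse collocation operators, and
field ↔ coefficient transforms use banded per-axis solves. Verification:
the collocated steady diffusion problem with a manufactured solution
converges at second order (observed order 1.996–1.999 on 32²–128² grids;
the estimate approaches 2 strictly from below, as it must for an exactly
second-order scheme).

Time stepping is implicit Euler. The φ-step solves the collocated
nonlinear system by Newton with the analytic reaction derivative;
anisotropy coefficients are frozen at the start-of-step field (IMEX
lagging, first-order consistent). Lagging them from the previous Newton
iterate instead — re-evaluating a(Ψ) inside the iteration — limit-cycles
near 5e-3 residual and never meets the 1e-4 tolerance, which is why the
per-step freeze was adopted. The Jacobian is reassembled and refactorized
(sparse LU, MMD ordering) at the start of every step: at a moving
interface even a one-step-old factorization degrades the chord rate to
≈0.5 per iteration, and a fresh assembly (2–3 quadratic iterations) is
cheaper in total. The residual ∞-norm of every accepted step is below the
1e-4 tolerance; on linear configurations the first update solves the
system exactly.

Boundary collocation rows are replaced by outward-normal first-derivative
rows (homogeneous Neumann; corners take the sum of both one-sided normals
— same-signed corner rows cancel the corner coefficient and leave the
system near-singular). Then c_tub follows (Jacobi-preconditioned BiCGStab
with LU fallback), then the temperature with a prefactorized constant
operator. Sequential splitting is first-order consistent with implicit
Euler.

Stage transitions are schedule-driven (iteration budgets); the model does
not detect them automatically. Tips are re-detected every 25 iterations;
the domain auto-extends by 10 knot spans per flagged side when a tip comes
within 10 points of a wall, transferring fields by spline evaluation
(exact at pre-existing collocation points).

## Tip detection, axon selection, cues, guard

Tips are geodesically extremal boundary clusters: local maxima of the
octile (8-connected, √2 diagonals) geodesic distance from the soma,
beyond an exclusion radius 1.05·r₀ + 2 (the octile metric inflates disk
boundary distances by up to ~8 %, so a bare disk yields no tips), merged
within a minimum separation and refined to the cap apex by a local
Euclidean rim-band centroid. On k-armed star fixtures this recovers
exactly k tips within one lattice point of the constructed apex for
k = 2…8.

The axon is the neurite with the largest geodesic length at the start of
stage 3 (ties to the lowest id). It receives r_g^tip; all others get
assembly rate 0, so r·c_tub < s and their driving force is exactly zero.
Each guided tip's activation zone is shifted 2 points toward an
extracellular cue placed at distance 20 from the tip, rotated from the
tip heading by a signed angle whose magnitude is drawn from the measured
turning-angle distribution (mean 41.673°, sd 32.007°) with a random sign.
Cues are re-sampled every 250 iterations: a single frozen cue can wedge
the zone so the front pins against the zone box permanently, and the
periodic redraw both unjams growth and makes each drawn angle shape one
path segment — the geometry the turning-angle statistics measure. In
stage 4 all neurites are re-enabled with cue guidance (branching-permissive
activation).

The self-intersection guard labels each neuron's arms (mask minus soma
disk, ignoring sub-arm fragments) and zeroes positive φ-updates wherever a
5×5 neighborhood touches two distinct arms of the same neuron; arms of
different neurons may touch.

## Change-point test

The statistic at candidate i is the absolute angle between the backward
and forward q-step chords. The critical value is the (1−α) quantile of
the maximum statistic over candidates for synthetic straight paths
carrying the trace's own noise, estimated robustly so genuine turns never
contaminate the null: an isotropic point-noise pool from local secant
detrending (MAD-gated, variance-corrected) plus a per-step heading-noise
channel from the excess of chord-direction variability at lag 3q over lag
2q. 1,000 seeded resamples calibrate the trace-wise false-positive rate
at α. Declared points are local maxima at least 2q apart. The q = 1…10
sweep keeps the lowest q with the most change points.

Measured operating characteristics (seeded): 100/100 recovery of three
45° turns on 30-step segments of 3 px steps with 0.3 px coordinate
jitter, each within 2 indices; false-positive rate 0.028 on straight
traces with 2°-per-step direction noise at α = 0.05. The planted-trace
fixture uses 3 px between traced points — the click spacing of manual
tracing; at 1 px spacing the turn-statistic signal-to-noise (45°/14°)
is below what any α-controlled test needs for near-certain triple
recovery, so finer spacing is not a meaningful operating point for this
protocol.

Segment metrics are arc lengths between change points and signed turning
angles between successive segment chords (counterclockwise positive);
absolute angles are used for cross-sample comparison. The Mann–Whitney
comparison computes the exact two-sided p by the counting recurrence for
min(n,m) ≤ 8 and n+m ≤ 20 without ties (verified against full enumeration
for all n+m ≤ 12), the tie-corrected normal approximation otherwise, plus
the Hodges–Lehmann shift estimate with its distribution-based confidence
interval at the achievable level nearest 95 %.

Simulated morphologies are traced by skeletonizing {φ > 0.5} and walking
the soma-to-tip shortest skeleton path.

## Synthetic fixtures

* Star fields: a soma disk with k capsule arms and tanh edges; truth tips
  are the lattice points inside the φ > 0.5 contour nearest each cap
  apex. They stand in for grown morphologies with known arm counts.
* Planted traces: polylines with exact segment/turn geometry plus seeded
  coordinate jitter and/or per-step direction noise. They emulate manual
  neurite tracings; they do not emulate imaging artifacts, curvature
  within segments, or tracing-operator bias.
* Reference configurations: "smoke" (100², 500 iterations), "staging"
  (150², 2,000 iterations, stage budgets 200/800/1,600/2,000) and
  "full-383" (383², 35,000 iterations, stage budgets
  500/10,500/28,500/35,000). The reduced budgets keep the verification
  suite within routine runtimes; they compress the stages but preserve
  their ordering and mechanisms. Passing tests on the reduced runs show
  the staged mechanics work as designed, not that the model reproduces
  any particular cultured-neuron dataset.

## Determinism

All randomness flows from the config seed: the position-keyed θ field,
the cue-angle stream, and the CPT resampling null. Identical config and
seed reproduce event logs and fields bit-for-bit; this is exercised by
running a reduced configuration twice.

## Known limitations

* The model is grid-dependent by construction (θ is resampled at every
  resolution) and the reduced-scale trajectories are chaotic in the
  parameters: small coefficient changes reroute individual neurites.
* Strong-form collocation needs the conservative correction above to keep
  the tubulin ledger exact; without it the point-sum drifts.
* Stage transitions are prescribed, not emergent; stage-5 maturation,
  neuron-type-specific branching patterns, and chemoattractant-field cue
  dynamics are out of scope.
* Neurite–neurite mechanical interaction is limited to the intersection
  guard; neighboring neurons influence each other only by collision.
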