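# neurongrowth

Phase-field simulation of multi-stage neuron growth driven by intracellular
tubulin transport, solved by isogeometric collocation on tensor-product
cubic B-splines, together with the change-point-test morphometrics used to
compare simulated and hand-traced neurite geometries.

The package is aimed at computational neuroscientists and numerical-methods
researchers studying neuronal morphogenesis: it reproduces, at configurable
scale, the four early stages of neuron development — lamellipodia formation,
initial neurite outgrowth, axon differentiation, and dendrite formation —
from a single circular cell, and provides the statistical pipeline
(change-point segmentation, turning angles, Mann–Whitney comparison) for
validating simulated morphologies against traced micrographs.

## Model

The neuron is a phase field φ (1 inside the cell, 0 in the medium) evolving
by a dendritic-solidification-type law with orientation-dependent gradient
coefficient a(Ψ) = ā(1 + δ cos j(Ψ − θ₀)):

```
∂φ/∂t = M_φ [ ∇·(a²∇φ) − ∂x(a a' ∂φ/∂y) + ∂y(a a' ∂φ/∂x)
              + φ(1−φ)(φ − ½ + E + 6H|∇θ|) ]
```

θ is a static random orientation field; its gradient magnitude perturbs the
double-well tilt and seeds lamellipodia. Intracellular tubulin c_tub is
produced at the initial cell membrane, transported by diffusion and
(optionally radial) active transport, and decays:

```
∂(φ c)/∂t = δ_t ∇·(φ∇c) − α_t·∇(φc) − β_t φc + ε₀ |∇φ₀|²/∫|∇φ₀|²
```

Neurite tips are detected on the φ field; each tip's extension rate is
dL/dt = r_g·c_tub − s_g, and growth is driven only inside 6×6 activation
zones around tips through

```
E = (α/π) · atan( H_ε(dL/dt) · γ · ΔT )
```

with ΔT the undercooling evolved by a latent-heat-coupled heat equation. At
the axon-differentiation stage the neurite with the longest geodesic length
gets the elevated tip assembly rate r_g^tip while all others are rate-gated
to E = 0; extracellular cues sampled from the measured turning-angle
distribution (mean 41.673°, sd 32.007°) steer the activation zones.

The strong form is collocated at Greville abscissae of an open uniform cubic
B-spline space and advanced with implicit Euler + Newton (residual tolerance
1e-4); the domain auto-extends by 10 grid points per side when a neurite
approaches the boundary.

## Worked example

Run the reduced staging simulation (150×150 grid, 2,000 iterations through
all four stages) and analyze the grown morphology:

```
neurongrowth run --preset staging --outdir out/
```

which writes snapshots plus an event log. The same run through the Python
API:

```python
from neurongrowth.fixtures import reference_configs
from neurongrowth.time_integrator import run_simulation

result = run_simulation(reference_configs()["staging"])
tips = [e for e in result.events if e["event"] == "tips"][-1]["tips"]
print(len(tips), sorted(round(t["length"], 1) for t in tips)[-3:])
```

prints `9 [80.8, 95.5, 128.8]` — nine neurites at the end of stage 4, the
differentiated axon having grown to a geodesic length of ≈129 grid units
while the others trail far behind: during stage 3 the axon gains +37.2
units of geodesic length while the median competitor *loses* 2.6 (curvature
retraction with the driving force gated off).

Morphometrics of traced neurites (CSV polylines with header `x,y`):

```
neurongrowth analyze --traces traces/ --alpha 0.05 --qmax 10
neurongrowth compare --a culture_angles.csv --b model_angles.csv
```

`compare` on the canonical separated samples `{1,2,3}` vs `{4,5,6}` prints
`U = 0.0, two-sided p = 0.1 (exact)` with the Hodges–Lehmann shift estimate
`-3.0` — the exact enumeration result.

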