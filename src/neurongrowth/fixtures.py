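"""Synthetic inputs with known ground truth.

Star-shaped phase fields with a known number of arms exercise tip
detection; polylines with planted turn locations and angles exercise the
change point test; reduced reference configurations exercise the staged
growth loop at desk scale.  Fixture truth is constructed geometrically,
independently of the detectors under test, and every fixture is
byte-reproducible from its seed and spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import ConfigurationError
from .growth_model import ModelParameters, StageSchedule
from .morphometrics import Trace

__all__ = [
    "StarFixture", "PlantedTrace", "make_star_phi", "make_planted_trace",
    "reference_configs",
]


@dataclass(frozen=True)
class StarFixture:
    """A soma disk with k straight arms at equal angular spacing.

    Truth tips sit at the apex of each arm's rounded end (where the
    phi = 0.5 contour is farthest from the center).
    """
    k: int = 4
    arm_length: float = 30.0
    arm_width: float = 5.0
    soma_radius: float = 15.0
    edge_width: float = 1.0        # tanh falloff width of the interface
    angle_offset: float = 0.0      # rotation of the first arm, radians

    def __post_init__(self):
        if self.k < 2:
            raise ConfigurationError(f"need k >= 2 arms, got {self.k}")
        if self.k > 2 or self.arm_length > 0:
            # adjacent arm tips must not touch: chord between arm axes at
            # the soma boundary must exceed the arm width
            chord = 2.0 * self.soma_radius * math.sin(math.pi / self.k)
            if self.arm_length > 0 and chord <= self.arm_width + 2.0:
                raise ConfigurationError(
                    "arms overlap: angular spacing too small for arm width")


def _segment_distance(px, py, ax, ay, bx, by):
    """Distance from points (px, py) to segment (a, b)."""
    abx, aby = bx - ax, by - ay
    ab2 = abx * abx + aby * aby
    t = ((px - ax) * abx + (py - ay) * aby) / ab2 if ab2 > 0 else 0.0
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (ax + t * abx), py - (ay + t * aby))


def make_star_phi(fixture: StarFixture, shape, center=None):
    """Phase field of the star plus ground-truth tip lattice positions.

    ``phi = 1`` on the soma disk and arms with a smooth tanh falloff at
    the edges; the phi > 0.5 region is exactly the union of the disk and
    the arm capsules.

    Raises
    ------
    ConfigurationError
        If the star does not fit inside the grid with a margin.
    """
    nu, nv = shape
    if center is None:
        center = ((nu - 1) / 2.0, (nv - 1) / 2.0)
    cx, cy = center
    reach = fixture.soma_radius + fixture.arm_length + fixture.arm_width / 2
    margin = 3.0 * fixture.edge_width + 2.0
    if (cx - reach < margin or cx + reach > nu - 1 - margin or
            cy - reach < margin or cy + reach > nv - 1 - margin):
        raise ConfigurationError("star does not fit inside the grid")

    X, Y = np.meshgrid(np.arange(nu, dtype=float),
                       np.arange(nv, dtype=float), indexing="ij")
    sdf = np.hypot(X - cx, Y - cy) - fixture.soma_radius
    truth = []
    if fixture.arm_length > 0:
        half_w = fixture.arm_width / 2.0
        end_r = fixture.soma_radius + fixture.arm_length
        for arm in range(fixture.k):
            ang = fixture.angle_offset + 2.0 * math.pi * arm / fixture.k
            dx, dy = math.cos(ang), math.sin(ang)
            ex, ey = cx + end_r * dx, cy + end_r * dy
            d = _segment_distance(X, Y, cx, cy, ex, ey) - half_w
            sdf = np.minimum(sdf, d)
            truth.append((ex + half_w * dx, ey + half_w * dy))
    phi = 0.5 * (1.0 + np.tanh(-sdf / fixture.edge_width))
    # discrete truth: the lattice point inside the phi > 0.5 contour
    # nearest to each continuous cap apex (the apex itself can round to a
    # point just outside the contour)
    mi, mj = np.nonzero(phi > 0.5)
    truth = [
        (int(mi[k]), int(mj[k]))
        for k in (int(np.argmin((mi - ax) ** 2 + (mj - ay) ** 2))
                  for ax, ay in truth)
    ]
    return phi, truth


@dataclass(frozen=True)
class PlantedTrace:
    """A polyline with known turn locations/angles plus seeded noise.

    Two noise channels: ``noise_sd`` jitters point coordinates (tracing
    error), ``direction_noise_sd`` perturbs the heading of every step
    (path meander) — the null model for false-positive control.
    """
    segment_steps: tuple = (30, 30, 30, 30)
    turn_angles: tuple = (45.0, 45.0, 45.0)   # signed degrees, ccw positive
    step_length: float = 3.0      # px between traced points (manual tracing
                                  # clicks are several pixels apart)
    noise_sd: float = 0.3                     # pixel jitter on coordinates
    direction_noise_sd: float = 0.0           # per-step heading noise, degrees
    seed: int = 0

    def __post_init__(self):
        if len(self.turn_angles) != len(self.segment_steps) - 1:
            raise ConfigurationError(
                "need one turn angle per internal segment boundary")
        if any(s < 1 for s in self.segment_steps):
            raise ConfigurationError("segments need at least one step")

    @property
    def truth_indices(self) -> np.ndarray:
        """Trace point indices of the planted turns."""
        return np.cumsum(self.segment_steps[:-1])


def make_planted_trace(spec: PlantedTrace):
    """Build the trace; returns ``(Trace, truth_change_point_indices)``."""
    rng = np.random.default_rng(spec.seed)
    heading = 0.0
    pts = [np.zeros(2)]
    for si, steps in enumerate(spec.segment_steps):
        for _ in range(steps):
            h = heading
            if spec.direction_noise_sd > 0:
                h += math.radians(rng.normal(0.0, spec.direction_noise_sd))
            d = np.array([math.cos(h), math.sin(h)])
            pts.append(pts[-1] + spec.step_length * d)
        if si < len(spec.turn_angles):
            heading += math.radians(spec.turn_angles[si])
    pts = np.array(pts)
    if spec.noise_sd > 0:
        pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
    return Trace(points=pts), spec.truth_indices


def reference_configs() -> dict:
    """Named reduced configurations of the single-neuron growth run.

    ``smoke`` (about 100x100, 500 iterations) checks the pipeline end to
    end; ``staging`` (about 150x150, 2,000 iterations) reproduces the four
    stages at reduced scale; ``full-383`` is the full-scale single-neuron
    setup (383x383, 35,000 iterations) and is not meant for routine test
    runs.
    """
    smoke = RunConfig(
        name="smoke", nu=100, nv=100, centers=[[50.0, 50.0]],
        params=ModelParameters(
            schedule=StageSchedule(50, 250, 400, 500)),
        snapshot_every=250,
    )
    staging = RunConfig(
        name="staging", nu=150, nv=150, centers=[[75.0, 75.0]],
        params=ModelParameters(
            schedule=StageSchedule(200, 800, 1600, 2000)),
        snapshot_every=500,
    )
    full = RunConfig(
        name="full-383", nu=383, nv=383, centers=[[191.0, 191.0]],
        params=ModelParameters(
            schedule=StageSchedule(500, 10_500, 28_500, 35_000)),
        snapshot_every=2500,
    )
    return {"smoke": smoke, "staging": staging, "full-383": full}
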