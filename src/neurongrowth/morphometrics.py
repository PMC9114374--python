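"""Change-point-test segmentation and turning-angle morphometrics.

A traced neurite is an ordered (x, y) polyline.  The change point test
(CPT) finds locations of significant direction change by comparing the
mean direction of the q step vectors before a candidate point with the q
step vectors after it.  The deviation statistic is the absolute angle
between the backward and forward q-step chords; significance is assessed
against a seeded isotropic direction-noise null: the trace's own
coordinate-noise and heading-noise amplitudes are estimated robustly (so
genuine turns do not contaminate them) and laid along straight synthetic
paths, whose maximum statistic calibrates the critical value — the
per-trace false-positive rate is controlled at the significance level
alpha.  Following the standard protocol, the test is run for q = 1..10
and the lowest q that yields the most change points is selected.

Segments between change points yield lengths and turning angles (each
segment's chord direction relative to the previous segment's,
counterclockwise positive); absolute turning angles are the quantity
compared across samples with the Mann-Whitney U test and a Hodges-Lehmann
shift estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InsufficientLengthError

__all__ = [
    "Trace", "ChangePointSet", "AngleSummary", "MannWhitneyResult",
    "load_trace", "save_trace", "change_point_test", "select_q",
    "segment_metrics", "summarize_angles", "mann_whitney_compare",
    "extract_trace", "angle_table",
]


@dataclass
class Trace:
    """Ordered polyline of a neurite in pixel or grid units."""
    points: np.ndarray              # (n, 2)
    scale: float = 1.0              # physical units per pixel

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 \
                or len(self.points) < 2:
            raise ValueError("a trace needs at least two (x, y) points")
        steps = np.diff(self.points, axis=0)
        if np.any(np.all(steps == 0.0, axis=1)):
            raise ValueError("consecutive trace points must be distinct")

    @property
    def n_steps(self) -> int:
        return len(self.points) - 1


@dataclass
class ChangePointSet:
    """CPT segmentation of one trace."""
    indices: np.ndarray             # change-point indices into the trace
    q: int
    alpha: float
    seg_lengths: np.ndarray         # per-segment arc length (scaled)
    turn_angles: np.ndarray         # signed turning angles, degrees
    turn_angles_abs: np.ndarray
    statistic: np.ndarray = field(default=None, repr=False)
    critical_value: float = float("nan")

    @property
    def n_change_points(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class AngleSummary:
    """Table-style summary of an angle (or length) sample, in degrees."""
    mean: float
    sd: float
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_value: float
    shift_estimate: float           # Hodges-Lehmann estimate of a - b
    ci_low: float
    ci_high: float
    ci_level: float                 # achieved confidence level
    method: str                     # "exact" or "asymptotic"


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def load_trace(path, scale: float = 1.0) -> Trace:
    """Read a trace from CSV with header ``x,y`` (one row per point)."""
    df = pd.read_csv(path)
    return Trace(points=df[["x", "y"]].to_numpy(dtype=float), scale=scale)


def save_trace(trace: Trace, path) -> None:
    pd.DataFrame(trace.points, columns=["x", "y"]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# change point test
# --------------------------------------------------------------------------

def _chord_angles(cum: np.ndarray, cand: np.ndarray, q: int) -> np.ndarray:
    """|angle| between backward and forward q-step chords at candidates.

    ``cum`` is the cumulative-sum array of step vectors with a leading
    zero row, shape (..., n_steps + 1, 2).
    """
    back = cum[..., cand, :] - cum[..., cand - q, :]
    fwd = cum[..., cand + q, :] - cum[..., cand, :]
    cross = back[..., 0] * fwd[..., 1] - back[..., 1] * fwd[..., 0]
    dot = back[..., 0] * fwd[..., 0] + back[..., 1] * fwd[..., 1]
    return np.abs(np.degrees(np.arctan2(cross, dot)))


def change_point_test(trace: Trace, alpha: float = 0.05, q: int = 2,
                      n_permutations: int = 1000,
                      seed: int = 0, presmooth: int = 1) -> ChangePointSet:
    """Locate significant direction changes along a trace.

    The statistic at candidate point i is the absolute angle between the
    chord spanning the q steps before i and the chord spanning the q steps
    after.  Its critical value is the (1 - alpha) quantile of the maximum
    statistic over all candidates for a straight path carrying the trace's
    own coordinate noise: each point's isotropic noise amplitude is
    estimated by local secant detrending (perpendicular offset of a point
    from the chord joining its q-th neighbors, rescaled; a robust MAD
    scale, so planted turns do not inflate the estimate), and
    ``n_permutations`` sign-flipped shuffles of those residuals laid along
    a straight path give the null maxima.  A straight path with direction
    noise therefore yields a change point with probability about alpha,
    while the null is never contaminated by the very turns under test.
    Declared points are local maxima of the statistic at least q indices
    apart.

    Raises
    ------
    InsufficientLengthError
        If the trace has fewer than 2q + 1 points.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if q < 1:
        raise ValueError(f"q must be >= 1, got {q}")
    n_steps = trace.n_steps
    if n_steps < 2 * q:
        raise InsufficientLengthError(
            f"trace with {n_steps + 1} points is too short for q = {q}")
    steps = np.diff(trace.points, axis=0)
    cand = np.arange(q, n_steps - q + 1)
    # light moving-average smoothing of the coordinates suppresses pixel
    # jitter before the direction comparison; the null paths below pass
    # through the identical filter, so the test stays calibrated
    if presmooth > 1:
        sm = ndimage.uniform_filter1d(trace.points, presmooth, axis=0,
                                      mode="nearest")
    else:
        sm = trace.points
    cum = np.vstack([np.zeros(2), np.cumsum(np.diff(sm, axis=0), axis=0)])
    stat = _chord_angles(cum, cand, q)

    # local secant detrending of the raw points: perpendicular offset of
    # point i from the chord (p[i-q], p[i+q]); for a straight path with
    # iid point noise the offset variance is 1.5 sigma^2
    pts = trace.points
    sec = pts[2 * q:] - pts[:-2 * q]
    sec_len = np.linalg.norm(sec, axis=1)
    sec_len[sec_len == 0] = 1.0
    mid = pts[q:n_steps - q + 1]
    rel = mid - pts[:-2 * q]
    offs = (rel[:, 1] * sec[:, 0] - rel[:, 0] * sec[:, 1]) / sec_len
    mean_step = float(np.mean(np.linalg.norm(steps, axis=1)))
    # drop the few turn-contaminated offsets (robust MAD gate), keep the
    # noise-carrying bulk; 1/sqrt(1.5) undoes the detrending inflation
    mad = float(np.median(np.abs(offs)))
    keep = np.abs(offs) <= max(3.5 * mad / 0.6745, 1e-12)
    pool = (offs[keep] if keep.any() else np.zeros(1)) / np.sqrt(1.5)

    # second noise channel: slow heading meander.  The walk variance per
    # step is the excess of chord-direction variability at lag 3q over lag
    # 2q (both lags use disjoint windows, so the point-jitter contribution
    # cancels); robust MAD variances keep planted turns out of the
    # estimate.
    sigma_walk = 0.0
    csteps = np.diff(sm, axis=0)
    ccum = np.vstack([np.zeros(2), np.cumsum(csteps, axis=0)])
    chord = ccum[q:] - ccum[:-q]
    cdir = np.arctan2(chord[:, 1], chord[:, 0])

    def _robust_var(d):
        d = (d + np.pi) % (2 * np.pi) - np.pi
        return (1.4826 * np.median(np.abs(d - np.median(d)))) ** 2

    if len(cdir) > 3 * q + 4:
        v2 = _robust_var(cdir[2 * q:] - cdir[:-2 * q])
        v3 = _robust_var(cdir[3 * q:] - cdir[:-3 * q])
        sigma_walk = math.sqrt(max(v3 - v2, 0.0) / q)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(pool), size=(n_permutations, n_steps + 1))
    signs = rng.integers(0, 2, size=idx.shape) * 2.0 - 1.0
    noise = pool[idx] * signs
    # straight path of the trace's mean step length, bent by the estimated
    # heading walk, plus resampled point noise on the perpendicular
    # component (the statistic is rotation invariant)
    null_pts = np.zeros((n_permutations, n_steps + 1, 2))
    if sigma_walk > 0:
        headings = np.cumsum(
            rng.normal(0.0, sigma_walk, size=(n_permutations, n_steps)),
            axis=1)
        null_pts[:, 1:, 0] = mean_step * np.cumsum(np.cos(headings), axis=1)
        null_pts[:, 1:, 1] = mean_step * np.cumsum(np.sin(headings), axis=1)
    else:
        null_pts[..., 0] = mean_step * np.arange(n_steps + 1)
    null_pts[..., 1] += noise
    if presmooth > 1:
        null_pts = ndimage.uniform_filter1d(null_pts, presmooth, axis=1,
                                            mode="nearest")
    null_steps = np.diff(null_pts, axis=1)
    null_cum = np.concatenate(
        [np.zeros((n_permutations, 1, 2)), np.cumsum(null_steps, axis=1)],
        axis=1)
    perm_stat = _chord_angles(null_cum, cand, q)   # (B, n_cand)
    crit = float(np.quantile(perm_stat.max(axis=1), 1.0 - alpha))

    above = stat > crit
    picked = []
    for k in np.argsort(-stat, kind="stable"):
        if not above[k]:
            break
        if all(abs(cand[k] - cand[j]) >= 2 * q for j in picked):
            picked.append(k)
    indices = np.sort(cand[picked]).astype(int)

    lengths, angles, angles_abs = segment_metrics(
        trace, indices, scale=trace.scale)
    return ChangePointSet(indices=indices, q=q, alpha=alpha,
                          seg_lengths=lengths, turn_angles=angles,
                          turn_angles_abs=angles_abs, statistic=stat,
                          critical_value=crit)


def select_q(trace: Trace, alpha: float = 0.05, q_range=range(1, 11),
             n_permutations: int = 1000, seed: int = 0, presmooth: int = 1):
    """Run the CPT over a range of q and keep the lowest q that yields the
    most change points.

    Returns ``(q, ChangePointSet)``.  q values the trace is too short for
    are skipped; if all are skipped the length error propagates.
    """
    results = {}
    last_err = None
    for q in q_range:
        try:
            results[q] = change_point_test(trace, alpha=alpha, q=q,
                                           n_permutations=n_permutations,
                                           seed=seed, presmooth=presmooth)
        except InsufficientLengthError as err:
            last_err = err
    if not results:
        raise last_err
    best_count = max(c.n_change_points for c in results.values())
    q = min(q for q, c in results.items() if c.n_change_points == best_count)
    return q, results[q]


def segment_metrics(trace: Trace, change_points, scale: float | None = None):
    """Per-segment arc lengths and turning angles for a segmentation.

    The turning angle of a segment is the signed angle (counterclockwise
    positive, degrees) between its chord direction and the previous
    segment's chord direction; absolute values are returned alongside.

    Returns ``(lengths, signed_angles, abs_angles)``.
    """
    if scale is None:
        scale = trace.scale
    if hasattr(change_points, "indices"):
        change_points = change_points.indices
    idx = np.asarray(change_points, dtype=int)
    bounds = np.concatenate([[0], idx, [len(trace.points) - 1]])
    step_len = np.linalg.norm(np.diff(trace.points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(step_len)])
    lengths = (cum[bounds[1:]] - cum[bounds[:-1]]) * scale
    chords = trace.points[bounds[1:]] - trace.points[bounds[:-1]]
    angles = []
    for k in range(1, len(chords)):
        v0, v1 = chords[k - 1], chords[k]
        cross = v0[0] * v1[1] - v0[1] * v1[0]
        dot = v0[0] * v1[0] + v0[1] * v1[1]
        angles.append(math.degrees(math.atan2(cross, dot)))
    angles = np.asarray(angles)
    return lengths, angles, np.abs(angles)


# --------------------------------------------------------------------------
# summaries and comparison
# --------------------------------------------------------------------------

def summarize_angles(angles) -> AngleSummary:
    """Mean, sd (n-1 denominator; 0 for a single value by convention),
    minimum, linearly interpolated quartiles, median and maximum."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("cannot summarize an empty sample")
    sd = float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    return AngleSummary(mean=float(np.mean(a)), sd=sd,
                        minimum=float(a.min()), q1=float(q1),
                        median=float(med), q3=float(q3),
                        maximum=float(a.max()))


def angle_table(samples: dict) -> pd.DataFrame:
    """Table of angle-summary rows (one per named sample)."""
    rows = {}
    for name, sample in samples.items():
        s = summarize_angles(sample)
        rows[name] = {"mean": s.mean, "sd": s.sd, "minimum": s.minimum,
                      "q1": s.q1, "median": s.median, "q3": s.q3,
                      "maximum": s.maximum}
    return pd.DataFrame(rows).T


def _u_null_cdf(n: int, m: int) -> np.ndarray:
    """Exact null CDF of U (no ties) by dynamic programming.

    Uses the recurrence on (n, m): the largest observation is an a with
    probability n/(n+m) (then U gains m) or a b (then U is unchanged),
    giving counts N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1).
    """
    # table[u] for current (i, j)
    tables = {}

    def counts(i, j):
        if (i, j) in tables:
            return tables[(i, j)]
        if i == 0 or j == 0:
            c = np.zeros(i * j + 1)
            c[0] = 1.0
            tables[(i, j)] = c
            return c
        a = counts(i - 1, j)
        b = counts(i, j - 1)
        c = np.zeros(i * j + 1)
        c[j:j + len(a)] += a          # largest value is an a: U += j
        c[:len(b)] += b               # largest value is a b
        tables[(i, j)] = c
        return c

    c = counts(n, m)
    return np.cumsum(c) / c.sum()


def mann_whitney_compare(a, b, ci_target: float = 0.95) -> MannWhitneyResult:
    """Mann-Whitney U comparison with a Hodges-Lehmann shift estimate.

    The p-value is exact (full null enumeration via the counting
    recurrence) for ``min(n, m) <= 8`` and ``n + m <= 20`` without ties,
    otherwise the tie-corrected normal approximation is used.  The shift
    estimate is the median of all pairwise differences ``a_i - b_j``; its
    confidence interval is the distribution-based interval at the
    achievable level nearest ``ci_target``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(a), len(b)
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    U = float(sum((x > y) + 0.5 * (x == y) for x in a for y in b)) \
        if n * m <= 10000 else float(
            stats.mannwhitneyu(a, b, alternative="two-sided").statistic)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n + m

    exact = (min(n, m) <= 8 and n + m <= 20 and not has_ties)
    if exact:
        cdf = _u_null_cdf(n, m)
        u_int = int(round(U))
        p_low = cdf[u_int]
        p_high = 1.0 - (cdf[u_int - 1] if u_int > 0 else 0.0)
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"

    # distribution-based CI for the shift
    K = n * m
    if K <= 2500 and not has_ties:
        cdf = _u_null_cdf(n, m)
        cs = np.concatenate([[0.0], cdf])   # cs[c+1] = P(U <= c)
        levels = 1.0 - 2.0 * cs[:K // 2 + 1]
        cbest = int(np.argmin(np.abs(levels - ci_target)))
        c = cbest - 1                        # P(U <= c) tail count
        achieved = float(levels[cbest])
        lo_idx = max(c + 1, 0)
        hi_idx = K - 1 - max(c + 1, 0)
        if lo_idx > hi_idx:
            lo_idx, hi_idx = 0, K - 1
            achieved = 1.0
        ci_low, ci_high = float(diffs[lo_idx]), float(diffs[hi_idx])
    else:
        sigma = math.sqrt(n * m * (n + m + 1) / 12.0)
        z = stats.norm.ppf(1.0 - (1.0 - ci_target) / 2.0)
        c = int(math.floor(n * m / 2.0 - z * sigma))
        c = max(c, 0)
        ci_low = float(diffs[c]) if c < K else float(diffs[0])
        ci_high = float(diffs[K - 1 - c]) if c < K else float(diffs[-1])
        achieved = ci_target
    return MannWhitneyResult(U=U, p_value=float(p),
                             shift_estimate=float(np.median(diffs)),
                             ci_low=ci_low, ci_high=ci_high,
                             ci_level=achieved, method=method)


# --------------------------------------------------------------------------
# trace extraction from simulated fields
# --------------------------------------------------------------------------

def extract_trace(phi: np.ndarray, soma_center, tip=None,
                  threshold: float = 0.5) -> Trace:
    """Soma-to-tip skeleton path of ``{phi > threshold}`` as a Trace.

    The mask is skeletonized; the trace is the shortest skeleton path from
    the point nearest the soma center to ``tip`` (or to the geodesically
    farthest skeleton point when ``tip`` is None).
    """
    from skimage.morphology import skeletonize
    from scipy.sparse.csgraph import dijkstra
    from .neurite_topology import _lattice_graph, _snap_to_mask

    mask = phi > threshold
    skel = skeletonize(mask)
    g, idx, pts = _lattice_graph(skel)
    si, sj = _snap_to_mask(skel, soma_center, max_dist=max(phi.shape))
    source = idx[si, sj]
    dist, preds = dijkstra(g, directed=False, indices=source,
                           return_predecessors=True)
    if tip is None:
        finite = np.where(np.isfinite(dist))[0]
        target = int(finite[np.argmax(dist[finite])])
    else:
        ti, tj = _snap_to_mask(skel, tip, max_dist=max(phi.shape))
        target = int(idx[ti, tj])
    path = [target]
    while path[-1] != source:
        p = preds[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    path.reverse()
    coords = np.array([np.unravel_index(pts[p], mask.shape) for p in path],
                      dtype=float)
    return Trace(points=coords)
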