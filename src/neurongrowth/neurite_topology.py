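"""Discrete geometric reasoning on the phase field.

Everything here works in lattice index space (row = u/x, column = v/y):
neuron labeling by connected components, neurite tip detection, activation
zone masks, geodesic lengths along the neurite, axon selection,
extracellular cue placement, and the same-neuron self-intersection guard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import (
    DisconnectedTipError,
    EmptyStateError,
    SelectionError,
)
from .growth_model import RateParams, CueParams

__all__ = [
    "Tip", "CuePlacement", "label_components", "detect_tips",
    "activation_zones", "geodesic_length", "geodesic_map", "select_axon",
    "place_extracellular_cue", "intersection_guard", "export_swc",
]

_EIGHT = np.ones((3, 3), dtype=bool)
# 8-neighborhood shifts and their step lengths
_SHIFTS = [(-1, 0, 1.0), (1, 0, 1.0), (0, -1, 1.0), (0, 1, 1.0),
           (-1, -1, math.sqrt(2)), (-1, 1, math.sqrt(2)),
           (1, -1, math.sqrt(2)), (1, 1, math.sqrt(2))]


@dataclass
class Tip:
    """A detected neurite tip.

    ``position`` is the lattice index of the tip point; ``zone_center`` is
    where the activation zone is placed (shifted toward the extracellular
    cue when one is active, otherwise the tip itself).
    """
    position: tuple
    neuron_id: int
    neurite_id: int
    geodesic_length: float
    c_tub_local: float = 0.0
    heading: np.ndarray | None = None
    rate_r: float = 0.0
    rate_s: float = 0.0
    zone_center: tuple = None
    history: list = field(default_factory=list)

    def __post_init__(self):
        if self.zone_center is None:
            self.zone_center = tuple(int(round(x)) for x in self.position)


@dataclass(frozen=True)
class CuePlacement:
    """An extracellular cue at a fixed distance from a tip."""
    position: tuple          # (i, j) lattice coordinates, float
    tip_id: int              # neurite id of the target tip
    angle_deg: float         # sampled signed turning angle, degrees


# --------------------------------------------------------------------------
# labeling
# --------------------------------------------------------------------------

def label_components(phi: np.ndarray, threshold: float = 0.5,
                     soma_centers=None) -> np.ndarray:
    """Label the 8-connected components of ``{phi > threshold}``.

    When soma lattice positions are given, the component containing soma k
    is relabeled k + 1 (neuron identity); components containing no soma get
    fresh ids after the neurons.

    Raises
    ------
    EmptyStateError
        If there is no component above threshold.
    """
    mask = phi > threshold
    lab, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        raise EmptyStateError("no connected component above threshold")
    if soma_centers is None:
        return lab.astype(np.int32)
    out = np.zeros_like(lab, dtype=np.int32)
    used = set()
    for k, (ci, cj) in enumerate(np.atleast_2d(soma_centers), start=1):
        comp = lab[int(round(ci)), int(round(cj))]
        if comp > 0:
            out[lab == comp] = k
            used.add(comp)
    nxt = len(np.atleast_2d(soma_centers)) + 1
    for comp in range(1, n + 1):
        if comp not in used and np.any((lab == comp) & (out == 0)):
            out[lab == comp] = nxt
            nxt += 1
    return out


# --------------------------------------------------------------------------
# geodesics
# --------------------------------------------------------------------------

def _lattice_graph(mask: np.ndarray):
    """Sparse 8-connected graph over mask points (diagonals weighted sqrt 2)."""
    idx = np.full(mask.shape, -1, dtype=np.int64)
    pts = np.flatnonzero(mask)
    idx.flat[pts] = np.arange(len(pts))
    rows_list, cols_list, w_list = [], [], []
    ii, jj = np.nonzero(mask)
    for di, dj, w in _SHIFTS:
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < mask.shape[0]) & (nj >= 0) & (nj < mask.shape[1])
        ok[ok] &= mask[ni[ok], nj[ok]]
        rows_list.append(idx[ii[ok], jj[ok]])
        cols_list.append(idx[ni[ok], nj[ok]])
        w_list.append(np.full(ok.sum(), w))
    rows = np.concatenate(rows_list)
    cols = np.concatenate(cols_list)
    data = np.concatenate(w_list)
    g = csr_matrix((data, (rows, cols)), shape=(len(pts), len(pts)))
    return g, idx, pts


def _snap_to_mask(mask: np.ndarray, point, max_dist: float = 5.0):
    i, j = int(round(point[0])), int(round(point[1]))
    i = min(max(i, 0), mask.shape[0] - 1)
    j = min(max(j, 0), mask.shape[1] - 1)
    if mask[i, j]:
        return i, j
    ii, jj = np.nonzero(mask)
    d2 = (ii - point[0]) ** 2 + (jj - point[1]) ** 2
    k = int(np.argmin(d2))
    if d2[k] > max_dist ** 2:
        raise DisconnectedTipError(
            f"point {point} is farther than {max_dist} from the mask")
    return int(ii[k]), int(jj[k])


def geodesic_map(phi: np.ndarray, source, threshold: float = 0.5) -> np.ndarray:
    """Geodesic distance from ``source`` on the 8-connected ``phi > threshold``
    lattice graph (diagonal steps weighted sqrt 2); inf off the component."""
    mask = phi > threshold
    if not mask.any():
        raise EmptyStateError("no points above threshold")
    si, sj = _snap_to_mask(mask, source)
    g, idx, pts = _lattice_graph(mask)
    d = dijkstra(g, directed=False, indices=idx[si, sj])
    out = np.full(phi.shape, np.inf)
    out.flat[pts] = d
    return out


def geodesic_length(phi: np.ndarray, soma_center, tip,
                    threshold: float = 0.5) -> float:
    """Shortest-path length from the cell center to the tip along the neurite.

    Raises
    ------
    DisconnectedTipError
        If tip and center are not in the same component.
    """
    d = geodesic_map(phi, soma_center, threshold=threshold)
    ti, tj = _snap_to_mask(phi > threshold, tip)
    val = d[ti, tj]
    if not np.isfinite(val):
        raise DisconnectedTipError(
            f"tip {tip} not connected to center {soma_center}")
    return float(val)


# --------------------------------------------------------------------------
# tip detection
# --------------------------------------------------------------------------

def _estimate_soma(mask: np.ndarray):
    """Soma center/radius estimate: the maximum inscribed disk (EDT peak)."""
    edt = ndimage.distance_transform_edt(mask)
    k = int(np.argmax(edt))
    ci, cj = np.unravel_index(k, mask.shape)
    return (int(ci), int(cj)), float(edt[ci, cj])


def detect_tips(phi: np.ndarray, neuron_labels: np.ndarray | None = None,
                soma_centers=None, soma_radius: float | None = None,
                threshold: float = 0.5, smooth: bool = True,
                exclusion_factor: float = 1.05,
                min_protrusion: float = 2.0,
                min_separation: float = 4.0) -> list:
    """Detect one tip per neurite arm.

    A tip is the centroid of a cluster of geodesically extremal points:
    mask points whose geodesic distance from the soma is a local maximum
    over the 8-neighborhood and exceeds the soma exclusion radius
    ``exclusion_factor * r_soma + min_protrusion``.  These are exactly the
    regional-phi-maximum points with fewest occupied neighbors for a
    neurite arm, but the geodesic formulation is robust to the small
    oscillations collocation fields carry near interfaces.  Points inside
    the soma are never tips; a bare disk yields an empty list.

    ``phi`` is mean-filtered over 3x3 before thresholding when ``smooth``
    (switchable).  When ``min_separation`` > 0, tips of the same neuron
    closer than that (Euclidean) are merged, keeping the most protruding
    one — one growth cone per emerging neurite.
    """
    f = ndimage.uniform_filter(phi, size=3) if smooth else phi
    mask_all = f > threshold
    if not mask_all.any():
        return []
    if neuron_labels is None:
        neuron_labels, _ = ndimage.label(mask_all, structure=_EIGHT)
    tips = []
    neurite_counter = 0
    for nid in sorted(int(v) for v in np.unique(neuron_labels) if v > 0):
        mask = (neuron_labels == nid) & mask_all
        if not mask.any():
            continue
        if soma_centers is not None:
            centers = np.atleast_2d(soma_centers)
            inside = [c for c in centers
                      if mask[int(round(c[0])), int(round(c[1]))]]
            center = tuple(inside[0]) if inside else _estimate_soma(mask)[0]
            r_soma = (soma_radius if soma_radius is not None
                      else _estimate_soma(mask)[1])
        else:
            center, r_soma = _estimate_soma(mask)
        d = geodesic_map(mask.astype(float), center, threshold=0.5)
        cutoff = exclusion_factor * r_soma + min_protrusion
        dm = np.where(mask, d, -np.inf)
        local_max = np.ones_like(mask)
        for di, dj, _ in _SHIFTS:
            local_max &= dm >= _shift(dm, di, dj)
        cand = mask & local_max & np.isfinite(d) & (d > cutoff)
        if not cand.any():
            continue
        clab, nc = ndimage.label(cand, structure=_EIGHT)
        clusters = []          # (peak distance, centroid, point arrays)
        for c in range(1, nc + 1):
            ii, jj = np.nonzero(clab == c)
            peak = float(d[ii, jj].max())
            clusters.append((peak, (ii.mean(), jj.mean()), ii, jj))
        clusters.sort(key=lambda t: (-t[0], t[1]))
        groups = []
        if min_separation > 0:
            # merge nearby extremal clusters (a rounded arm cap splits into
            # several octile-distance maxima) into one growth cone
            for cl in clusters:
                for grp in groups:
                    if np.hypot(cl[1][0] - grp[0][1][0],
                                cl[1][1] - grp[0][1][1]) < min_separation:
                        grp.append(cl)
                        break
                else:
                    groups.append([cl])
        else:
            groups = [[cl] for cl in clusters]
        mi, mj = np.nonzero(mask)
        for grp in groups:
            ii = np.concatenate([g[2] for g in grp])
            jj = np.concatenate([g[3] for g in grp])
            ci, cj = ii.mean(), jj.mean()
            # refine to the mask point near the merged centroid farthest
            # (Euclidean) from the soma: the octile geodesic metric
            # overvalues diagonal cap points, the straight-line distance
            # restores the true apex
            near = (mi - ci) ** 2 + (mj - cj) ** 2 <= (min_separation + 1) ** 2
            if near.any():
                ni, nj = mi[near], mj[near]
                far = np.hypot(ni - center[0], nj - center[1])
                band = far >= far.max() - 1.0   # the cap rim
                bi, bj = ni[band], nj[band]
                k = int(np.argmin((bi - bi.mean()) ** 2
                                  + (bj - bj.mean()) ** 2))
                pos = (int(bi[k]), int(bj[k]))
            else:
                k = int(np.argmin((ii - ci) ** 2 + (jj - cj) ** 2))
                pos = (int(ii[k]), int(jj[k]))
            neurite_counter += 1
            tips.append(Tip(position=pos, neuron_id=nid,
                            neurite_id=neurite_counter,
                            geodesic_length=float(d[pos])))
    tips.sort(key=lambda t: (t.neuron_id, t.position))
    for k, t in enumerate(tips, start=1):
        t.neurite_id = k
    return tips


def _shift(a: np.ndarray, di: int, dj: int, fill=-np.inf) -> np.ndarray:
    out = np.full_like(a, fill)
    src_i = slice(max(-di, 0), a.shape[0] - max(di, 0))
    src_j = slice(max(-dj, 0), a.shape[1] - max(dj, 0))
    dst_i = slice(max(di, 0), a.shape[0] - max(-di, 0))
    dst_j = slice(max(dj, 0), a.shape[1] - max(-dj, 0))
    out[dst_i, dst_j] = a[src_i, src_j]
    return out


# --------------------------------------------------------------------------
# activation zones, axon selection, cues
# --------------------------------------------------------------------------

def activation_zones(tips, zone_size: int, shape) -> np.ndarray:
    """Union of zone_size x zone_size squares centered at tips, clipped."""
    mask = np.zeros(shape, dtype=bool)
    half = zone_size // 2
    for tip in tips:
        i, j = (int(tip.zone_center[0]), int(tip.zone_center[1])) \
            if hasattr(tip, "zone_center") else (int(tip[0]), int(tip[1]))
        i0, i1 = max(i - half, 0), min(i - half + zone_size, shape[0])
        j0, j1 = max(j - half, 0), min(j - half + zone_size, shape[1])
        mask[i0:i1, j0:j1] = True
    return mask


def select_axon(tips, rates: RateParams):
    """Pick the longest neurite (by geodesic length) as the axon.

    The axon tip gets the elevated assembly rate ``r_g_tip`` so that
    ``r c_tub > s`` holds and E > 0 in its zone; every other neurite gets
    assembly rate 0, so ``r c_tub < s`` and its driving force vanishes.
    Ties break to the lowest neurite id.

    Returns ``(axon_neurite_id, {neurite_id: (r, s)})``.

    Raises
    ------
    SelectionError
        If the tip set is empty.
    """
    if not tips:
        raise SelectionError("cannot select an axon from an empty tip set")
    best = max(tips, key=lambda t: (t.geodesic_length, -t.neurite_id))
    assignment = {}
    for t in tips:
        if t.neurite_id == best.neurite_id:
            assignment[t.neurite_id] = (rates.r_g_tip, rates.s_g)
        else:
            assignment[t.neurite_id] = (0.0, rates.s_g)
    return best.neurite_id, assignment


def place_extracellular_cue(tip: Tip, cue: CueParams, rng: np.random.Generator,
                            soma_center=None) -> CuePlacement:
    """Place a cue at the configured distance from the tip.

    The turning angle magnitude is drawn from ``Normal(angle_mean,
    angle_sd)`` folded to its absolute value, with a random sign (absolute
    turning angles are what the morphometric comparison uses).  The cue
    sits at ``cue.distance`` from the tip, rotated by the signed angle
    (counterclockwise positive) from the tip's heading.  A newborn tip
    without a heading defaults to heading radially outward from the soma.
    """
    magnitude = abs(rng.normal(cue.angle_mean, cue.angle_sd))
    sign = 1.0 if rng.random() < 0.5 else -1.0
    angle = sign * magnitude
    heading = tip.heading
    if heading is None or np.allclose(heading, 0):
        if soma_center is None:
            raise SelectionError(
                "tip has no heading and no soma center was given")
        v = np.asarray(tip.position, float) - np.asarray(soma_center, float)
        n = np.linalg.norm(v)
        heading = v / n if n > 0 else np.array([1.0, 0.0])
    base = math.atan2(heading[1], heading[0])
    ang = base + math.radians(angle)
    pos = (tip.position[0] + cue.distance * math.cos(ang),
           tip.position[1] + cue.distance * math.sin(ang))
    return CuePlacement(position=pos, tip_id=tip.neurite_id, angle_deg=angle)


# --------------------------------------------------------------------------
# self-intersection guard
# --------------------------------------------------------------------------

def merge_conflict_mask(phi: np.ndarray, neuron_labels: np.ndarray,
                        soma_centers=None, soma_radius: float | None = None,
                        threshold: float = 0.5, window: int = 5,
                        min_arm_size: int = 12) -> np.ndarray:
    """Points where two distinct arms of the same neuron are about to merge.

    For each neuron, the arm regions (the above-threshold mask minus the
    soma disk) are labeled; a point is flagged when its ``window x window``
    neighborhood touches two distinct arms of that neuron.  Arms of
    different neurons never flag each other.  Fragments smaller than
    ``min_arm_size`` points (interface ring slivers around the soma, not
    real arms) are ignored.
    """
    conflict = np.zeros(phi.shape, dtype=bool)
    structure = np.ones((window, window), dtype=bool)
    X, Y = np.meshgrid(np.arange(phi.shape[0]), np.arange(phi.shape[1]),
                       indexing="ij")
    for nid in sorted(int(v) for v in np.unique(neuron_labels) if v > 0):
        mask = (neuron_labels == nid) & (phi > threshold)
        if not mask.any():
            continue
        if soma_centers is not None and soma_radius is not None:
            centers = np.atleast_2d(soma_centers)
            soma = np.zeros_like(mask)
            for ci, cj in centers:
                if 0 <= int(round(ci)) < mask.shape[0] and \
                        0 <= int(round(cj)) < mask.shape[1] and \
                        mask[int(round(ci)), int(round(cj))]:
                    soma |= np.hypot(X - ci, Y - cj) <= soma_radius
        else:
            (ci, cj), r_est = _estimate_soma(mask)
            soma = np.hypot(X - ci, Y - cj) <= r_est
        arms = mask & ~soma
        armlab, n_arms = ndimage.label(arms, structure=_EIGHT)
        sizes = ndimage.sum_labels(arms, armlab, index=range(1, n_arms + 1))
        real = [a for a, s in zip(range(1, n_arms + 1), sizes)
                if s >= min_arm_size]
        if len(real) < 2:
            continue
        count = np.zeros(mask.shape, dtype=np.int16)
        for a in real:
            count += ndimage.binary_dilation(armlab == a,
                                             structure=structure)
        conflict |= count >= 2
    return conflict


def intersection_guard(phi: np.ndarray, phi_update: np.ndarray,
                       neuron_labels: np.ndarray,
                       soma_centers=None, soma_radius: float | None = None,
                       threshold: float = 0.5, window: int = 5,
                       conflict: np.ndarray | None = None) -> np.ndarray:
    """Suppress growth where two arms of the same neuron would merge.

    Positive phase-field updates are zeroed on the merge-conflict set (see
    :func:`merge_conflict_mask`); growth toward arms of *other* neurons is
    untouched (neurite interaction between different neurons is allowed).
    A precomputed conflict mask may be passed to avoid recomputation.
    """
    if conflict is None:
        conflict = merge_conflict_mask(phi, neuron_labels, soma_centers,
                                       soma_radius, threshold, window)
    out = phi_update.copy()
    out[conflict & (out > 0)] = 0.0
    return out


# --------------------------------------------------------------------------
# SWC export
# --------------------------------------------------------------------------

def export_swc(phi: np.ndarray, soma_center, path,
               threshold: float = 0.5, scale: float = 1.0):
    """Write the skeleton of ``{phi > threshold}`` as an SWC tree.

    One tree rooted at the soma center; node type 1 for the root, 3
    (dendrite) elsewhere.  Intended for downstream morphology tools.
    """
    from skimage.morphology import skeletonize
    mask = phi > threshold
    skel = skeletonize(mask)
    si, sj = _snap_to_mask(skel, soma_center)
    g, idx, pts = _lattice_graph(skel)
    from scipy.sparse.csgraph import breadth_first_order
    order, preds = breadth_first_order(g, idx[si, sj], directed=False)
    node_of = {int(p): k + 1 for k, p in enumerate(order)}
    lines = []
    for k, p in enumerate(order):
        i, j = np.unravel_index(pts[p], mask.shape)
        parent = -1 if preds[p] < 0 else node_of[int(preds[p])]
        ntype = 1 if parent == -1 else 3
        lines.append(f"{k + 1} {ntype} {i * scale:.3f} {j * scale:.3f} 0.0 "
                     f"1.0 {parent}")
    with open(path, "w") as fh:
        fh.write("# SWC export (neurongrowth)\n")
        fh.write("\n".join(lines) + "\n")
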