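"""MCI heatmap construction and sub-arc collimator angle optimization.

The SACAO core: for every control point of an arc the conformal-aperture
MCI is evaluated over a grid of collimator angles, giving a 2D heatmap
(control points x collimator angles). The arc is then partitioned into
contiguous sub-arcs — at least ``min_span`` degrees each and at most
``max_subarcs`` of them — and each sub-arc is assigned the collimator
angle maximizing its summed MCI. The segmentation maximizing the total
best-angle MCI sum is found exactly by dynamic programming over segment
boundaries; because splitting never decreases that objective, among
segmentations within a small relative tolerance of the optimum the one
with the fewest sub-arcs is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    ArcSpec,
    LinacGeometry,
    StructureVolume,
    generate_control_points,
    project_contours_to_bev,
)
from .mlc import MLCModel, mci_profile_polygon


class HeatmapError(ValueError):
    """A control point produced no usable silhouette."""


class SegmentationError(ValueError):
    """Sub-arc constraints are infeasible for the given arc."""


@dataclass
class MCIHeatmap:
    """MCI values indexed by control point (rows) and collimator angle (cols)."""

    values: np.ndarray
    gantry_angles: np.ndarray
    thetas: np.ndarray
    arc: ArcSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gantry_angles = np.asarray(self.gantry_angles, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        if self.values.shape != (len(self.gantry_angles), len(self.thetas)):
            raise ValueError("heatmap shape does not match its gantry/theta axes")
        if np.any(self.values <= 0) or np.any(self.values > 1 + 1e-9):
            raise ValueError("MCI values must lie in (0, 1]")

    @property
    def n_cp(self) -> int:
        return self.values.shape[0]

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]

    @property
    def cp_spacing(self) -> float:
        if self.arc is not None:
            return self.arc.cp_spacing
        if len(self.gantry_angles) < 2:
            raise ValueError("cannot infer cp_spacing from a single control point")
        return float(np.abs((self.gantry_angles[1] - self.gantry_angles[0] + 180) % 360 - 180))


def default_thetas(step: float = 1.0) -> np.ndarray:
    """Collimator angle grid [0, 180) — 180 values at the 1-degree default."""
    return np.arange(0.0, 180.0, step)


def build_mci_heatmap(
    structures: list[StructureVolume] | StructureVolume,
    arc: ArcSpec,
    geom: LinacGeometry = LinacGeometry(),
    mlc: MLCModel | None = None,
    thetas: np.ndarray | None = None,
    voxel: float = 1.0,
    pixel: float = 0.5,
    mode: str = "divergent",
    margin: float = 0.0,
    endpoint: str = "inclusive",
    progress: bool = False,
) -> MCIHeatmap:
    """Evaluate the conformal-aperture MCI over control points x collimator angles.

    ``structures`` (one or several target volumes) are merged and, per
    control point, their contour polygons are projected analytically onto
    the iso-plane; each silhouette is then rotated exactly into every
    collimator frame before fitting the leaf bank (no raster resampling,
    so a rotationally symmetric target yields a flat heatmap up to contour
    discretization). ``voxel``/``pixel`` are accepted for signature
    compatibility with the raster-based single-aperture path and ignored
    here.
    """
    if isinstance(structures, StructureVolume):
        structures = [structures]
    if not structures:
        raise HeatmapError("no target structures given")
    mlc = mlc or MLCModel.millennium120()
    thetas = default_thetas() if thetas is None else np.asarray(thetas, dtype=float)
    cps = generate_control_points(arc, endpoint=endpoint)

    values = np.empty((len(cps), len(thetas)))
    for i, g in enumerate(cps):
        region = project_contours_to_bev(structures, g, geom=geom, mode=mode)
        if region.is_empty or region.area <= 0:
            raise HeatmapError(f"empty silhouette at control point {g} deg")
        values[i] = mci_profile_polygon(region, mlc, thetas, margin=margin)
        if progress and i % 20 == 0:
            print(f"  CP {i + 1}/{len(cps)}", flush=True)
    return MCIHeatmap(values=values, gantry_angles=cps, thetas=thetas, arc=arc)


@dataclass(frozen=True)
class SegmentationConstraints:
    """Sub-arc segmentation constraints.

    ``min_span`` (deg) is the minimum gantry range of a sub-arc ("more than
    30 degrees" read as span >= 30); ``max_subarcs`` caps the count ("less
    than 10" read as <= 9); ``score_tolerance`` is the relative slack delta
    within which a segmentation with fewer sub-arcs is preferred.
    """

    min_span: float = 30.0
    max_subarcs: int = 9
    cp_spacing: float = 2.0
    score_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.min_span < self.cp_spacing:
            raise ValueError("min_span must be at least cp_spacing")
        if self.max_subarcs < 1:
            raise ValueError("max_subarcs must be >= 1")
        if self.score_tolerance < 0:
            raise ValueError("score_tolerance must be >= 0")

    @property
    def min_len_cp(self) -> int:
        """Minimum number of CPs per sub-arc."""
        return max(int(np.ceil(self.min_span / self.cp_spacing - 1e-9)), 1)


@dataclass(frozen=True)
class SubArc:
    gantry_start: float
    gantry_end: float
    collimator: float
    score: float
    cp_start: int
    cp_stop: int  # exclusive CP index
    span_deg: float

    @property
    def n_cp(self) -> int:
        return self.cp_stop - self.cp_start


@dataclass
class SubArcPlan:
    """An ordered, contiguous partition of one arc into collimator sub-arcs."""

    subarcs: list[SubArc]
    total_score: float
    arc: ArcSpec | None = None

    @property
    def n_subarcs(self) -> int:
        return len(self.subarcs)

    def table_string(self) -> str:
        """Render as 'start-end/theta' segments, e.g. '179-71/91, 71-293/95'."""

        def fmt(x: float) -> str:
            return str(int(round(x))) if abs(x - round(x)) < 1e-9 else f"{x:g}"

        return ", ".join(
            f"{fmt(s.gantry_start)}-{fmt(s.gantry_end)}/{fmt(s.collimator)}" for s in self.subarcs
        )


def select_collimator(h: MCIHeatmap, cp_range) -> tuple[float, float]:
    """Best single collimator angle for a CP range: argmax_theta sum of MCI.

    ``cp_range`` is anything that indexes heatmap rows (slice, index list).
    Ties break toward the lowest theta. Returns (theta, summed MCI).
    """
    rows = h.values[cp_range]
    if rows.ndim == 1:
        rows = rows[None, :]
    if rows.shape[0] == 0:
        raise ValueError("empty control-point range")
    sums = rows.sum(axis=0)
    j = int(np.argmax(sums))  # first max -> lowest theta on the ascending grid
    return float(h.thetas[j]), float(sums[j])


def _segment_scores(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(score, theta-index) of the best collimator for every CP range [i, j).

    Returned arrays are (n+1, n+1), valid for j > i.
    """
    n = values.shape[0]
    prefix = np.vstack([np.zeros(values.shape[1]), np.cumsum(values, axis=0)])
    score = np.full((n + 1, n + 1), -np.inf)
    argth = np.zeros((n + 1, n + 1), dtype=int)
    for i in range(n):
        diff = prefix[i + 1 :] - prefix[i]  # rows: j = i+1 .. n
        idx = np.argmax(diff, axis=1)
        score[i, i + 1 :] = diff[np.arange(diff.shape[0]), idx]
        argth[i, i + 1 :] = idx
    return score, argth


def _gantry_bounds(h: MCIHeatmap, i: int, j: int) -> tuple[float, float, float]:
    """(gantry_start, gantry_end, span_deg) for CPs [i, j) of the heatmap's arc."""
    start = float(h.gantry_angles[i])
    if j < h.n_cp:
        end = float(h.gantry_angles[j])
    elif h.arc is not None:
        end = float(h.arc.gantry_stop % 360.0)
    else:
        step = h.gantry_angles[-1] - h.gantry_angles[-2]
        end = float((h.gantry_angles[-1] + step) % 360.0)
    if h.arc is not None:
        sign = h.arc.sign
    else:
        sign = 1 if (h.gantry_angles[1] - h.gantry_angles[0]) % 360.0 < 180.0 else -1
    span = (end - start) * sign % 360.0
    if span == 0.0 and j > i:
        span = 360.0
    return start, end, span


def _plan_from_boundaries(
    h: MCIHeatmap, boundaries: list[int], seg_score: np.ndarray, seg_arg: np.ndarray
) -> SubArcPlan:
    subarcs = []
    total = 0.0
    for i, j in zip(boundaries[:-1], boundaries[1:]):
        start, end, span = _gantry_bounds(h, i, j)
        total = total + seg_score[i, j]
        subarcs.append(
            SubArc(
                gantry_start=start,
                gantry_end=end,
                collimator=float(h.thetas[seg_arg[i, j]]),
                score=float(seg_score[i, j]),
                cp_start=i,
                cp_stop=j,
                span_deg=span,
            )
        )
    return SubArcPlan(subarcs=subarcs, total_score=float(total), arc=h.arc)


def segment_subarcs(h: MCIHeatmap, c: SegmentationConstraints) -> SubArcPlan:
    """Optimal constrained segmentation of the heatmap into sub-arcs.

    Maximizes the summed best-collimator MCI over sub-arcs by exact dynamic
    programming over segment end points; among segmentations scoring within
    ``c.score_tolerance`` (relative) of the best achievable, the one with
    the fewest sub-arcs wins. Collimator ties within a sub-arc break toward
    the lowest theta.
    """
    n = h.n_cp
    m = c.min_len_cp
    if n < m:
        raise SegmentationError(
            f"arc has {n} CPs but the minimum sub-arc span requires {m}; infeasible"
        )
    kmax = min(c.max_subarcs, n // m)
    seg_score, seg_arg = _segment_scores(h.values)

    # f[k][j]: best score of covering CPs [0, j) with exactly k sub-arcs
    neg = -np.inf
    f = np.full((kmax + 1, n + 1), neg)
    parent = np.zeros((kmax + 1, n + 1), dtype=int)
    f[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for j in range(k * m, n + 1):
            i_lo, i_hi = (k - 1) * m, j - m
            if i_hi < i_lo:
                continue
            cand = f[k - 1, i_lo : i_hi + 1] + seg_score[i_lo : i_hi + 1, j]
            b = int(np.argmax(cand))
            if cand[b] > neg:
                f[k, j] = cand[b]
                parent[k, j] = i_lo + b

    best_by_k = {k: f[k, n] for k in range(1, kmax + 1) if np.isfinite(f[k, n])}
    if not best_by_k:
        raise SegmentationError("no feasible segmentation under the given constraints")
    best = max(best_by_k.values())
    k_star = min(k for k, s in best_by_k.items() if s >= best - c.score_tolerance * abs(best))

    boundaries = [n]
    k, j = k_star, n
    while k > 0:
        i = parent[k, j]
        boundaries.append(int(i))
        k, j = k - 1, int(i)
    boundaries.reverse()
    return _plan_from_boundaries(h, boundaries, seg_score, seg_arg)


def brute_force_segment(
    h: MCIHeatmap, c: SegmentationConstraints, guard: int = 40
) -> SubArcPlan:
    """Exhaustive-enumeration oracle for :func:`segment_subarcs`.

    Enumerates every contiguous partition satisfying the constraints with
    the same objective, k-selection rule and tie-breaks; refuses heatmaps
    with more CPs than ``guard``.
    """
    n = h.n_cp
    if n > guard:
        raise ValueError(f"brute force refused for n_cp={n} > {guard}")
    m = c.min_len_cp
    if n < m:
        raise SegmentationError("infeasible constraints: arc shorter than min sub-arc span")
    kmax = min(c.max_subarcs, n // m)
    seg_score, seg_arg = _segment_scores(h.values)

    best_by_k: dict[int, tuple[float, list[int]]] = {}

    def recurse(start: int, bounds: list[int], acc: float) -> None:
        k = len(bounds) - 1
        if start == n:
            if k >= 1 and (k not in best_by_k or acc > best_by_k[k][0]):
                best_by_k[k] = (acc, bounds.copy())
            return
        if k >= kmax:
            return
        for j in range(start + m, n + 1):
            if j < n and n - j < m:
                continue  # remainder too short to ever finish
            bounds.append(j)
            recurse(j, bounds, acc + seg_score[start, j])
            bounds.pop()

    recurse(0, [0], 0.0)
    if not best_by_k:
        raise SegmentationError("no feasible segmentation under the given constraints")
    best = max(s for s, _ in best_by_k.values())
    k_star = min(
        k for k, (s, _) in best_by_k.items() if s >= best - c.score_tolerance * abs(best)
    )
    return _plan_from_boundaries(h, best_by_k[k_star][1], seg_score, seg_arg)
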