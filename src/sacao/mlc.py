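"""Conformal MLC aperture fitting and the MLC conformity index (MCI).

The MCI for one control point is the ratio of the target-silhouette area in
the beam's eye view, A_TP, to the area of the conformal aperture fitted by
the MLC, A_MLC:

    MCI = A_TP / A_MLC,     0 < MCI <= 1.

A leaf pair is a single interval: two islands sharing the same pair force
one opening spanning the gap between them ("island blocking"), which is
what makes the MCI depend on the collimator angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import BEVMask


class ApertureError(ValueError):
    """Silhouette cannot be fitted by the leaf bank."""


def _millennium120_widths() -> tuple[float, ...]:
    # Millennium 120: 60 leaf pairs; 10 outer 10 mm, 40 central 5 mm,
    # 10 outer 10 mm (widths projected at isocenter).
    return tuple([10.0] * 10 + [5.0] * 40 + [10.0] * 10)


@dataclass(frozen=True)
class MLCModel:
    """Leaf-bank description projected at the isocenter plane.

    ``leaf_widths`` lists pair widths (mm) along the leaf-stacking axis v;
    leaves travel along u. The bank is centered on the isocenter
    projection unless ``bank_v_offset`` (v of the first leaf edge) is given.
    The width list must be symmetric about its center so that the aperture
    — and hence the MCI — is periodic under a 180-degree collimator turn.
    """

    leaf_widths: tuple[float, ...] = None  # type: ignore[assignment]
    leaf_travel_axis: str = "u"
    bank_v_offset: float | None = None
    max_leaf_span: float = 400.0

    def __post_init__(self) -> None:
        if self.leaf_widths is None:
            object.__setattr__(self, "leaf_widths", _millennium120_widths())
        widths = tuple(float(w) for w in self.leaf_widths)
        object.__setattr__(self, "leaf_widths", widths)
        if not all(w > 0 for w in widths):
            raise ValueError("leaf widths must be positive")
        if widths != widths[::-1]:
            raise ValueError("leaf width list must be symmetric about the bank center")
        if not self.max_leaf_span > 0:
            raise ValueError("max_leaf_span must be positive")

    @property
    def bank_height(self) -> float:
        return float(sum(self.leaf_widths))

    @property
    def v_edges(self) -> np.ndarray:
        """Leaf-pair edge positions (len = n_pairs + 1), mm in v."""
        start = -self.bank_height / 2.0 if self.bank_v_offset is None else self.bank_v_offset
        return start + np.concatenate([[0.0], np.cumsum(self.leaf_widths)])

    @property
    def n_pairs(self) -> int:
        return len(self.leaf_widths)

    @classmethod
    def millennium120(cls) -> "MLCModel":
        return cls()

    @classmethod
    def from_json(cls, path: str | Path) -> "MLCModel":
        """Load a machine file ``{"leaf_widths_mm": [...], "max_span_mm": ...}``."""
        with open(path) as f:
            data = json.load(f)
        return cls(
            leaf_widths=tuple(data["leaf_widths_mm"]),
            max_leaf_span=float(data.get("max_span_mm", 400.0)),
        )


@dataclass(frozen=True)
class LeafPair:
    index: int
    v_low: float
    v_high: float
    u_left: float
    u_right: float
    is_open: bool

    @property
    def width(self) -> float:
        return self.v_high - self.v_low

    @property
    def area_mm2(self) -> float:
        return (self.u_right - self.u_left) * self.width if self.is_open else 0.0


@dataclass
class Aperture:
    """A conformal MLC opening plus the tight jaw rectangle around it."""

    pairs: list[LeafPair]
    jaw_rect: tuple[float, float, float, float]  # (u_min, u_max, v_min, v_max), mm

    @property
    def open_pairs(self) -> list[LeafPair]:
        return [p for p in self.pairs if p.is_open]

    @property
    def area_mm2(self) -> float:
        return float(sum(p.area_mm2 for p in self.pairs))

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / 100.0

    def to_csv(self, path) -> None:
        """Write pair index, v-band and leaf positions of open pairs."""
        import csv

        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["pair", "v_low_mm", "v_high_mm", "u_left_mm", "u_right_mm", "open"])
            for p in self.pairs:
                w.writerow([p.index, p.v_low, p.v_high, p.u_left, p.u_right, int(p.is_open)])


@dataclass(frozen=True)
class MCIValue:
    mci: float
    a_tp: float  # cm^2
    a_mlc: float  # cm^2


def fit_conformal_aperture(bev: BEVMask, mlc: MLCModel, margin: float = 0.0) -> Aperture:
    """Fit leaves to the outermost silhouette extent within each leaf pair.

    For each pair whose v-band contains true-pixel centers, the leaf tips
    are set at the extreme pixel edges (snapped outward, never clipping the
    target) plus ``margin`` mm; pairs without target are closed. Raises
    :class:`ApertureError` for an empty mask or a silhouette exceeding the
    bank height or the maximum leaf span.
    """
    uu, vv = bev.true_uv()
    if uu.size == 0:
        raise ApertureError("cannot fit an aperture to an empty silhouette")
    edges = mlc.v_edges
    if vv.min() < edges[0] or vv.max() >= edges[-1]:
        raise ApertureError("silhouette exceeds the MLC bank height")
    band = np.searchsorted(edges, vv, side="right") - 1

    half_px = bev.pixel_spacing / 2.0
    n = mlc.n_pairs
    u_min = np.full(n, np.inf)
    u_max = np.full(n, -np.inf)
    np.minimum.at(u_min, band, uu)
    np.maximum.at(u_max, band, uu)

    pairs: list[LeafPair] = []
    for i in range(n):
        if np.isfinite(u_min[i]):
            left = u_min[i] - half_px - margin
            right = u_max[i] + half_px + margin
            if right - left > mlc.max_leaf_span:
                raise ApertureError(
                    f"pair {i}: required opening {right - left:.1f} mm exceeds "
                    f"max leaf span {mlc.max_leaf_span:.1f} mm"
                )
            pairs.append(LeafPair(i, edges[i], edges[i + 1], left, right, True))
        else:
            pairs.append(LeafPair(i, edges[i], edges[i + 1], 0.0, 0.0, False))

    open_pairs = [p for p in pairs if p.is_open]
    jaw = (
        min(p.u_left for p in open_pairs),
        max(p.u_right for p in open_pairs),
        min(p.v_low for p in open_pairs),
        max(p.v_high for p in open_pairs),
    )
    return Aperture(pairs=pairs, jaw_rect=jaw)


def compute_mci(bev: BEVMask, ap: Aperture) -> MCIValue:
    """MCI = A_TP / A_MLC for a silhouette and its fitted aperture."""
    a_tp = bev.area_cm2
    a_mlc = ap.area_cm2
    if a_mlc <= 0:
        raise ApertureError("A_MLC is zero; MCI undefined")
    mci = a_tp / a_mlc
    if not 0 < mci <= 1.0 + 1e-9:
        raise ApertureError(f"MCI {mci} outside (0, 1]; aperture does not cover the target")
    return MCIValue(mci=min(mci, 1.0), a_tp=a_tp, a_mlc=a_mlc)


def mci_vs_collimator(
    bev: BEVMask, mlc: MLCModel, thetas: np.ndarray, margin: float = 0.0
) -> np.ndarray:
    """MCI of the conformal fit at every collimator angle, for one silhouette.

    The silhouette's pixel-center coordinates are rotated exactly into each
    collimator frame (the target area A_TP is rotation-invariant), leaves
    are fitted per v-band as in :func:`fit_conformal_aperture`, and
    MCI = A_TP / A_MLC is returned per angle. Exact coordinate rotation
    avoids the raster-resampling jitter of rotating the mask itself and is
    identical to the mask path at theta = 0.
    """
    uu, vv = bev.true_uv()
    if uu.size == 0:
        raise ApertureError("cannot fit an aperture to an empty silhouette")
    thetas = np.asarray(thetas, dtype=float)
    rad = np.deg2rad(thetas)
    # frame rotated by theta: phi -> phi - theta
    ur = np.cos(rad)[:, None] * uu + np.sin(rad)[:, None] * vv
    vr = -np.sin(rad)[:, None] * uu + np.cos(rad)[:, None] * vv

    edges = mlc.v_edges
    if vr.min() < edges[0] or vr.max() >= edges[-1]:
        raise ApertureError("silhouette exceeds the MLC bank height")
    band = np.searchsorted(edges, vr.ravel(), side="right") - 1
    n_pairs = mlc.n_pairs
    key = np.repeat(np.arange(len(thetas)), uu.size) * n_pairs + band

    u_min = np.full(len(thetas) * n_pairs, np.inf)
    u_max = np.full(len(thetas) * n_pairs, -np.inf)
    np.minimum.at(u_min, key, ur.ravel())
    np.maximum.at(u_max, key, ur.ravel())
    u_min = u_min.reshape(len(thetas), n_pairs)
    u_max = u_max.reshape(len(thetas), n_pairs)

    open_ = np.isfinite(u_min)
    chords = np.where(open_, u_max - u_min + bev.pixel_spacing + 2.0 * margin, 0.0)
    if np.any(chords > mlc.max_leaf_span):
        raise ApertureError("required opening exceeds the maximum leaf span")
    widths = np.asarray(mlc.leaf_widths)
    a_mlc = (chords * widths).sum(axis=1)
    a_tp = bev.area_mm2
    return np.minimum(a_tp / a_mlc, 1.0)


def _region_rings(region) -> list[np.ndarray]:
    """Boundary rings (exterior and holes) of a shapely (Multi)Polygon."""
    geoms = getattr(region, "geoms", [region])
    rings = []
    for g in geoms:
        rings.append(np.asarray(g.exterior.coords)[:-1])
        for hole in g.interiors:
            rings.append(np.asarray(hole.coords)[:-1])
    return rings


def mci_profile_polygon(
    region, mlc: MLCModel, thetas: np.ndarray, margin: float = 0.0
) -> np.ndarray:
    """MCI versus collimator angle for an analytic silhouette polygon.

    ``region`` is a shapely (Multi)Polygon in BEV (u, v) mm (see
    :func:`sacao.geometry.project_contours_to_bev`). For each angle the
    boundary is rotated exactly and every leaf pair opens to the extreme u
    extent of the region inside its v-band — evaluated from boundary
    vertices plus the boundary's crossings of the band edges, so chords
    are exact for the polygonal silhouette. A_TP is the (rotation
    invariant) polygon area.
    """
    if region.is_empty or region.area <= 0:
        raise ApertureError("cannot fit an aperture to an empty silhouette")
    a_tp = float(region.area)
    rings = _region_rings(region)
    V = np.vstack(rings)
    starts = np.cumsum([0] + [len(r) for r in rings])
    ei = np.arange(len(V))
    ej = ei + 1
    for k in range(len(rings)):  # close each ring
        ej[starts[k + 1] - 1] = starts[k]

    edges = mlc.v_edges
    widths = np.asarray(mlc.leaf_widths)
    n_pairs = mlc.n_pairs
    thetas = np.asarray(thetas, dtype=float)
    out = np.empty(len(thetas))
    for t, a in enumerate(np.deg2rad(thetas)):
        c, s = np.cos(a), np.sin(a)
        u = c * V[:, 0] + s * V[:, 1]  # frame rotated by theta: phi -> phi - theta
        v = -s * V[:, 0] + c * V[:, 1]
        if v.min() < edges[0] or v.max() >= edges[-1]:
            raise ApertureError("silhouette exceeds the MLC bank height")
        band = np.searchsorted(edges, v, side="right") - 1
        u_min = np.full(n_pairs, np.inf)
        u_max = np.full(n_pairs, -np.inf)
        np.minimum.at(u_min, band, u)
        np.maximum.at(u_max, band, u)
        v1, v2 = v[ei], v[ej]
        lo, hi = np.minimum(v1, v2), np.maximum(v1, v2)
        for k in range(int(band.min()) + 1, int(band.max()) + 1):
            e = edges[k]
            sel = (lo < e) & (hi >= e)
            if not sel.any():
                continue
            frac = (e - v1[sel]) / (v2[sel] - v1[sel])
            uc = u[ei[sel]] * (1.0 - frac) + u[ej[sel]] * frac
            for b in (k - 1, k):
                u_min[b] = min(u_min[b], uc.min())
                u_max[b] = max(u_max[b], uc.max())
        open_ = np.isfinite(u_min)
        chords = np.where(open_, u_max - u_min + 2.0 * margin, 0.0)
        if np.any(chords > mlc.max_leaf_span):
            raise ApertureError("required opening exceeds the maximum leaf span")
        out[t] = min(a_tp / float((chords * widths).sum()), 1.0)
    return out


def aperture_field_size(ap: Aperture) -> float:
    """Area (cm^2) of the tight jaw rectangle around the open aperture."""
    if not ap.open_pairs:
        raise ApertureError("field size undefined for an all-closed aperture")
    u_min, u_max, v_min, v_max = ap.jaw_rect
    return (u_max - u_min) * (v_max - v_min) / 100.0
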