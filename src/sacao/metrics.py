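"""Dose-volume plan-quality indices and cohort summary statistics.

Given a 3D dose grid (Gy) and target/body structures this module computes
DVH samples and the standard SRS plan indices:

* conformity index  CI = V_ref / V_T        (RTOG-style simple ratio),
* homogeneity index HI = (D2% - D98%) / Dp,
* gradient index    GI = V_50% / V_100%,

where V_ref is the tissue volume at or above the prescription dose Dp,
V_T the target volume, D_x% the dose received by at least x% of the
target, and V_x% the absolute tissue volume at or above x% of Dp. The
per-plan weighted field size is FS = sum_i (phi_i / Phi) * fs_i over
sub-arcs with gantry ranges phi_i (Phi = 358 degrees for one full arc).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geometry import StructureVolume, _slice_parity_fill


class DoseVolumeError(ValueError):
    """Region/dose mismatch or an undefined index."""


@dataclass
class DoseGrid:
    """3D dose array (Gy) with grid metadata.

    ``dose`` is indexed ``[z, y, x]``; ``origin`` is the world (x, y, z) of
    the center of voxel ``[0, 0, 0]``; ``spacing`` is (dx, dy, dz) in mm.
    """

    dose: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be a 3D array")
        if not np.isfinite(self.dose).all() or (self.dose < 0).any():
            raise ValueError("dose must be finite and non-negative")

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center world coordinates along x (0), y (1) or z (2)."""
        n = self.dose.shape[2 - axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


def region_mask(dose: DoseGrid, region: StructureVolume) -> np.ndarray:
    """Boolean mask of dose voxels whose centers fall inside the region.

    Each dose slice collects the region contours nearest in z (within half
    the larger of the dose and contour slice spacings) and fills them by
    the even-odd rule.
    """
    xs, ys, zs = (dose.axis_coords(a) for a in range(3))
    cz = region.z_values
    contour_dz = float(np.median(np.diff(np.unique(cz)))) if len(np.unique(cz)) > 1 else dose.spacing[2]
    tol = max(dose.spacing[2], contour_dz) / 2.0 + 1e-9

    polys_by_z: dict[float, list[Polygon]] = {}
    for z, pts in region.contours:
        poly = Polygon(pts)
        if poly.area <= 0:
            continue
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys_by_z.setdefault(z, []).append(poly)
    if not polys_by_z:
        raise DoseVolumeError(f"region {region.name!r} has no usable contours")
    zkeys = np.array(sorted(polys_by_z))

    mask = np.zeros(dose.dose.shape, dtype=bool)
    for k, z in enumerate(zs):
        j = int(np.argmin(np.abs(zkeys - z)))
        if abs(zkeys[j] - z) <= tol:
            mask[k] = _slice_parity_fill(polys_by_z[zkeys[j]], xs, ys)
    return mask


@dataclass
class DVH:
    """Dose samples of a region at voxel centers, with cumulative queries."""

    doses: np.ndarray  # sorted descending, Gy
    voxel_volume_cc: float

    @property
    def volume_cc(self) -> float:
        return self.doses.size * self.voxel_volume_cc

    @property
    def d_min(self) -> float:
        return float(self.doses[-1])

    @property
    def d_max(self) -> float:
        return float(self.doses[0])

    @property
    def d_mean(self) -> float:
        return float(self.doses.mean())

    def d_at_percent(self, x: float) -> float:
        """D_x%: dose received by at least x% of the region (linear interp)."""
        if not 0 <= x <= 100:
            raise DoseVolumeError("percentage must be in [0, 100]")
        return float(np.percentile(self.doses, 100.0 - x, method="linear"))

    def v_at_dose(self, t: float) -> float:
        """Absolute volume (cc) with dose >= t Gy."""
        return float((self.doses >= t).sum()) * self.voxel_volume_cc

    def cumulative(self, bins: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(dose bins, volume cc at or above each bin)."""
        if bins is None:
            bins = np.linspace(0.0, self.d_max, 201)
        vols = np.array([self.v_at_dose(t) for t in bins])
        return bins, vols


def dvh(dose: DoseGrid, region: StructureVolume) -> DVH:
    """Sample the dose at voxel centers inside a region."""
    mask = region_mask(dose, region)
    if not mask.any():
        raise DoseVolumeError(f"region {region.name!r} does not overlap the dose grid")
    samples = np.sort(dose.dose[mask])[::-1]
    return DVH(doses=samples, voxel_volume_cc=dose.voxel_volume_cc)


@dataclass
class PlanIndices:
    ci: float
    hi: float
    gi: float
    coverage: float  # % of PTV at or above Dp
    d_min: float
    d_max: float
    d_mean: float
    d2: float
    d50: float
    d98: float
    v100: float  # cc at >= Dp
    v50: float  # cc at >= Dp/2
    prescription_dose: float
    fs: float | None = None  # weighted field size, cm^2

    def as_dict(self) -> dict:
        return {
            "CI": self.ci,
            "HI": self.hi,
            "GI": self.gi,
            "Coverage (%)": self.coverage,
            "Dmin (Gy)": self.d_min,
            "Dmax (Gy)": self.d_max,
            "Dmean (Gy)": self.d_mean,
            "D2% (Gy)": self.d2,
            "D50% (Gy)": self.d50,
            "D98% (Gy)": self.d98,
            "V100% (cc)": self.v100,
            "V50% (cc)": self.v50,
            "Prescription dose (Gy)": self.prescription_dose,
            "FS (cm2)": self.fs,
        }


def compute_indices(
    dose: DoseGrid,
    ptv: StructureVolume,
    body: StructureVolume | None = None,
    Dp: float = 30.0,
    fs: float | None = None,
) -> PlanIndices:
    """CI, HI, GI, coverage and DVH point metrics for one plan.

    V_ref and V_x% are counted within the body contour when given, else
    over the whole dose grid.
    """
    if not Dp > 0:
        raise DoseVolumeError("prescription dose must be positive")
    target = dvh(dose, ptv)
    if body is not None:
        tissue = dose.dose[region_mask(dose, body)]
    else:
        tissue = dose.dose.ravel()
    vox = dose.voxel_volume_cc
    v100 = float((tissue >= Dp).sum()) * vox
    v50 = float((tissue >= Dp / 2.0).sum()) * vox
    if v100 <= 0:
        raise DoseVolumeError("no tissue reaches the prescription dose; GI/CI undefined")
    d2, d98 = target.d_at_percent(2), target.d_at_percent(98)
    return PlanIndices(
        ci=v100 / target.volume_cc,
        hi=(d2 - d98) / Dp,
        gi=v50 / v100,
        coverage=100.0 * target.v_at_dose(Dp) / target.volume_cc,
        d_min=target.d_min,
        d_max=target.d_max,
        d_mean=target.d_mean,
        d2=d2,
        d50=target.d_at_percent(50),
        d98=d98,
        v100=v100,
        v50=v50,
        prescription_dose=Dp,
        fs=fs,
    )


def weighted_field_size(
    subarcs: list[tuple[float, float]], total_span: float = 358.0, tol: float = 2.0
) -> float:
    """Span-weighted mean field size: FS = sum_i (phi_i / Phi) * fs_i.

    ``subarcs`` is a list of (span_deg, field_size_cm2). The spans must sum
    to ``total_span`` within ``tol`` degrees (one CP spacing of slack).
    """
    if not subarcs:
        raise DoseVolumeError("no sub-arcs given")
    spans = np.array([s for s, _ in subarcs], dtype=float)
    sizes = np.array([f for _, f in subarcs], dtype=float)
    if abs(spans.sum() - total_span) > tol:
        raise DoseVolumeError(
            f"sub-arc spans sum to {spans.sum()} deg, expected {total_span} +/- {tol}"
        )
    return float(np.sum(spans / total_span * sizes))


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Median and range of total target volume and per-axis R_max.

    Expects columns ``total_volume`` (cc) and ``r_max_x/y/z`` (cm); the
    median of an even-sized cohort is the midpoint of the two middle
    values, and reported numbers are rounded half-away-from-zero to
    ``decimals`` places.
    """
    if len(table) == 0:
        raise ValueError("empty cohort table")
    cols = [c for c in ("total_volume", "r_max_x", "r_max_y", "r_max_z") if c in table]
    if not cols:
        raise ValueError("cohort table lacks summary columns")
    rows = {}
    for c in cols:
        vals = np.asarray(table[c], dtype=float)
        rows[c] = {
            "median": _round_half_up(float(np.median(vals)), decimals),
            "min": _round_half_up(float(vals.min()), decimals),
            "max": _round_half_up(float(vals.max()), decimals),
        }
    return pd.DataFrame(rows).T[["median", "min", "max"]]
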