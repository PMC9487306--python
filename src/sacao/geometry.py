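"""Beam's-eye-view (BEV) geometry for coplanar VMAT arcs.

This module turns 3D target structures (z-sorted planar contour stacks in
patient coordinates) into per-control-point 2D silhouettes on the isocenter
plane, expressed in the collimator frame where MLC leaf fitting is
axis-aligned.

Conventions
-----------
* Patient coordinates are DICOM LPS, millimetres: +x patient left,
  +y posterior, +z superior (head-first supine).
* Gantry angles follow IEC 61217. At gantry 0 the source is anterior to the
  patient; the source direction from the isocenter is
  ``s(g) = (sin g, -cos g, 0)`` so the gantry rotates about the patient
  superior-inferior axis (coplanar arcs only).
* The BEV plane passes through the isocenter, perpendicular to the beam
  axis. Its ``u`` axis is the MLC leaf-travel direction at collimator 0,
  ``u(g) = (cos g, sin g, 0)``; the ``v`` axis is the leaf-stacking
  direction, ``v = (0, 0, 1)`` (patient superior). ``(u, v, s)`` is
  right-handed, i.e. the view from the source with ``u`` rightward and
  ``v`` upward.
* Rasters are indexed ``[row = v, col = u]`` with pixel centers at
  half-integer multiples of the pixel spacing; the isocenter projects to
  the array center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon


class ConfigurationError(ValueError):
    """Invalid arc/machine configuration (e.g. non-divisible CP spacing)."""


class GeometryError(ValueError):
    """Geometrically impossible request (e.g. voxel at or behind the source)."""


@dataclass(frozen=True)
class LinacGeometry:
    """C-arm linac geometry.

    Parameters
    ----------
    sad:
        Source-axis distance in mm (distance from the radiation source to
        the gantry rotation axis). 1000 mm for conventional C-arm machines.
    isocenter:
        Isocenter position in patient coordinates (mm). Single-isocenter
        plans place it at the geometric center of the combined PTV.
    """

    sad: float = 1000.0
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gantry_convention: str = "IEC61217"

    def __post_init__(self) -> None:
        if not self.sad > 0:
            raise ConfigurationError(f"SAD must be positive, got {self.sad}")


@dataclass(frozen=True)
class ArcSpec:
    """One coplanar gantry arc.

    ``direction`` is "CW" (gantry angle increasing mod 360) or "CCW"
    (decreasing). A full arc from 179 to 181 going CCW through 0 spans
    358 degrees, the conventional dual-arc geometry for single-isocenter
    cranial VMAT.
    """

    gantry_start: float
    gantry_stop: float
    direction: str = "CCW"
    cp_spacing: float = 2.0

    def __post_init__(self) -> None:
        if self.direction not in ("CW", "CCW"):
            raise ConfigurationError(f"direction must be CW or CCW, got {self.direction!r}")
        if not self.cp_spacing > 0:
            raise ConfigurationError("cp_spacing must be positive")
        if self.total_span <= 0:
            raise ConfigurationError("arc span must be positive")

    @property
    def sign(self) -> int:
        """+1 for CW (increasing gantry angle), -1 for CCW."""
        return 1 if self.direction == "CW" else -1

    @property
    def total_span(self) -> float:
        """Arc length in degrees, measured in the arc direction."""
        span = (self.gantry_stop - self.gantry_start) * self.sign % 360.0
        return span

    @property
    def n_intervals(self) -> int:
        """Number of cp_spacing steps in the arc span."""
        n = self.total_span / self.cp_spacing
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"cp_spacing {self.cp_spacing} does not divide arc span {self.total_span}"
            )
        return int(round(n))

    @property
    def n_cp(self) -> int:
        """Control point count with both endpoints kept (span/spacing + 1).

        The 358-degree full arc at 2 deg/CP has 180 control points
        (179, 177, ..., 1, 359, ..., 181), giving a heatmap with 180 rows.
        """
        return self.n_intervals + 1


def generate_control_points(arc: ArcSpec, endpoint: str = "inclusive") -> np.ndarray:
    """Enumerate the gantry angles of an arc's control points.

    With ``endpoint="inclusive"`` (the default) both the start and stop
    angles are control points: the 179->181 full arc at 2 deg/CP yields 180
    angles ending at 181. ``"exclusive"`` omits the stop angle (useful for
    a true 360-degree arc, where it would duplicate the start).
    """
    n = arc.n_intervals  # raises ConfigurationError on non-divisible spacing
    if endpoint not in ("exclusive", "inclusive"):
        raise ConfigurationError(f"endpoint must be exclusive|inclusive, got {endpoint!r}")
    count = n if endpoint == "exclusive" else n + 1
    angles = (arc.gantry_start + arc.sign * arc.cp_spacing * np.arange(count)) % 360.0
    return angles


@dataclass
class StructureVolume:
    """A named 3D region as a stack of planar contour polygons.

    ``contours`` is a list of ``(z_mm, polygon)`` pairs where ``polygon`` is
    an ``(N, 2)`` array of (x, y) vertices in patient coordinates. Multiple
    polygons may share a z (even-odd rule: a polygon inside another makes a
    hole, disjoint polygons are separate islands).
    """

    name: str
    contours: list[tuple[float, np.ndarray]]
    frame: str = "LPS"

    def __post_init__(self) -> None:
        cleaned = []
        for z, pts in self.contours:
            pts = np.asarray(pts, dtype=float)
            if not np.isfinite(z) or not np.isfinite(pts).all():
                raise ValueError(f"structure {self.name!r}: non-finite contour data")
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise ValueError(f"structure {self.name!r}: polygon needs >= 3 (x, y) points")
            cleaned.append((float(z), pts))
        cleaned.sort(key=lambda c: c[0])
        self.contours = cleaned

    @property
    def z_values(self) -> np.ndarray:
        return np.array([z for z, _ in self.contours])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners (x, y, z) over all contour vertices, mm."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for z, pts in self.contours:
            lo[:2] = np.minimum(lo[:2], pts.min(axis=0))
            hi[:2] = np.maximum(hi[:2], pts.max(axis=0))
            lo[2] = min(lo[2], z)
            hi[2] = max(hi[2], z)
        return lo, hi


def merge_structures(structures: list[StructureVolume], name: str = "union") -> StructureVolume:
    """Concatenate contour stacks of disjoint structures into one region."""
    contours: list[tuple[float, np.ndarray]] = []
    for s in structures:
        contours.extend(s.contours)
    return StructureVolume(name=name, contours=contours)


@dataclass
class VolumeMask:
    """Boolean 3D raster with grid metadata.

    ``mask`` is indexed ``[z, y, x]``; ``origin`` is the world position of
    the center of voxel ``[0, 0, 0]`` as (x, y, z); ``spacing`` is
    (dx, dy, dz) in mm.
    """

    mask: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume_cc(self) -> float:
        return self.mask.sum() * self.voxel_volume_mm3 / 1000.0

    def voxel_centers_world(self) -> np.ndarray:
        """World (x, y, z) coordinates of all true voxels, (N, 3) mm."""
        iz, iy, ix = np.nonzero(self.mask)
        return self.origin + np.column_stack([ix, iy, iz]) * self.spacing


def _slice_parity_fill(polys: list[Polygon], xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd fill of a list of polygons sampled at a point grid.

    Returns a boolean array ``[len(ys), len(xs)]`` where a point is inside
    iff it is contained in an odd number of polygons.
    """
    gx, gy = np.meshgrid(xs, ys)
    inside = np.zeros(gx.shape, dtype=bool)
    for poly in polys:
        inside ^= shapely.contains_xy(poly, gx, gy)
    return inside


def rasterize_structure(s: StructureVolume, voxel: float = 1.0) -> VolumeMask:
    """Rasterize a contour stack to a 3D boolean mask on a uniform grid.

    Each contour is assigned to the nearest grid slice; slices carrying
    several polygons are filled with the even-odd rule. Zero-area polygons
    are skipped with a warning.
    """
    if not voxel > 0:
        raise ValueError("voxel size must be positive")
    slices: list[tuple[float, Polygon]] = []
    for z, pts in s.contours:
        poly = Polygon(pts)
        if poly.area <= 0:
            warnings.warn(f"structure {s.name!r}: skipping degenerate polygon at z={z}")
            continue
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.is_empty:
                warnings.warn(f"structure {s.name!r}: skipping invalid polygon at z={z}")
                continue
        slices.append((z, poly))
    if not slices:
        raise ValueError(f"structure {s.name!r} has no non-degenerate contours")

    lo, hi = s.bounding_box()
    # x/y pixel centers at origin + i*voxel with one voxel pad; the z grid is
    # anchored on the lowest contour plane so slices land on voxel centers
    origin = np.array([lo[0] - voxel / 2.0, lo[1] - voxel / 2.0, lo[2]])
    n = np.empty(3, dtype=int)
    n[:2] = np.ceil((hi[:2] - origin[:2]) / voxel).astype(int) + 1
    n[2] = int(np.floor((hi[2] - origin[2]) / voxel + 0.5)) + 1
    xs = origin[0] + np.arange(n[0]) * voxel
    ys = origin[1] + np.arange(n[1]) * voxel

    # polygons sharing one contour plane obey the even-odd rule (holes);
    # distinct planes falling into the same voxel slice are unioned. Each
    # contour fills every grid slice within half the contour spacing, so a
    # grid finer than the contour stack has no empty gap slices.
    dz_c = _contour_slab_thickness(np.array([z for z, _ in slices]))
    by_slice: dict[int, dict[float, list[Polygon]]] = {}
    for z, poly in slices:
        k_lo = int(np.ceil((z - dz_c / 2.0 - origin[2]) / voxel - 1e-9))
        k_hi = int(np.ceil((z + dz_c / 2.0 - origin[2]) / voxel - 1e-9)) - 1
        if k_hi < k_lo:  # grid coarser than the slab: nearest slice only
            k_lo = k_hi = int(np.floor((z - origin[2]) / voxel + 0.5))
        for k in range(max(k_lo, 0), min(k_hi, n[2] - 1) + 1):
            by_slice.setdefault(k, {}).setdefault(z, []).append(poly)

    mask = np.zeros((n[2], n[1], n[0]), dtype=bool)
    for k, groups in by_slice.items():
        for polys in groups.values():
            mask[k] |= _slice_parity_fill(polys, xs, ys)
    return VolumeMask(mask=mask, origin=origin, spacing=np.full(3, float(voxel)))


@dataclass
class BEVMask:
    """Binary silhouette raster on the isocenter plane for one control point.

    ``pixels[i, j]`` covers the point ``u = (j + 0.5 - n_u/2) * pixel_spacing``,
    ``v = (i + 0.5 - n_v/2) * pixel_spacing`` (mm); the isocenter projects to
    the raster center.
    """

    pixels: np.ndarray
    pixel_spacing: float = 0.5
    gantry: float | None = None
    axes: str = "u=leaf travel at collimator 0, v=leaf stacking"
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing**2

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_area_mm2

    @property
    def area_cm2(self) -> float:
        return self.area_mm2 / 100.0

    def u_centers(self) -> np.ndarray:
        n_u = self.pixels.shape[1]
        return (np.arange(n_u) + 0.5 - n_u / 2.0) * self.pixel_spacing

    def v_centers(self) -> np.ndarray:
        n_v = self.pixels.shape[0]
        return (np.arange(n_v) + 0.5 - n_v / 2.0) * self.pixel_spacing

    def true_uv(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) coordinates (mm) of true pixel centers."""
        rows, cols = np.nonzero(self.pixels)
        return self.u_centers()[cols], self.v_centers()[rows]

    def centroid_uv(self) -> tuple[float, float]:
        u, v = self.true_uv()
        if u.size == 0:
            raise ValueError("empty BEV mask has no centroid")
        return float(u.mean()), float(v.mean())


def beam_basis(gantry: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, v, s) unit vectors for a gantry angle: BEV axes and source direction."""
    g = np.deg2rad(gantry)
    u = np.array([np.cos(g), np.sin(g), 0.0])
    v = np.array([0.0, 0.0, 1.0])
    s = np.array([np.sin(g), -np.cos(g), 0.0])
    return u, v, s


_CLOSE_STRUCT = np.ones((3, 3), dtype=bool)  # 1-pixel-radius closing element


def project_to_bev(
    vol: VolumeMask,
    gantry: float,
    geom: LinacGeometry = LinacGeometry(),
    pixel: float = 0.5,
    mode: str = "divergent",
    pad_mm: float = 3.0,
    min_half_extent: float | None = None,
) -> BEVMask:
    """Project a 3D mask onto the isocenter plane for one gantry angle.

    In ``divergent`` mode a voxel at signed distance ``d`` from the
    isocenter plane toward the source is magnified by ``SAD / (SAD - d)``
    (point-source geometry); ``parallel`` mode uses unit magnification.
    The projected point cloud is rasterized and morphologically closed
    (1-pixel radius) to remove sampling holes.

    ``min_half_extent`` forces the raster to cover at least that radius
    (mm), useful to keep rasters comparable across control points.
    """
    if mode not in ("divergent", "parallel"):
        raise ConfigurationError(f"mode must be divergent|parallel, got {mode!r}")
    pts = vol.voxel_centers_world()
    if pts.shape[0] == 0:
        raise GeometryError("cannot project an empty volume")
    pts = pts - np.asarray(geom.isocenter, dtype=float)
    u_ax, v_ax, s_ax = beam_basis(gantry)
    d = pts @ s_ax
    if mode == "divergent":
        if d.max() >= geom.sad:
            raise GeometryError("structure voxel at or behind the radiation source")
        scale = geom.sad / (geom.sad - d)
    else:
        scale = 1.0
    up = scale * (pts @ u_ax)
    vp = scale * (pts @ v_ax)

    r = float(np.sqrt(up**2 + vp**2).max()) + pad_mm
    if min_half_extent is not None:
        r = max(r, float(min_half_extent))
    half_n = max(int(np.ceil(r / pixel)), 8)
    n = 2 * half_n

    def _bin(x: np.ndarray) -> np.ndarray:
        # mirror-symmetric binning about the isocenter: a point and its
        # reflection always land in mirrored pixels, even exactly on a
        # pixel boundary (opposed parallel beams then match identically)
        k = np.floor(np.abs(x) / pixel).astype(int)
        return np.where(x >= 0, half_n + k, half_n - 1 - k)

    cols = _bin(up)
    rows = _bin(vp)
    grid = np.zeros((n, n), dtype=bool)
    grid[rows, cols] = True
    grid = ndimage.binary_closing(grid, structure=_CLOSE_STRUCT)
    return BEVMask(pixels=grid, pixel_spacing=float(pixel), gantry=float(gantry % 360.0))


def _contour_slab_thickness(z_values: np.ndarray) -> float:
    zu = np.unique(z_values)
    if len(zu) < 2:
        return 1.0
    return float(np.median(np.diff(zu)))


def project_contours_to_bev(
    structures: "list[StructureVolume] | StructureVolume",
    gantry: float,
    geom: LinacGeometry = LinacGeometry(),
    mode: str = "divergent",
):
    """Analytic BEV silhouette of contour stacks for a coplanar beam.

    For a beam axis perpendicular to the slice normal, each contour's
    silhouette contribution at its own plane is the u-shadow interval of
    the polygon: its endpoints are exact because the divergent map
    u' = SAD*u/(SAD - d) is fractional-linear, so its extremes over a
    polygon occur at vertices; the magnification of the realizing vertex
    is applied to its v-coordinate. Between slices the shadow is linearly
    interpolated (the standard contour-to-surface reconstruction — the
    chain vertices lie on the true surface, so the silhouette is free of
    slab-staircase corners), and half-slab apex caps close the stack at
    either end. Structures with several islands on one slice fall back to
    per-polygon slab boxes. Returns a shapely (Multi)Polygon in BEV (u, v)
    mm, the silhouette source for heatmap construction.
    """
    from shapely.geometry import box as shapely_box
    from shapely.ops import unary_union

    if mode not in ("divergent", "parallel"):
        raise ConfigurationError(f"mode must be divergent|parallel, got {mode!r}")
    if isinstance(structures, StructureVolume):
        structures = [structures]
    iso = np.asarray(geom.isocenter, dtype=float)
    u_ax, v_ax, s_ax = beam_basis(gantry)
    pieces = []
    for s in structures:
        dz = _contour_slab_thickness(s.z_values)
        # per-slice shadow interval endpoints, with the magnification of the
        # 3D vertex realizing each endpoint applied to its v-coordinate
        slices: dict[float, list[tuple[float, float, float, float]]] = {}
        for z, pts in s.contours:
            if Polygon(pts).area <= 0:
                continue
            p3 = np.column_stack([pts, np.full(len(pts), z)]) - iso
            d = p3 @ s_ax
            if mode == "divergent":
                if d.max() >= geom.sad:
                    raise GeometryError("structure voxel at or behind the radiation source")
                scale = geom.sad / (geom.sad - d)
            else:
                scale = np.ones(len(p3))
            up = scale * (p3 @ u_ax)
            vp = scale * p3[:, 2]
            i0, i1 = int(np.argmin(up)), int(np.argmax(up))
            slices.setdefault(z, []).append(
                (float(up[i0]), float(vp[i0]), float(up[i1]), float(vp[i1]))
            )
        if not slices:
            continue
        zs = sorted(slices)
        if all(len(slices[z]) == 1 for z in zs):
            # single polygon per slice: linear interpolation between slice
            # shadows (vertices on the true surface), closed by half-slab
            # apex caps at either end
            left = [(slices[z][0][0], slices[z][0][1]) for z in zs]
            right = [(slices[z][0][2], slices[z][0][3]) for z in zs]
            mag_bot = left[0][1] / (zs[0] - iso[2]) if zs[0] != iso[2] else 1.0
            mag_top = left[-1][1] / (zs[-1] - iso[2]) if zs[-1] != iso[2] else 1.0
            bot = (
                0.5 * (left[0][0] + right[0][0]),
                (zs[0] - dz / 2.0 - iso[2]) * abs(mag_bot),
            )
            top = (
                0.5 * (left[-1][0] + right[-1][0]),
                (zs[-1] + dz / 2.0 - iso[2]) * abs(mag_top),
            )
            ring = [bot] + left + [top] + right[::-1]
            poly = Polygon(ring)
            if not poly.is_valid:
                poly = poly.buffer(0)
            pieces.append(poly)
        else:
            # several islands per slice: fall back to per-polygon slab boxes
            for z in zs:
                for u0, v0, u1, v1 in slices[z]:
                    mag = max(abs(v0 / (z - iso[2])), abs(v1 / (z - iso[2]))) if z != iso[2] else 1.0
                    pieces.append(
                        shapely_box(u0, (z - dz / 2.0 - iso[2]) * mag, u1, (z + dz / 2.0 - iso[2]) * mag)
                    )
    if not pieces:
        raise GeometryError("structure has no projectable contours")
    return unary_union(pieces)


def rotate_to_collimator_frame(bev: BEVMask, theta: float) -> BEVMask:
    """Express a BEV silhouette in the frame of a collimator rotated by theta.

    The raster is rotated by -theta about the isocenter projection so that
    leaf fitting always happens along fixed (u, v) axes: a silhouette
    feature at polar angle phi (measured from +u toward +v) appears at
    phi - theta in the collimator frame. Bilinear interpolation thresholded
    at 0.5; theta must lie in [0, 180).
    """
    if not (0.0 <= theta < 180.0):
        raise ValueError(f"collimator angle must be in [0, 180), got {theta}")
    if theta == 0.0:
        return BEVMask(
            pixels=bev.pixels.copy(), pixel_spacing=bev.pixel_spacing, gantry=bev.gantry
        )
    # ndimage.rotate with a positive angle moves content from +u toward -v in
    # this raster layout, i.e. phi -> phi - theta: the collimator-frame view.
    rot = ndimage.rotate(
        bev.pixels.astype(np.float32), angle=theta, reshape=False, order=1, prefilter=False
    )
    return BEVMask(pixels=rot >= 0.5, pixel_spacing=bev.pixel_spacing, gantry=bev.gantry)
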