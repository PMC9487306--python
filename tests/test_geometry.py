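"""BEV geometry: control points, rasterization, projection, rotation."""

import numpy as np
import pytest

from sacao import (
    ArcSpec,
    ConfigurationError,
    GeometryError,
    LinacGeometry,
    StructureVolume,
    VolumeMask,
    generate_control_points,
    project_contours_to_bev,
    project_to_bev,
    rasterize_structure,
    rotate_to_collimator_frame,
    sphere_structure,
)

SAD = 1000.0


def single_voxel_volume():
    m = np.zeros((3, 3, 3), dtype=bool)
    m[1, 1, 1] = True
    return VolumeMask(mask=m, origin=np.array([-1.0, -1.0, -1.0]), spacing=np.ones(3))


class TestControlPoints:
    def test_full_arc_has_180_cps_through_zero(self):
        cps = generate_control_points(ArcSpec(179, 181, "CCW", 2.0))
        assert len(cps) == 180
        assert cps[0] == 179 and cps[-1] == 181
        assert cps[89] == 1 and cps[90] == 359  # passes through 0
        steps = (np.diff(cps) + 180) % 360 - 180
        assert np.all(steps == -2)

    def test_quarter_arc_inclusive(self):
        assert generate_control_points(ArcSpec(0, 90, "CW", 30.0)).tolist() == [0, 30, 60, 90]

    def test_non_divisible_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_control_points(ArcSpec(179, 181, "CCW", 7.0))

    def test_exclusive_endpoint_drops_stop(self):
        cps = generate_control_points(ArcSpec(0, 90, "CW", 30.0), endpoint="exclusive")
        assert cps.tolist() == [0, 30, 60]

    def test_bad_direction_rejected(self):
        with pytest.raises(ConfigurationError):
            ArcSpec(0, 90, "clockwise", 30.0)


class TestRasterize:
    @pytest.mark.parametrize("r,center", [(10.0, (0, 0, 0)), (10.0, (5, -3, 7))])
    def test_sphere_volume_within_2pct(self, r, center):
        vol = rasterize_structure(sphere_structure("s", center, r), voxel=1.0)
        analytic = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        assert vol.volume_cc == pytest.approx(analytic, rel=0.02)

    def test_disjoint_spheres_additive(self):
        a = sphere_structure("a", (-30, 0, 0), 10.0)
        b = sphere_structure("b", (30, 0, 0), 10.0)
        both = StructureVolume("ab", a.contours + b.contours)
        analytic = 2 * 4.0 / 3.0 * np.pi * 1000.0 / 1000.0
        assert rasterize_structure(both, 1.0).volume_cc == pytest.approx(analytic, rel=0.02)

    def test_fine_grid_has_no_gap_slices(self):
        vol = rasterize_structure(sphere_structure("s", (0, 0, 0), 10.0), voxel=0.5)
        filled = vol.mask.any(axis=(1, 2))
        run = np.nonzero(filled)[0]
        assert np.all(np.diff(run) == 1)  # contiguous slab fill

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            rasterize_structure(StructureVolume("empty", []), 1.0)

    def test_degenerate_polygon_skipped_with_warning(self):
        s = sphere_structure("s", (0, 0, 0), 10.0)
        bad = StructureVolume(
            "bad", s.contours + [(0.0, np.array([[0, 0], [5, 0], [10, 0]], float))]
        )
        with pytest.warns(UserWarning):
            vol = rasterize_structure(bad, 1.0)
        assert vol.volume_cc == pytest.approx(4.189, rel=0.02)


class TestProjection:
    @pytest.mark.parametrize("gantry", [0.0, 37.0, 90.0, 213.0])
    def test_isocenter_voxel_projects_to_raster_center(self, gantry):
        bev = project_to_bev(single_voxel_volume(), gantry)
        rows, cols = np.nonzero(bev.pixels)
        n = bev.pixels.shape[0]
        assert rows.tolist() == [n // 2] and cols.tolist() == [n // 2]

    def test_centered_sphere_projects_to_tangent_cone_disk(self):
        r = 20.0
        vol = rasterize_structure(sphere_structure("s", (0, 0, 0), r), 1.0)
        bev = project_to_bev(vol, 0.0)
        r_meas = np.sqrt(bev.area_mm2 / np.pi)
        r_pred = SAD * r / np.sqrt(SAD**2 - r**2)
        assert abs(r_meas - r_pred) <= 2 * bev.pixel_spacing

    def test_offset_sphere_matches_ray_traced_oracle(self):
        # sphere offset toward the source: compare against analytic
        # ray-sphere intersection from the source through each pixel
        from scipy import ndimage

        r, cy = 10.0, -50.0
        vol = rasterize_structure(sphere_structure("s", (0, cy, 0), r), 1.0)
        bev = project_to_bev(vol, 0.0, min_half_extent=20.0)
        px = bev.pixel_spacing
        n = bev.pixels.shape[0]
        src = np.array([0.0, -SAD, 0.0])
        center = np.array([0.0, cy, 0.0])
        uu, vv = np.meshgrid(bev.u_centers(), bev.v_centers())
        plane_pts = np.stack([uu, np.zeros_like(uu), vv], axis=-1)
        d = plane_pts - src
        oc = src - center
        b = 2 * np.einsum("ijk,k->ij", d, oc)
        disc = b**2 - 4 * (d**2).sum(-1) * ((oc**2).sum() - r**2)
        oracle = disc >= 0
        boundary = oracle ^ ndimage.binary_erosion(oracle)
        near_boundary = ndimage.binary_dilation(boundary, np.ones((3, 3)))
        assert not np.any((oracle ^ bev.pixels) & ~near_boundary)

    def test_magnification_monotone_toward_source(self):
        near = rasterize_structure(sphere_structure("s", (0, -50, 0), 10.0), 1.0)
        far = rasterize_structure(sphere_structure("s", (0, 50, 0), 10.0), 1.0)
        a_near = project_to_bev(near, 0.0).area_mm2
        a_far = project_to_bev(far, 0.0).area_mm2
        a_par_near = project_to_bev(near, 0.0, mode="parallel").area_mm2
        a_par_far = project_to_bev(far, 0.0, mode="parallel").area_mm2
        assert a_near > a_par_near == a_par_far > a_far

    def test_voxel_behind_source_rejected(self):
        vol = single_voxel_volume()
        geom = LinacGeometry(sad=SAD, isocenter=(0.0, 1001.0, 0.0))  # source behind voxel
        with pytest.raises(GeometryError):
            project_to_bev(vol, 0.0, geom=geom)

    def test_coplanar_si_shift_moves_v_centroid_uniformly(self):
        vol0 = rasterize_structure(sphere_structure("s", (0, 0, 0), 10.0), 1.0)
        vol1 = rasterize_structure(sphere_structure("s", (0, 0, 20.0), 10.0), 1.0)
        offsets = []
        for g in (0.0, 45.0, 130.0, 270.0):
            _, v0 = project_to_bev(vol0, g, min_half_extent=40).centroid_uv()
            _, v1 = project_to_bev(vol1, g, min_half_extent=40).centroid_uv()
            offsets.append(v1 - v0)
        assert np.ptp(offsets) <= 1.0  # within one pixel worth of jitter


class TestCollimatorRotation:
    def test_theta_zero_is_identity(self):
        vol = rasterize_structure(sphere_structure("s", (10, 0, 5), 8.0), 1.0)
        bev = project_to_bev(vol, 30.0)
        assert np.array_equal(rotate_to_collimator_frame(bev, 0.0).pixels, bev.pixels)

    def test_centered_disk_area_preserved(self):
        vol = rasterize_structure(sphere_structure("s", (0, 0, 0), 15.0), 1.0)
        bev = project_to_bev(vol, 0.0)
        for theta in (17.0, 45.0, 120.0):
            rot = rotate_to_collimator_frame(bev, theta)
            assert rot.area_mm2 == pytest.approx(bev.area_mm2, rel=0.01)

    def test_square_four_fold_symmetry(self):
        from .conftest import rect_mask

        sq = rect_mask(20.0, 20.0)
        rot = rotate_to_collimator_frame(sq, 90.0)
        disagree = (rot.pixels ^ sq.pixels).sum()
        assert disagree <= 0.01 * sq.pixels.sum()

    def test_feature_moves_clockwise_in_collimator_frame(self):
        # phi -> phi - theta: a feature on +u appears on -v after theta=90
        vol = rasterize_structure(sphere_structure("s", (30, 0, 0), 8.0), 1.0)
        bev = project_to_bev(vol, 0.0, min_half_extent=50)
        u, v = rotate_to_collimator_frame(bev, 90.0).centroid_uv()
        assert abs(u) < 1.0 and v < -25.0

    def test_out_of_range_theta_rejected(self):
        vol = rasterize_structure(sphere_structure("s", (0, 0, 0), 10.0), 1.0)
        bev = project_to_bev(vol, 0.0)
        with pytest.raises(ValueError):
            rotate_to_collimator_frame(bev, 180.0)


class TestContourSilhouette:
    def test_centered_sphere_silhouette_is_tangent_cone_disk(self):
        region = project_contours_to_bev(sphere_structure("s", (0, 0, 0), 20.0), 0.0)
        r_pred = SAD * 20.0 / np.sqrt(SAD**2 - 20.0**2)
        assert region.area == pytest.approx(np.pi * r_pred**2, rel=0.01)

    def test_parallel_mode_keeps_true_radius(self):
        region = project_contours_to_bev(
            sphere_structure("s", (0, 50, 0), 20.0), 0.0, mode="parallel"
        )
        assert region.area == pytest.approx(np.pi * 400.0, rel=0.01)

    def test_two_structures_union(self):
        a = sphere_structure("a", (0, 0, 30), 10.0)
        b = sphere_structure("b", (0, 0, -30), 10.0)
        region = project_contours_to_bev([a, b], 0.0)
        assert region.area == pytest.approx(2 * np.pi * 100.0, rel=0.02)
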