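"""MCI heatmaps, sub-arc segmentation and collimator selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sacao import (
    ArcSpec,
    MCIHeatmap,
    SegmentationConstraints,
    brute_force_segment,
    build_mci_heatmap,
    segment_subarcs,
    select_collimator,
    sphere_structure,
)
from sacao.heatmap import HeatmapError, SegmentationError


def synthetic_heatmap(values, cp_spacing=2.0, start=179.0, direction="CCW"):
    values = np.asarray(values, dtype=float)
    n, _ = values.shape
    sign = 1 if direction == "CW" else -1
    angles = (start + sign * cp_spacing * np.arange(n)) % 360.0
    # attach arc metadata when the row range forms a valid arc; otherwise
    # leave it to be inferred from the gantry angles (single-row or
    # wrap-around matrices)
    span = (cp_spacing * (n - 1)) % 360.0
    arc = (
        ArcSpec(start, (start + sign * cp_spacing * (n - 1)) % 360.0, direction, cp_spacing)
        if span > 0
        else None
    )
    thetas = np.linspace(0.0, 180.0, values.shape[1], endpoint=False)
    return MCIHeatmap(values=values, gantry_angles=angles, thetas=thetas, arc=arc)


def random_heatmap(rng, n_cp=None, n_theta=None, cp_spacing=None):
    n_cp = n_cp or int(rng.integers(8, 41))
    n_theta = n_theta or int(rng.integers(3, 13))
    cp_spacing = cp_spacing or float(rng.choice([6.0, 10.0, 15.0, 30.0]))
    vals = rng.uniform(0.2, 1.0, size=(n_cp, n_theta))
    return synthetic_heatmap(vals, cp_spacing=cp_spacing, start=0.0, direction="CW")


class TestSelectCollimator:
    def test_single_row(self):
        h = synthetic_heatmap(np.array([[0.5, 0.9, 0.7]]))
        h.thetas = np.array([0.0, 60.0, 120.0])
        assert select_collimator(h, slice(0, 1)) == (60.0, 0.9)

    def test_two_rows_sum(self):
        vals = np.full((2, 4), 0.4)
        vals[:, 2] = (0.9, 0.8)
        h = synthetic_heatmap(vals)
        theta, score = select_collimator(h, slice(0, 2))
        assert theta == h.thetas[2]
        assert score == pytest.approx(1.7)

    def test_uniform_ties_break_low(self):
        h = synthetic_heatmap(np.full((3, 5), 0.6))
        theta, score = select_collimator(h, slice(0, 3))
        assert theta == 0.0
        assert score == pytest.approx(1.8)


class TestSegmentation:
    def test_constant_heatmap_single_subarc(self):
        h = synthetic_heatmap(np.full((180, 180), 0.7))
        plan = segment_subarcs(h, SegmentationConstraints())
        assert plan.n_subarcs == 1
        assert plan.subarcs[0].collimator == 0.0
        assert plan.total_score == pytest.approx(0.7 * 180)

    def test_block_heatmap_splits_at_block_boundary(self):
        vals = np.full((180, 180), 0.5)
        vals[:90, 30] = 0.9
        vals[90:, 120] = 0.9
        plan = segment_subarcs(synthetic_heatmap(vals), SegmentationConstraints())
        assert plan.n_subarcs == 2
        assert [(s.cp_start, s.cp_stop) for s in plan.subarcs] == [(0, 90), (90, 180)]
        assert [s.collimator for s in plan.subarcs] == [30.0, 120.0]
        assert plan.total_score == pytest.approx(162.0)

    def test_plan_string_uses_gantry_range_convention(self):
        vals = np.full((180, 180), 0.5)
        vals[:90, 30] = 0.9
        vals[90:, 120] = 0.9
        plan = segment_subarcs(synthetic_heatmap(vals), SegmentationConstraints())
        assert plan.table_string() == "179-359/30, 359-181/120"
        assert sum(s.span_deg for s in plan.subarcs) == pytest.approx(358.0)

    def test_infeasible_constraints_rejected(self):
        h = synthetic_heatmap(np.full((10, 6), 0.5))  # 10 CPs at 2 deg = 18 deg arc
        with pytest.raises(SegmentationError):
            segment_subarcs(h, SegmentationConstraints(min_span=30.0, cp_spacing=2.0))

    def test_min_span_below_cp_spacing_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConstraints(min_span=1.0, cp_spacing=2.0)

    def test_dp_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1234)
        checked = 0
        while checked < 12:
            h = random_heatmap(rng)
            c = SegmentationConstraints(
                min_span=30.0,
                max_subarcs=int(rng.integers(1, 10)),
                cp_spacing=h.cp_spacing,
                score_tolerance=float(rng.choice([0.0, 0.01])),
            )
            try:
                plan = segment_subarcs(h, c)
            except SegmentationError:
                continue
            oracle = brute_force_segment(h, c)
            assert plan.total_score == oracle.total_score
            assert plan.n_subarcs == oracle.n_subarcs
            checked += 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_cp=st.integers(8, 24),
        max_subarcs=st.integers(1, 9),
    )
    def test_dp_equals_brute_force_property(self, seed, n_cp, max_subarcs):
        rng = np.random.default_rng(seed)
        h = random_heatmap(rng, n_cp=n_cp, n_theta=5, cp_spacing=10.0)
        c = SegmentationConstraints(
            min_span=30.0, max_subarcs=max_subarcs, cp_spacing=10.0
        )
        try:
            plan = segment_subarcs(h, c)
        except SegmentationError:
            return
        assert plan.total_score == brute_force_segment(h, c).total_score

    def test_partition_validity_invariants(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            h = random_heatmap(rng)
            c = SegmentationConstraints(min_span=30.0, cp_spacing=h.cp_spacing)
            try:
                plan = segment_subarcs(h, c)
            except SegmentationError:
                continue
            bounds = [(s.cp_start, s.cp_stop) for s in plan.subarcs]
            assert bounds[0][0] == 0 and bounds[-1][1] == h.n_cp
            assert all(b[1] == nb[0] for b, nb in zip(bounds, bounds[1:]))
            assert plan.n_subarcs <= 9
            for s in plan.subarcs:
                assert s.n_cp * h.cp_spacing >= 30.0
                assert s.span_deg >= 30.0 - h.cp_spacing

    def test_relaxing_constraints_never_decreases_optimum(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            h = random_heatmap(rng, cp_spacing=10.0)
            base = SegmentationConstraints(
                min_span=40.0, max_subarcs=4, cp_spacing=10.0, score_tolerance=0.0
            )
            more_arcs = SegmentationConstraints(
                min_span=40.0, max_subarcs=9, cp_spacing=10.0, score_tolerance=0.0
            )
            shorter = SegmentationConstraints(
                min_span=30.0, max_subarcs=4, cp_spacing=10.0, score_tolerance=0.0
            )
            try:
                s0 = segment_subarcs(h, base).total_score
            except SegmentationError:
                continue
            assert segment_subarcs(h, more_arcs).total_score >= s0 - 1e-12
            assert segment_subarcs(h, shorter).total_score >= s0 - 1e-12

    def test_brute_force_guard(self):
        h = synthetic_heatmap(np.full((50, 4), 0.5), cp_spacing=10.0, start=0.0, direction="CW")
        with pytest.raises(ValueError):
            brute_force_segment(h, SegmentationConstraints(min_span=30, cp_spacing=10.0))


class TestHeatmapBuild:
    def test_rejects_empty_structure_list(self):
        with pytest.raises(HeatmapError):
            build_mci_heatmap([], ArcSpec(0, 90, "CW", 30.0))

    def test_centered_sphere_heatmap_flat(self):
        h = build_mci_heatmap(
            sphere_structure("s", (0, 0, 0), 18.0),
            ArcSpec(0, 330, "CW", 30.0),
            thetas=np.arange(0.0, 180.0, 15.0),
        )
        assert np.ptp(h.values, axis=1).max() < 0.02
        assert np.ptp(h.values, axis=0).max() < 0.02

    def test_opposed_parallel_beams_identical(self):
        targets = [
            sphere_structure("a", (0, 0, 30), 10.0),
            sphere_structure("b", (0, 0, -30), 10.0),
        ]
        h = build_mci_heatmap(
            targets,
            ArcSpec(0, 180, "CW", 180.0),
            thetas=np.arange(0.0, 180.0, 15.0),
            mode="parallel",
        )
        assert np.abs(h.values[0] - h.values[1]).max() < 1e-6

    def test_structure_rotation_shifts_collimators(self):
        # rotating the targets about the gantry-0 beam axis by delta shifts
        # the MCI profile by delta along the collimator axis
        delta, step = 30.0, 5.0
        a = np.deg2rad(delta)
        base = [
            sphere_structure("a", (-15, 0, 0), 7.0),
            sphere_structure("b", (15, 0, 0), 7.0),
        ]
        rot = [
            sphere_structure("a", (-15 * np.cos(a), 0, -15 * np.sin(a)), 7.0),
            sphere_structure("b", (15 * np.cos(a), 0, 15 * np.sin(a)), 7.0),
        ]
        arc = ArcSpec(0, 90, "CW", 90.0)
        thetas = np.arange(0.0, 180.0, step)
        p0 = build_mci_heatmap(base, arc, thetas=thetas).values[0]
        p1 = build_mci_heatmap(rot, arc, thetas=thetas).values[0]
        assert np.abs(np.roll(p0, int(delta / step)) - p1).max() < 0.02
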