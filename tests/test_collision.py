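"""Collision detection: violation filtering, interval rules, oracle equivalence."""

import numpy as np
import pytest

from linacclear.collision import (
    check_plan,
    collision_map,
    densify_polygon,
    find_violations,
    group_regions,
    oracle_collision_set,
    oracle_intervals,
    region_interval,
    union_intervals,
    write_collision_map_csv,
)
from linacclear.geometry import (
    AngleInterval,
    MachineGeometry,
    Point3,
    circular_diff_deg,
    interval_overlap,
)
from linacclear.phantoms import PhantomSpec, make_phantom
from linacclear.structures import BeamField, PlanSpec, StructureSet, StructureSlice

ORIGIN = Point3(0.0, 0.0, 0.0)


def point_cloud(polars, rhos, z=0.0, structure="X"):
    """Build violation-point lists directly for interval-rule tests."""
    from linacclear.collision import ViolationPoint

    pts = []
    for polar, rho in zip(polars, rhos):
        lat = rho * np.sin(np.radians(polar))
        vert = rho * np.cos(np.radians(polar))
        pts.append(
            ViolationPoint(
                patient_point=Point3(lat, vert, z),
                room_point=Point3(lat, vert, z, frame="room"),
                rho_mm=float(rho),
                polar_deg=float(polar),
                structure_name=structure,
            )
        )
    return pts


def tiny_structure(vertices, z=0.0, name="SPIKE"):
    return StructureSet(name=name, slices=[StructureSlice(z_mm=z, polygons=[np.asarray(vertices)])])


def membership(intervals, grid):
    return np.array([any(iv.contains(g) for iv in intervals) for g in grid])


class TestFindViolations:
    def test_contained_structure_yields_nothing(self, machine):
        torso = make_phantom(PhantomSpec(kind="torso", length_mm=100.0), [0.0])
        assert find_violations([torso], machine, 0.0, ORIGIN, 30.0) == []

    def test_single_protruding_vertex(self, machine):
        spike = tiny_structure([[800.0, -1.0], [800.0, 1.0], [790.0, 0.0]])
        pts = find_violations([spike], machine, 0.0, ORIGIN, 0.0)
        assert pts
        deepest = max(pts, key=lambda p: p.rho_mm)
        assert deepest.rho_mm == pytest.approx(800.0, abs=0.01)
        assert deepest.polar_deg == pytest.approx(90.0, abs=0.1)
        assert deepest.structure_name == "SPIKE"

    def test_points_outside_head_window_ignored(self, machine):
        spike = tiny_structure([[800.0, -1.0], [800.0, 1.0], [790.0, 0.0]], z=301.0)
        assert find_violations([spike], machine, 0.0, ORIGIN, 0.0) == []

    def test_boundary_point_is_safe(self, machine):
        # apex exactly on the clearance circle, everything else inside
        on_circle = tiny_structure([[400.0, 0.0], [399.0, 1.0], [399.0, -1.0]])
        assert find_violations([on_circle], machine, 0.0, ORIGIN, 0.0) == []

    def test_edge_subdivision_catches_window_crossing_edge(self, machine):
        # at couch 45 deg both top-edge vertices fall outside the head
        # window (|u| > L/2) while the mid-edge crosses it at rho = 420 mm;
        # without subdivision the whole edge would be missed
        poly = [[-500.0, 420.0], [500.0, 420.0], [0.0, 100.0]]
        pts = find_violations([tiny_structure(poly)], machine, 45.0, ORIGIN, 0.0, max_edge_mm=5.0)
        assert pts and max(p.rho_mm for p in pts) > 400.0
        coarse = find_violations(
            [tiny_structure(poly)], machine, 45.0, ORIGIN, 0.0, max_edge_mm=10000.0
        )
        assert coarse == []

    def test_isocenter_offset_is_applied(self, machine):
        spike = tiny_structure([[900.0, -1.0], [900.0, 1.0], [890.0, 0.0]])
        assert find_violations([spike], machine, 0.0, ORIGIN, 0.0)
        # moving the isocenter toward the spike brings it within 400 mm
        assert find_violations([spike], machine, 0.0, Point3(510.0, 0.0, 0.0), 0.0) == []


class TestDensify:
    def test_max_edge_respected_and_vertices_kept(self):
        tri = np.array([[0.0, 0.0], [30.0, 0.0], [0.0, 40.0]])
        dense = densify_polygon(tri, max_edge_mm=5.0)
        for v in tri:
            assert np.any(np.all(np.isclose(dense, v), axis=1))
        closed = np.vstack([dense, dense[:1]])
        steps = np.hypot(*np.diff(closed, axis=0).T)
        assert steps.max() <= 5.0 + 1e-9


class TestGroupRegions:
    def test_empty_input(self):
        assert group_regions([]) == []

    def test_nearby_points_form_one_region(self):
        pts = point_cloud([10.0, 12.0], [500.0, 480.0])
        regions = group_regions(pts)
        assert len(regions) == 1
        assert regions[0].max_point.rho_mm == 500.0

    def test_distant_points_split(self):
        regions = group_regions(point_cloud([10.0, 90.0], [500.0, 500.0]))
        assert len(regions) == 2

    def test_polar_gap_wraps_across_seam(self):
        regions = group_regions(point_cloud([178.0, -178.0], [500.0, 500.0]))
        assert len(regions) == 1

    def test_z_gap_splits_same_polar(self):
        a = point_cloud([10.0], [500.0], z=0.0)
        b = point_cloud([10.0], [500.0], z=50.0)
        assert len(group_regions(a + b)) == 2


class TestRegionInterval:
    def test_max_point_rule_interval(self):
        region = group_regions(point_cloud([10.0], [800.0]))[0]
        iv = region_interval(region, 400.0)
        assert iv.start_deg == pytest.approx(-50.0, abs=1e-6)
        assert iv.end_deg == pytest.approx(70.0, abs=1e-6)

    def test_boundary_point_gives_degenerate_interval(self):
        region = group_regions(point_cloud([25.0], [400.0]))[0]
        iv = region_interval(region, 400.0)
        assert iv.width_deg == pytest.approx(0.0, abs=1e-9)

    def test_wrapping_interval_matches_enumeration(self):
        rho = 400.0 / np.cos(np.radians(20.0))  # phi = 20 deg
        region = group_regions(point_cloud([170.0], [rho]))[0]
        iv = region_interval(region, 400.0)
        assert iv.start_deg == pytest.approx(150.0, abs=1e-6)
        assert iv.end_deg == pytest.approx(-170.0, abs=1e-6)
        grid = np.arange(-180.0, 180.0, 0.1)
        oracle = oracle_collision_set(region.points, 400.0)
        enum = np.isin(np.round(grid, 4), np.round(oracle, 4))
        mine = membership([iv], grid)
        disagreements = grid[enum != mine]
        assert all(
            min(circular_diff_deg(g, iv.start_deg), circular_diff_deg(g, iv.end_deg)) <= 0.1001
            for g in disagreements
        )


class TestUnionVsOracle:
    def test_single_point_consistency(self):
        pts = point_cloud([40.0], [800.0])
        iv_union = union_intervals(pts, 400.0)
        iv_region = region_interval(group_regions(pts)[0], 400.0)
        assert len(iv_union) == 1
        assert iv_union[0].start_deg == pytest.approx(iv_region.start_deg)
        assert iv_union[0].end_deg == pytest.approx(iv_region.end_deg)

    def test_disjoint_points_give_disjoint_arcs(self):
        pts = point_cloud([0.0, 150.0], [420.0, 420.0])
        arcs = union_intervals(pts, 400.0)
        assert len(arcs) == 2

    def test_one_point_at_twice_radius_covers_pm_60(self):
        colliding = oracle_collision_set(point_cloud([0.0], [800.0]), 400.0)
        assert colliding.min() == pytest.approx(-60.0, abs=0.11)
        assert colliding.max() == pytest.approx(60.0, abs=0.11)

    def test_no_points_empty_oracle(self):
        assert len(oracle_collision_set([], 400.0)) == 0

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_union_equals_oracle_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.arange(-180.0, 180.0, 0.1)
        for _ in range(20):
            n = rng.integers(10, 500)
            polars = rng.uniform(-180.0, 180.0, n)
            rhos = 400.0 * rng.uniform(0.5, 3.0, n)
            pts = point_cloud(polars[rhos > 400.0], rhos[rhos > 400.0])
            arcs = union_intervals(pts, 400.0)
            oracle = oracle_collision_set(pts, 400.0)
            enum = np.isin(np.round(grid, 4), np.round(oracle, 4))
            mine = membership(arcs, grid)
            bad = grid[enum != mine]
            endpoints = [e for iv in arcs for e in (iv.start_deg, iv.end_deg)]
            assert all(
                any(circular_diff_deg(g, e) <= 0.1001 for e in endpoints) for g in bad
            ), f"seed {seed}: disagreement away from endpoints"

    def test_max_point_rule_never_exceeds_union_for_singletons(self):
        pts = point_cloud([30.0], [600.0])
        union = union_intervals(pts, 400.0)
        mp = region_interval(group_regions(pts)[0], 400.0)
        grid = np.arange(-180.0, 180.0, 0.5)
        assert np.array_equal(membership([mp], grid), membership(union, grid))

    def test_max_point_rule_can_undercover_multipoint_regions(self):
        # two moderately deep points 4 deg apart: one region, but the deepest
        # point's arc does not reach the other's far side
        pts = point_cloud([0.0, 4.0], [405.0, 406.0])
        union = union_intervals(pts, 400.0)
        mp = region_interval(group_regions(pts)[0], 400.0)
        grid = np.arange(-180.0, 180.0, 0.05)
        in_union = membership(union, grid)
        in_mp = membership([mp], grid)
        assert np.all(~in_mp | in_union)  # max-point arc is a subset of the union
        assert in_union.sum() > in_mp.sum()


class TestCheckPlan:
    def test_scenario_verdicts_under_both_rules(self, scenarios):
        for sc in scenarios:
            for method in ("union", "max_point"):
                rep = check_plan(sc.plan, sc.structures, sc.machine, 0.0, method=method)
                got = "collision" if rep.calculated_collision else "safe"
                assert got == sc.expected_verdict, (sc.label, method)
                if sc.expected_structures:
                    seen = {n for f in rep.fields for n in f.violating_structures}
                    assert sc.expected_structures <= seen, sc.label

    def test_field_state_reflects_overlap(self, scenarios):
        sc = next(s for s in scenarios if s.expected_verdict == "collision")
        rep = check_plan(sc.plan, sc.structures, sc.machine, 0.0)
        for f in rep.fields:
            assert (f.state == "red") == f.overlap

    def test_collision_outside_planned_arc_stays_green(self, machine):
        # protrusion straight below (polar 180) while the plan only sweeps
        # the upper hemisphere
        spike = tiny_structure([[-1.0, -500.0], [1.0, -500.0], [0.0, -490.0]])
        plan = PlanSpec(
            isocenter=ORIGIN,
            fields=(BeamField("a", 0.0, AngleInterval(-80.0, 80.0)),),
        )
        rep = check_plan(plan, [spike], machine, 0.0)
        assert not rep.calculated_collision
        assert rep.fields[0].collision_intervals  # arcs exist, but miss the plan

    def test_margin_monotonicity_of_flagged_angles(self, scenarios, machine):
        sc = scenarios[0]  # the safe scenario has margin headroom
        grid = np.arange(-180.0, 180.0, 1.0)
        previous = np.zeros(len(grid), dtype=bool)
        for margin in (0.0, 40.0, 80.0, 120.0):
            pts = find_violations(sc.structures, machine, 0.0, sc.plan.isocenter, margin)
            arcs = union_intervals(pts, 400.0 - margin)
            flagged = membership(arcs, grid)
            assert np.all(previous <= flagged), f"margin {margin} lost flagged angles"
            previous = flagged
        assert previous.any()  # large margin eventually flags the couch

    def test_lateral_mirror_negates_intervals(self, machine):
        body = make_phantom(
            PhantomSpec(kind="torso", center_lateral_mm=260.0, length_mm=100.0), [0.0]
        )
        mirrored = body.mirrored_lateral()
        pts = find_violations([body], machine, 0.0, ORIGIN, 0.0)
        pts_m = find_violations([mirrored], machine, 0.0, ORIGIN, 0.0)
        arcs = union_intervals(pts, 400.0)
        arcs_m = union_intervals(pts_m, 400.0)
        assert len(arcs) == len(arcs_m) == 1
        assert arcs[0].start_deg == pytest.approx(-arcs_m[0].end_deg, abs=1e-6)
        assert arcs[0].end_deg == pytest.approx(-arcs_m[0].start_deg, abs=1e-6)

    def test_report_json_is_deterministic(self, scenarios):
        sc = scenarios[1]
        a = check_plan(sc.plan, sc.structures, sc.machine, 10.0).to_json()
        b = check_plan(sc.plan, sc.structures, sc.machine, 10.0).to_json()
        assert a == b
        assert '"calculated_collision": true' in a


class TestCollisionMap:
    def test_contained_structure_gives_empty_map(self, machine):
        torso = make_phantom(PhantomSpec(kind="torso", length_mm=200.0), [0.0, 50.0])
        cmap = collision_map([torso], ORIGIN, machine, [-30.0, 0.0, 30.0], 0.0)
        assert all(v == [] for v in cmap.values())

    def test_map_entry_matches_check_plan_field(self, scenarios):
        sc = next(s for s in scenarios if s.label == "noncoplanar_abdomen")
        cmap = collision_map(
            sc.structures, sc.plan.isocenter, sc.machine, [30.0], 0.0
        )
        rep = check_plan(sc.plan, sc.structures, sc.machine, 0.0)
        map_arcs = [(iv.start_deg, iv.end_deg) for iv in cmap[30.0]]
        field_arcs = [(iv.start_deg, iv.end_deg) for iv in rep.fields[0].collision_intervals]
        assert map_arcs == pytest.approx(field_arcs)

    def test_mirrored_setup_mirrors_the_map(self, machine):
        body = make_phantom(
            PhantomSpec(kind="torso", center_lateral_mm=280.0, length_mm=300.0),
            list(np.arange(-150.0, 151.0, 50.0)),
        )
        mirrored = body.mirrored_lateral()
        cmap = collision_map([body], ORIGIN, machine, [-20.0, 0.0, 20.0], 0.0)
        cmap_m = collision_map([mirrored], ORIGIN, machine, [-20.0, 0.0, 20.0], 0.0)
        for theta in (0.0,):
            for iv, iv_m in zip(cmap[theta], reversed(cmap_m[theta])):
                assert iv.start_deg == pytest.approx(-iv_m.end_deg, abs=1e-6)
                assert iv.end_deg == pytest.approx(-iv_m.start_deg, abs=1e-6)

    def test_csv_export_shape(self, machine, tmp_path):
        spike = tiny_structure([[500.0, -1.0], [500.0, 1.0], [490.0, 0.0]])
        cmap = collision_map([spike], ORIGIN, machine, [0.0, 10.0], 0.0)
        out = tmp_path / "map.csv"
        write_collision_map_csv(cmap, out, gantry_step_deg=5.0)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 couch angles
        header = lines[0].split(",")
        assert header[0] == "couch_angle_deg" and len(header) == 1 + 72
        row0 = lines[1].split(",")
        assert "1" in row0[1:]  # the spike collides somewhere


class TestOracleIntervals:
    def test_runs_recover_analytic_arcs(self):
        pts = point_cloud([20.0, 170.0], [800.0, 500.0])
        analytic = union_intervals(pts, 400.0)
        enum = oracle_intervals(pts, 400.0, step_deg=0.1)
        assert len(analytic) == len(enum)
        for a, b in zip(analytic, enum):
            assert circular_diff_deg(a.start_deg, b.start_deg) <= 0.1001
            assert circular_diff_deg(a.end_deg, b.end_deg) <= 0.1001
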