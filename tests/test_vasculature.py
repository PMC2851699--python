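import numpy as np
import pytest

from vasotherm.core import ConfigurationError, make_grid
from vasotherm.vasculature import (
    ARTERY,
    VEIN,
    assign_flows,
    build_network,
    vessel_speed,
    vessel_surface_profile,
)


class TestGeometry:
    @pytest.mark.parametrize("gamma,expected", [
        (0.7, [1.0, 0.7, 0.49, 0.343, 0.2401, 0.16807, 0.16807]),
        (1.0, [1.0] * 7),
    ])
    def test_diameters_follow_generation_ratio(self, grid, gamma, expected):
        net = build_network(grid, gamma=gamma, d1=1e-3)
        for lvl, d in enumerate(expected, start=1):
            seg = next(net.iter_segments(ARTERY, lvl))
            assert seg.diameter == pytest.approx(d * 1e-3, rel=1e-12)

    def test_seven_levels_and_128_terminals(self, network):
        for lvl in range(1, 8):
            assert any(network.iter_segments(ARTERY, lvl))
        assert len(network.subvolumes) == 128
        assert network.vessel_count_by_level(7)[ARTERY] == 128

    def test_total_vessel_count(self, network):
        # chain-merged count: 341 per tree
        assert network.vessel_count(ARTERY) == 341
        assert network.vessel_count() == 682

    def test_subvolumes_tile_control_volume(self, grid, network):
        # oracle: every 2-mm cell center lies in exactly one subvolume box
        centers = 0
        nx, ny, nz = grid.shape
        xs = (np.arange(nx - 1) + 0.5) * 2.0
        ys = (np.arange(ny - 1) + 0.5) * 2.0
        zs = (np.arange(nz - 1) + 0.5) * 2.0
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        count = np.zeros(X.shape, dtype=int)
        for sv in network.subvolumes:
            lo, hi = sv.box.lo_mm, sv.box.hi_mm
            inside = ((X > lo[0]) & (X < hi[0]) & (Y > lo[1]) & (Y < hi[1])
                      & (Z > lo[2]) & (Z < hi[2]))
            count += inside
        assert (count == 1).all()
        vol = sum(sv.box.volume_m3() for sv in network.subvolumes)
        assert vol == pytest.approx(0.082 * 0.08 * 0.08, rel=1e-12)

    def test_terminal_end_inside_its_subvolume(self, grid, network):
        for sv in network.subvolumes:
            end = network.segments[sv.feeding_artery].path[-1] * 2.0
            assert sv.box.contains_mm(end)

    def test_margin_pathway_waypoints_present(self, grid, network):
        # the documented tumor-margin route, one straight run per level
        runs = [
            (2, (42, 40, 40), (42, 40, 60)),
            (3, (42, 40, 60), (42, 60, 60)),
            (4, (42, 60, 60), (62, 60, 60)),
            (5, (42, 60, 60), (42, 60, 50)),
            (6, (42, 60, 50), (42, 50, 50)),
        ]
        for lvl, a, b in runs:
            nodes = set()
            for seg in network.iter_segments(ARTERY, lvl):
                nodes.update(map(tuple, (seg.path * 2).tolist()))
            a, b = np.array(a), np.array(b)
            axis = int(np.nonzero(b - a)[0][0])
            step = np.sign(b[axis] - a[axis]) * 2
            p = a.astype(float)
            while True:
                assert tuple(p) in nodes, (lvl, tuple(p))
                if p[axis] == b[axis]:
                    break
                p[axis] += step

    def test_level1_spans_inlet_to_outlet(self, network):
        nodes = np.concatenate(
            [s.path for s in network.iter_segments(ARTERY, 1)])
        assert nodes[:, 0].min() == 0 and nodes[:, 0].max() == 41

    def test_vein_offset_and_no_collisions(self, network):
        art = set()
        vein = set()
        for seg in network.segments.values():
            target = art if seg.kind == ARTERY else vein
            target.update(map(tuple, seg.path.tolist()))
        assert not art & vein
        # congruence: every non-trunk artery node + (1,1,1) is a vein node
        trunk = set()
        for seg in network.iter_segments(ARTERY, 1):
            trunk.update(map(tuple, seg.path.tolist()))
        shifted = {(i + 1, j + 1, k + 1) for i, j, k in art - trunk}
        assert shifted <= vein

    def test_bad_gamma_rejected(self, grid):
        with pytest.raises(ConfigurationError):
            build_network(grid, gamma=0.0)
        with pytest.raises(ConfigurationError):
            build_network(grid, gamma=1.5)

    def test_waypoints_off_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            build_network(make_grid((81, 81, 81), 3))


class TestFlows:
    def test_terminal_flow_is_perfusion_times_volume(self, grid):
        net = assign_flows(build_network(grid), 0.5)
        sv = next(s for s in net.subvolumes
                  if s.box.volume_m3() == pytest.approx(4e-6))
        assert net.segments[sv.feeding_artery].mass_flow == \
            pytest.approx(0.5 * 4e-6, rel=1e-12)

    def test_zero_perfusion_zero_flows(self, grid):
        net = assign_flows(build_network(grid), 0.0)
        assert all(s.mass_flow == 0.0 for s in net.segments.values())

    def test_junction_mass_conservation_exact(self, network):
        # oracle: independent post-order subtree sum
        def subtree(seg_id):
            seg = network.segments[seg_id]
            return seg.base_flow + sum(subtree(c) for c in seg.children)

        for seg in network.segments.values():
            if seg.children:
                assert seg.mass_flow == pytest.approx(
                    subtree(seg.id), abs=1e-18)
                total_children = sum(
                    network.segments[c].mass_flow for c in seg.children)
                assert abs(seg.mass_flow - seg.base_flow - total_children) \
                    < 1e-15

    def test_inlet_carries_total_plus_passthrough(self, network):
        V = 0.082 * 0.08 * 0.08
        assert network.level1_inlet(ARTERY).mass_flow == \
            pytest.approx(0.5 * V * 1.001, rel=1e-12)
        assert network.level1_inlet(VEIN).mass_flow == \
            pytest.approx(0.5 * V * 1.001, rel=1e-12)

    def test_vein_flows_mirror_artery_flows(self, network):
        art = sorted(s.mass_flow for s in network.iter_segments(ARTERY))
        vein = sorted(s.mass_flow for s in network.iter_segments(VEIN))
        np.testing.assert_allclose(art, vein, rtol=1e-12)


class TestSpeeds:
    def test_level1_speed_matches_mass_conservation(self, grid):
        # ~320 mm/s at w_b = 0.5 and ~6 mm/s at 0.01 with a 1-mm main artery
        net = assign_flows(build_network(grid), 0.5)
        v = vessel_speed(net.level1_inlet())
        assert v * 1e3 == pytest.approx(320, rel=0.10)
        assign_flows(net, 0.01)
        v2 = vessel_speed(net.level1_inlet())
        assert v2 * 1e3 == pytest.approx(6, rel=0.15)
        assert v2 == pytest.approx(v * 0.02, rel=1e-12)  # linear in w_b

    def test_zero_flow_zero_speed(self, grid):
        net = assign_flows(build_network(grid), 0.0)
        assert vessel_speed(net.level1_inlet()) == 0.0

    @pytest.mark.parametrize("gamma", [0.7, 0.8, 0.9])
    def test_terminal_speed_below_main_artery(self, grid, gamma):
        # terminal lumen area per terminal shrinks as gamma^10; with 128
        # terminals sharing the flow, speeds drop below the main artery
        # from gamma ~0.65 upward (at 0.6 they exceed it)
        net = assign_flows(build_network(grid, gamma=gamma), 0.5)
        prof = vessel_surface_profile(net)
        art = prof[prof.kind == ARTERY].set_index("level")
        assert art.loc[7, "max_speed_m_s"] < art.loc[1, "max_speed_m_s"]

    def test_profile_monotone_trends(self, network):
        prof = vessel_surface_profile(network)
        art = prof[prof.kind == ARTERY].sort_values("level")
        d = art.diameter_m.to_numpy()
        assert (np.diff(d[:6]) < 0).all() and d[5] == d[6]
        assert art["count"].is_monotonic_increasing


class TestExport:
    def test_manifest_round_trip(self, network, tmp_path):
        import json
        from vasotherm.vasculature import load_network
        network.save_json(tmp_path / "net.json")
        man = json.loads((tmp_path / "net.json").read_text())
        assert man["vessel_count"] == 682
        assert len(man["segments"]) == len(network.segments)
        assert len(man["subvolumes"]) == 128
        assert man["gamma"] == network.gamma
        loaded = load_network(tmp_path / "net.json")
        assert loaded.vessel_count() == network.vessel_count()
        assert loaded.w_b == network.w_b
        for sid, seg in network.segments.items():
            other = loaded.segments[sid]
            np.testing.assert_array_equal(seg.path, other.path)
            assert other.mass_flow == seg.mass_flow
            assert other.diameter == seg.diameter
            assert sorted(other.children) == sorted(seg.children)
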