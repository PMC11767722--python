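"""Skeleton/graph extraction, edge regions and the R_tau / R_Q weighting."""

import numpy as np
import pytest

import lumenflow as lf
from lumenflow.masks import LumenMask
from lumenflow.network import (
    assign_edge_regions,
    extract_graph,
    orientation_deg,
    skeletonize_mask,
)

PX = 1.5625


class TestSkeleton:
    def test_straight_channel_two_endpoints_no_junctions(self, straight_channel):
        g = extract_graph(skeletonize_mask(straight_channel))
        kinds = [d["kind"] for _, d in g.g.nodes(data=True)]
        assert sorted(kinds) == ["endpoint", "endpoint"]
        assert g.n_edges == 1

    def test_y_branch_one_junction_three_endpoints(self, y_branch):
        g = extract_graph(skeletonize_mask(y_branch))
        kinds = sorted(d["kind"] for _, d in g.g.nodes(data=True))
        assert kinds == ["endpoint", "endpoint", "endpoint", "junction"]

    def test_solid_disc_degenerate_skeleton(self):
        m = np.zeros((64, 64), dtype=bool)
        rr, cc = np.ogrid[:64, :64]
        m[(rr - 32) ** 2 + (cc - 32) ** 2 < 24**2] = True
        skel = skeletonize_mask(LumenMask(m, PX), spur_min_px=5)
        assert skel.pixels.sum() <= 5

    def test_empty_mask_rejected(self):
        with pytest.raises(Exception):
            lf.LumenMask(np.zeros((8, 8), bool), PX)

    def test_roundtrip_pixels_exactly_covered(self, bridge_lattice, lattice):
        for mask in (bridge_lattice, lattice):
            skel = skeletonize_mask(mask)
            g = extract_graph(skel)
            covered = set()
            for _, d in g.g.nodes(data=True):
                covered |= set(d["pixels"])
            for _, _, _, d in g.edges():
                covered |= set(map(tuple, d["chain"]))
            assert covered == set(map(tuple, np.argwhere(skel.pixels)))


class TestGraphTopology:
    def test_lattice_cycle_rank_equals_hole_count(self, lattice):
        from scipy import ndimage as ndi

        g = extract_graph(skeletonize_mask(lattice))
        import networkx as nx

        C = nx.number_connected_components(g.g)
        cycle_rank = g.n_edges - g.n_nodes + C
        # holes of the mask: background components not touching the image border
        bg_lab, n = ndi.label(~lattice.pixels)
        border = set(bg_lab[0]) | set(bg_lab[-1]) | set(bg_lab[:, 0]) | set(bg_lab[:, -1])
        holes = len(set(range(1, n + 1)) - border)
        assert cycle_rank == holes
        assert holes == 4  # 3x3 channel lattice encloses a 2x2 grid of holes

    def test_bridge_graph_two_junctions_one_perpendicular_bridge(self, bridge_lattice):
        g = extract_graph(skeletonize_mask(bridge_lattice))
        junctions = [n for n, d in g.g.nodes(data=True) if d["kind"] == "junction"]
        assert len(junctions) == 2
        bridges = [
            d
            for u, v, k, d in g.edges()
            if {u, v} == set(junctions)
        ]
        assert len(bridges) == 1
        # toys flow along columns: the bridge runs along rows, i.e. within
        # 10 degrees of perpendicular to the flow axis
        ang = orientation_deg(bridges[0]["chain"])
        assert ang <= 10.0  # 0 deg = along rows = perpendicular to col-flow

    def test_isolated_cycle_gets_anchor_node(self):
        m = np.zeros((96, 96), dtype=bool)
        rr, cc = np.ogrid[:96, :96]
        ring = ((rr - 48) ** 2 + (cc - 48) ** 2 < 40**2) & (
            (rr - 48) ** 2 + (cc - 48) ** 2 > 28**2
        )
        g = extract_graph(skeletonize_mask(LumenMask(ring, PX)))
        assert g.n_nodes == 1
        assert g.n_edges == 1  # self-loop around the ring


class TestEdgeRegions:
    def test_straight_channel_region_covers_lumen(self, straight_channel):
        skel = skeletonize_mask(straight_channel)
        g = extract_graph(skel)
        regions, labels = assign_edge_regions(g, skel)
        coverage = (labels >= 0).sum() / straight_channel.pixels.sum()
        assert coverage >= 0.99

    def test_regions_disjoint_and_cover_flow_bearing_lumen(self, lattice_frame):
        wg = lattice_frame.weighted_graph
        labels = wg.region_labels
        lumen = wg.graph.skeleton.mask.pixels
        assert labels[~lumen].max() == -1  # regions never leave the lumen
        flow_ok = wg.domain.flow_lumen_mask()
        coverage = (labels[flow_ok] >= 0).mean()
        assert coverage >= 0.95


class TestWeights:
    def test_straight_channel_rq_is_one(self, straight_channel, cols_flow):
        r = lf.analyze_frame(straight_channel, flow_config=cols_flow)
        (rq,) = [d["R_Q"] for *_, d in r.weighted_graph.g.edges(keys=True, data=True)]
        assert rq == pytest.approx(1.0, rel=0.02)

    def test_y_branch_daughters_rq_half(self, y_branch_frame):
        g = y_branch_frame.weighted_graph.g
        rqs = sorted(d["R_Q"] for *_, d in g.edges(keys=True, data=True))
        assert len(rqs) == 3
        assert rqs[0] == pytest.approx(0.5, rel=0.02)
        assert rqs[1] == pytest.approx(0.5, rel=0.02)
        assert rqs[2] == pytest.approx(1.0, rel=0.02)

    def test_straight_channel_wall_integral_closed_form(self, cols_flow):
        # sum tau_i * h over both walls = (6 mu U / w) * 2 L
        mu, U = cols_flow.mu, cols_flow.U_inlet
        mask = lf.generate_toy_geometry(
            lf.ToyGeometrySpec("straight_channel", width_um=100.0, image_shape_px=(128, 256))
        )
        r = lf.analyze_frame(mask, flow_config=cols_flow)
        h = mask.pixel_size_m
        w = 64 * h
        L = 256 * h
        wall_sum = r.wss.tau.sum() * h
        assert wall_sum == pytest.approx(6 * mu * U / w * 2 * L, rel=0.05)
        # hence R_tau matches its closed form for the single-edge toy
        (rtau,) = [d["R_tau"] for *_, d in r.weighted_graph.g.edges(keys=True, data=True)]
        A = r.area.area_um2 * 1e-12
        tau_ref = 8 * mu * U * cols_flow.d_ch / A
        assert rtau == pytest.approx(6 * mu * U / w * 2 * L / (tau_ref * cols_flow.d_ch), rel=0.05)

    def test_cut_conservation_on_lattice(self, lattice_frame, cols_flow):
        wg = lattice_frame.weighted_graph
        w_in = wg.domain.inlet_width_m
        cut_col = 112  # between the first two vertical channels
        total = 0.0
        for *_, d in wg.g.edges(keys=True, data=True):
            ch = d["chain"]
            if ch and min(c for _, c in ch) < cut_col <= max(c for _, c in ch):
                total += d["Q_signed"] / (cols_flow.U_inlet * w_in)
        assert total == pytest.approx(1.0, abs=0.02)

    def test_rq_in_unit_interval_for_series_parallel_network(self, lattice_frame):
        for *_, d in lattice_frame.weighted_graph.g.edges(keys=True, data=True):
            assert -1e-9 <= d["R_Q"] <= 1.0 + 0.02

    def test_weights_invariant_under_inlet_velocity_scaling(self, bridge_lattice):
        r1 = lf.analyze_frame(bridge_lattice, flow_config=lf.FlowConfig(flow_axis="cols"))
        r2 = lf.analyze_frame(
            bridge_lattice, flow_config=lf.FlowConfig(flow_axis="cols", U_inlet=1e-3)
        )
        w1 = {d["eid"]: (d["R_Q"], d["R_tau"]) for *_, d in r1.weighted_graph.g.edges(keys=True, data=True)}
        w2 = {d["eid"]: (d["R_Q"], d["R_tau"]) for *_, d in r2.weighted_graph.g.edges(keys=True, data=True)}
        for eid in w1:
            assert w1[eid][0] == pytest.approx(w2[eid][0], abs=1e-9)
            assert w1[eid][1] == pytest.approx(w2[eid][1], abs=1e-9)

    def test_literal_normalization_rescales_uniformly(self, straight_channel, cols_flow):
        import lumenflow.network as net
        import lumenflow.flow as fl
        import lumenflow.masks as mk

        domain = fl.build_domain(straight_channel, cols_flow)
        field = fl.solve_flow(domain, cols_flow)
        wss = fl.compute_wss(field, domain, cols_flow)
        area = mk.measure_area(straight_channel)
        skel = net.skeletonize_mask(straight_channel)
        g = net.extract_graph(skel)

        def rtaus(norm):
            regions, labels = net.assign_edge_regions(g, skel, wss=wss)
            wg = net.weight_graph(
                g, regions, wss, field, area, cols_flow, domain=domain,
                region_labels=labels, rtau_normalization=norm,
            )
            return [d["R_tau"] for *_, d in wg.g.edges(keys=True, data=True)]

        a = rtaus("equivalent_channel")
        b = rtaus("literal")
        ratio = a[0] / b[0]
        assert all(x / y == pytest.approx(ratio, rel=1e-9) for x, y in zip(a, b))
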