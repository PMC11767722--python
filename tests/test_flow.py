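"""Stokes solver contracts: Poiseuille closed form, conservation, linearity."""

import numpy as np
import pytest

import lumenflow as lf
from lumenflow.flow import (
    FlowConfig,
    NoPerfusionError,
    build_domain,
    compute_wss,
    edge_flux,
    make_cross_section,
    solve_flow,
)
from lumenflow.masks import LumenMask

# plane Poiseuille references: tau_wall = 6 mu U / w, u_max = 1.5 U
MU, U, W = 1.0e-3, 1.0e-4, 1.0e-4


def _channel_mask(width_px: int, pixel_um: float, length_px: int = 256) -> LumenMask:
    m = np.zeros((length_px, 2 * width_px), dtype=bool)
    c0 = width_px // 2
    m[:, c0 : c0 + width_px] = True
    return LumenMask(m, pixel_um)


def _poiseuille_tau_error(width_px: int) -> float:
    pixel_um = W * 1e6 / width_px
    mask = _channel_mask(width_px, pixel_um)
    cfg = FlowConfig(mu=MU, U_inlet=U)
    field = solve_flow(build_domain(mask, cfg), cfg)
    wss = compute_wss(field)
    away = (wss.wall_pixels[:, 0] > 50) & (wss.wall_pixels[:, 0] < 200)
    tau = wss.tau[away].mean()
    return abs(tau - 6 * MU * U / W) / (6 * MU * U / W)


class TestPoiseuille:
    def test_centerline_velocity_is_three_halves_mean(self):
        mask = _channel_mask(64, W * 1e6 / 64)
        cfg = FlowConfig(mu=MU, U_inlet=U)
        field = solve_flow(build_domain(mask, cfg), cfg)
        centerline = field.vel_r[128].max()
        assert centerline == pytest.approx(1.5 * U, rel=0.03)

    def test_wall_shear_matches_closed_form(self):
        assert _poiseuille_tau_error(64) < 0.05

    def test_tau_error_decreases_under_refinement(self):
        errs = [_poiseuille_tau_error(n) for n in (16, 32, 64)]
        assert errs[0] > errs[1] > errs[2]


class TestConservationAndBCs:
    def test_global_mass_conservation(self, straight_solution):
        _, field = straight_solution
        assert abs(field.outlet_flux - field.inlet_flux) <= 0.01 * field.inlet_flux

    def test_divergence_free_to_solver_tolerance(self, straight_solution):
        _, field = straight_solution
        # worst cell divergence versus a characteristic velocity gradient U/h
        h = field.domain.h
        assert field.max_div < 1e-6 * field.config.U_inlet / h

    def test_sections_along_unbranched_channel_agree(self, straight_channel, straight_solution):
        _, field = straight_solution
        r = straight_channel.shape[0] // 2
        qs = []
        for c in (64, 192):  # 25% and 75% along the channel
            cs = make_cross_section(straight_channel, (r, c), (0.0, 1.0))
            qs.append(edge_flux(field, cs))
        assert abs(qs[0] - qs[1]) <= 0.01 * abs(qs[0])

    def test_full_width_section_recovers_inlet_flow(self, straight_channel, straight_solution):
        _, field = straight_solution
        cs = make_cross_section(straight_channel, (64, 128), (0.0, 1.0))
        q = edge_flux(field, cs)
        assert q == pytest.approx(field.inlet_flux, rel=0.01)

    def test_y_branch_daughters_split_evenly_and_balance(self, y_branch, cols_flow):
        domain = build_domain(y_branch, cols_flow)
        field = solve_flow(domain, cols_flow)
        mid = y_branch.shape[0] // 2
        q_parent = edge_flux(field, make_cross_section(y_branch, (mid, 40), (0.0, 1.0)))
        # daughter sections near the outlet, where the two arms are separate
        rows = np.nonzero(y_branch.pixels[:, 250])[0]
        top = rows[rows < mid]
        bot = rows[rows >= mid]
        q1 = edge_flux(field, make_cross_section(y_branch, (int(top.mean()), 250), (0.0, 1.0)))
        q2 = edge_flux(field, make_cross_section(y_branch, (int(bot.mean()), 250), (0.0, 1.0)))
        assert q1 == pytest.approx(q2, rel=0.01)            # mirror symmetry
        assert q1 + q2 == pytest.approx(q_parent, rel=0.01)  # junction balance

    def test_cross_section_outside_lumen_rejected(self, straight_channel):
        with pytest.raises(ValueError):
            make_cross_section(straight_channel, (0, 0), (0.0, 1.0))


class TestDomain:
    def test_no_perfusion_path_raises(self):
        m = np.zeros((64, 64), dtype=bool)
        m[20:40, 20:40] = True  # island touching no border
        with pytest.raises(NoPerfusionError, match="no perfusion path"):
            build_domain(LumenMask(m, 1.5625), FlowConfig())

    def test_isolated_island_flagged_no_flow(self, cols_flow):
        m = np.zeros((128, 256), dtype=bool)
        m[40:60, :] = True      # perfused channel
        m[90:110, 90:130] = True  # island
        mask = LumenMask(m, 1.5625)
        domain = build_domain(mask, cols_flow)
        assert domain.perfused
        assert domain.no_flow[100, 100]
        assert not domain.no_flow[50, 100]
        field = solve_flow(domain, cols_flow)
        assert np.all(field.speed[90:110, 90:130] == 0.0)

    def test_y_branch_boundary_partition(self, y_branch, cols_flow):
        domain = build_domain(y_branch, cols_flow)
        assert domain.border_segments() == (1, 2)


class TestLinearity:
    def test_velocity_and_tau_scale_with_inlet_velocity(self, straight_channel):
        f1 = solve_flow(build_domain(straight_channel, FlowConfig(flow_axis="cols", U_inlet=U)))
        f2 = solve_flow(
            build_domain(straight_channel, FlowConfig(flow_axis="cols", U_inlet=3 * U))
        )
        np.testing.assert_allclose(3 * f1.vel_c, f2.vel_c, rtol=1e-8, atol=1e-12 * U)
        t1 = compute_wss(f1).tau
        t2 = compute_wss(f2).tau
        np.testing.assert_allclose(3 * t1, t2, rtol=1e-8)

    def test_tau_linear_in_viscosity_at_fixed_field(self, straight_solution):
        domain, field = straight_solution
        t1 = compute_wss(field, domain, FlowConfig(flow_axis="cols", mu=MU))
        t2 = compute_wss(field, domain, FlowConfig(flow_axis="cols", mu=2 * MU))
        np.testing.assert_allclose(2 * t1.tau, t2.tau)

    def test_zero_flow_field_gives_zero_tau(self):
        m = np.zeros((64, 64), dtype=bool)
        m[0:64, 20:40] = True  # touches inlet border only along rows
        m[40:41, :] = False    # cut: outlet side unreachable... keep simple
        m[:, :] = False
        m[0:30, 20:40] = True  # touches top border only
        mask = LumenMask(m, 1.5625)
        domain = build_domain(mask, FlowConfig(flow_axis="rows"))
        assert not domain.perfused
        field = solve_flow(domain)
        assert field.zero_flow
        wss = compute_wss(field, domain)
        assert np.all(wss.tau == 0.0)
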