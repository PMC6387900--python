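"""Oxygen transport: uptake physics, limits, conservation, statistics."""

import math

import numpy as np
import pytest

import zonesim as zs
from zonesim.profiles import SurfaceProfile


class TestNoSinkLimit:
    def test_zero_vmax_gives_uniform_inlet_concentration(self, chamber):
        cfg, mesh, flow, conc = chamber(0.0, level=1, vmax_per_cell=0.0)
        assert np.allclose(conc.c[mesh.fluid], cfg.inlet_oxygen, rtol=1e-9)
        profile = zs.surface_oxygen_profile(conc, cfg)
        mean, mn = zs.surface_stats(profile)
        assert mean == pytest.approx(cfg.inlet_oxygen, rel=1e-9)
        assert mn == pytest.approx(cfg.inlet_oxygen, rel=1e-9)
        assert zs.oxygen_mass_balance(conc, flow, cfg) <= 1e-6

    def test_large_km_approaches_no_sink_solution(self):
        cfg = zs.build_geometry(km=1e3)
        mesh = zs.build_mesh(cfg, 1)
        flow = zs.solve_flow(cfg, mesh)
        conc = zs.solve_oxygen(cfg, mesh, flow)
        mean, _ = zs.surface_stats(zs.surface_oxygen_profile(conc, cfg))
        assert mean == pytest.approx(cfg.inlet_oxygen, rel=1e-3)


class TestStagnantColumnOracle:
    """The 2D solver against the closed-form 1D Michaelis-Menten column."""

    @pytest.mark.parametrize(
        "sigma_vmax, km",
        [(3e-8, 5e-3), (8e-8, 2e-2), (3e-8, 1e-9)],  # last: near zeroth-order
    )
    def test_surface_concentration_matches_quadratic_root(self, sigma_vmax, km):
        case = zs.stagnant_mm_case(
            c0=0.21, depth=5e-3, diffusivity=3e-9, sigma_vmax=sigma_vmax, km=km
        )
        case.self_check()
        mesh = case.mesh(2)
        flow = zs.solve_flow(case.config, mesh)
        conc = zs.solve_oxygen(case.config, mesh, flow)
        c_s = zs.surface_oxygen_profile(conc, case.config).mean()
        assert c_s == pytest.approx(case.analytic["surface_conc"], rel=0.01)

    def test_zeroth_order_limit_closed_form(self):
        # km -> 0 with saturated uptake: c_s = c0 - sigma_vmax * L / D
        case = zs.stagnant_mm_case(0.21, 5e-3, 3e-9, 3e-8, km=1e-9)
        expected = 0.21 - 3e-8 * 5e-3 / 3e-9
        assert case.analytic["surface_conc"] == pytest.approx(expected, rel=1e-4)

    def test_diffusive_supply_balances_uptake(self):
        case = zs.stagnant_mm_case(0.21, 5e-3, 3e-9, 3e-8, 5e-3)
        mesh = case.mesh(2)
        flow = zs.solve_flow(case.config, mesh)
        conc = zs.solve_oxygen(case.config, mesh, flow)
        budget = zs.transport_budget(conc, flow)
        assert budget["advective_in"] == 0.0
        assert budget["diffusive_in"] == pytest.approx(budget["uptake"], rel=1e-3)
        assert math.isinf(zs.oxygen_mass_balance(conc, flow, case.config))


class TestChamberTransport:
    def test_maximum_principle(self, chamber):
        for h in (0.0, 7e-3):
            cfg, mesh, _, conc = chamber(h)
            vals = conc.c[mesh.fluid]
            assert vals.min() >= -1e-8
            assert vals.max() <= cfg.inlet_oxygen + 1e-8
            assert np.all(conc.surface_c >= 0)

    def test_mass_balance_within_one_percent(self, chamber):
        for h in (0.0, 7e-3):
            cfg, _, flow, conc = chamber(h)
            assert zs.oxygen_mass_balance(conc, flow, cfg) <= 1e-2

    def test_mean_oxygen_decreases_with_uptake_capacity(self):
        means = []
        for vmax in (0.5e-17, 1.25e-17, 3e-17):
            cfg = zs.build_geometry(vmax_per_cell=vmax)
            mesh = zs.build_mesh(cfg, 1)
            flow = zs.solve_flow(cfg, mesh)
            conc = zs.solve_oxygen(cfg, mesh, flow)
            means.append(zs.surface_oxygen_profile(conc, cfg).mean())
        assert means[0] > means[1] > means[2]

    def test_mean_oxygen_increases_with_insert_height(self, design_sweep):
        means = [s.mean_surface_oxygen for s in design_sweep.summaries]
        assert np.all(np.diff(means) > 0)

    def test_perivenous_profile_below_periportal_everywhere(self, chamber):
        cfg0, _, _, conc0 = chamber(0.0)
        cfg7, _, _, conc7 = chamber(7e-3)
        p0 = zs.surface_oxygen_profile(conc0, cfg0)
        p7 = zs.surface_oxygen_profile(conc7, cfg7)
        lo = np.interp(p7.positions, p0.positions, p0.values)
        assert np.all(lo < p7.values)

    def test_zero_inlet_oxygen_gives_zero_field(self):
        cfg = zs.build_geometry(inlet_oxygen=0.0)
        mesh = zs.build_mesh(cfg, 0)
        flow = zs.solve_flow(cfg, mesh)
        conc = zs.solve_oxygen(cfg, mesh, flow)
        assert np.allclose(conc.c, 0.0, atol=1e-12)
        assert np.allclose(conc.surface_c, 0.0, atol=1e-12)


class TestStatistics:
    def test_constant_profile(self):
        p = SurfaceProfile(np.linspace(0, 1e-2, 5), np.full(5, 0.21), "oxygen", "mol/m^3")
        assert zs.surface_stats(p) == (pytest.approx(0.21), pytest.approx(0.21))

    def test_single_dip_sets_minimum_below_mean(self):
        values = np.full(21, 0.2)
        values[10] = 0.05
        p = SurfaceProfile(np.linspace(0, 1e-2, 21), values, "oxygen", "mol/m^3")
        mean, mn = zs.surface_stats(p)
        assert mn == pytest.approx(0.05)
        assert mean > mn

    def test_empty_profile_is_an_error(self):
        p = SurfaceProfile(np.array([]), np.array([]), "oxygen", "mol/m^3")
        with pytest.raises(ValueError):
            zs.surface_stats(p)

    def test_shear_profile_rejected(self):
        p = SurfaceProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]), "shear", "Pa")
        with pytest.raises(ValueError, match="oxygen"):
            zs.surface_stats(p)


class TestPercentConversion:
    @pytest.mark.parametrize("c, pct", [(0.15, 15.0), (0.06, 6.0), (0.0, 0.0), (0.21, 21.0)])
    def test_table_pairing_convention(self, c, pct):
        assert zs.conc_to_percent(c) == pytest.approx(pct, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            zs.conc_to_percent(-0.01)

    def test_array_input(self):
        out = zs.conc_to_percent(np.array([0.06, 0.12, 0.15]))
        assert np.allclose(out, [6.0, 12.0, 15.0])
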