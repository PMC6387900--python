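"""Zonation design: pipeline runs, sweep mechanics, zone report."""

import dataclasses
import json

import numpy as np
import pytest

import zonesim as zs
from zonesim.zonation import report_from_json, report_to_json

# shallow chamber: fast level-0/1 runs for sweep mechanics
SHALLOW = dict(chamber_depth=10e-3, port_center_height=8e-3)


class TestRunConfiguration:
    def test_populates_every_field_consistently(self):
        cfg = zs.build_geometry(insert_height=3e-3, **SHALLOW)
        s = zs.run_configuration(cfg, refinement_level=0)
        assert s.insert_height == 3e-3
        assert s.zone == "unassigned"
        assert s.min_surface_oxygen <= s.mean_surface_oxygen
        assert s.mean_surface_shear > 0
        # percent fields follow the conversion convention exactly
        assert s.mean_surface_oxygen_pct == 100.0 * s.mean_surface_oxygen
        assert s.min_surface_oxygen_pct == 100.0 * s.min_surface_oxygen

    def test_zero_uptake_reports_inlet_percentage(self):
        cfg = zs.build_geometry(insert_height=3e-3, vmax_per_cell=0.0, **SHALLOW)
        s = zs.run_configuration(cfg, refinement_level=0)
        assert s.mean_surface_oxygen_pct == pytest.approx(21.0, rel=1e-9)
        assert s.min_surface_oxygen_pct == pytest.approx(s.mean_surface_oxygen_pct, rel=1e-9)

    def test_deterministic_rerun_is_bit_identical(self):
        cfg = zs.build_geometry(insert_height=2e-3, **SHALLOW)
        a = zs.run_configuration(cfg, refinement_level=0)
        b = zs.run_configuration(cfg, refinement_level=0)
        assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_solver_errors_carry_the_configuration(self):
        cfg = zs.build_geometry(insert_height=3e-3, max_iterations=1, **SHALLOW)
        with pytest.raises(zs.OxygenSolverError, match="insert_height=0.003"):
            zs.run_configuration(cfg, refinement_level=0)


class TestHeightSweep:
    def test_target_met_at_base_stops_immediately(self):
        cfg = zs.build_geometry(vmax_per_cell=0.0, **SHALLOW)
        sweep = zs.height_sweep(cfg, target_pct=15.0, refinement_level=0)
        assert sweep.stop_height == 0.0
        assert len(sweep.summaries) == 1

    def test_unreachable_target_warns_and_reports_all_heights(self):
        cfg = zs.build_geometry(vmax_per_cell=0.0, **SHALLOW)
        with pytest.warns(zs.SweepWarning, match="not reached"):
            sweep = zs.height_sweep(cfg, target_pct=99.0, refinement_level=0)
        assert sweep.stop_height is None
        # heights 0..9 mm all evaluated inside the 10 mm chamber (1 mm clearance)
        assert sweep.heights == pytest.approx([i * 1e-3 for i in range(10)])

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            zs.height_sweep(zs.build_geometry(), target_pct=-5.0)
        with pytest.raises(ValueError):
            zs.height_sweep(zs.build_geometry(), step=0.0)

    def test_design_sweep_stops_at_periportal_height(self, design_sweep):
        assert design_sweep.stop_height == pytest.approx(7e-3)
        assert design_sweep.heights == pytest.approx([i * 1e-3 for i in range(8)])


class TestSelectZones:
    def test_three_zone_design_labels(self, design_sweep):
        zones = zs.select_zones(design_sweep, central_height=4e-3)
        assert zones["perivenous"].insert_height == 0.0
        assert zones["central"].insert_height == pytest.approx(4e-3)
        assert zones["periportal"].insert_height == pytest.approx(7e-3)
        assert all(z.zone == name for name, z in zones.items())

    def test_missing_central_height_is_an_error(self, design_sweep):
        with pytest.raises(ValueError, match="central"):
            zs.select_zones(design_sweep, central_height=3.5e-3)

    def test_central_equal_to_stop_is_an_error(self, design_sweep):
        with pytest.raises(ValueError, match="distinct"):
            zs.select_zones(design_sweep, central_height=design_sweep.stop_height)

    def test_incomplete_sweep_is_an_error(self):
        sweep = zs.SweepResult(summaries=[], target_pct=15.0, stop_height=None)
        with pytest.raises(ValueError):
            zs.select_zones(sweep)


class TestReport:
    def _zones(self):
        mk = lambda h, c, s, name: zs.ZoneSummary(
            insert_height=h,
            mean_surface_oxygen=c,
            mean_surface_oxygen_pct=100 * c,
            min_surface_oxygen=0.8 * c,
            min_surface_oxygen_pct=80 * c,
            mean_surface_shear=s,
            zone=name,
        )
        return {
            "perivenous": mk(0.0, 0.0612345678901234, 2.5e-8, "perivenous"),
            "central": mk(4e-3, 0.12, 4.3e-7, "central"),
            "periportal": mk(7e-3, 0.15, 1.7e-6, "periportal"),
        }

    def test_rows_ordered_periportal_central_perivenous(self):
        table = zs.table1_report(self._zones())
        assert list(table["zone"]) == ["periportal", "central", "perivenous"]

    def test_percent_column_matches_conversion_exactly(self):
        table = zs.table1_report(self._zones())
        assert (table["mean_O2_pct"] == 100.0 * table["mean_O2_mol_m3"]).all()

    def test_json_round_trip_is_bit_exact(self, tmp_path):
        table = zs.table1_report(self._zones())
        path = tmp_path / "zones.json"
        report_to_json(table, path)
        back = report_from_json(path)
        for col in table.columns:
            if table[col].dtype == float:
                assert (back[col] == table[col]).all()

    def test_missing_zone_rejected(self):
        zones = self._zones()
        del zones["central"]
        with pytest.raises(ValueError):
            zs.table1_report(zones)


def test_cli_verify_and_run(tmp_path):
    """The shell entry points drive the library and exit cleanly."""
    from click.testing import CliRunner

    from zonesim.cli import main

    runner = CliRunner()
    out = tmp_path / "out"
    res = runner.invoke(
        main, ["run", "--height", "3", "--level", "0", "--out", str(out)]
    )
    assert res.exit_code == 0, res.output
    assert (out / "zone_summary.json").exists()
    summary = json.loads((out / "zone_summary.json").read_text())
    assert 0 < summary["mean_surface_oxygen_pct"] < 21
    assert (out / "oxygen_profile.csv").exists()
    assert (out / "fields.vtk").exists()


def test_cli_report_rebuilds_zone_table(tmp_path):
    from click.testing import CliRunner

    from zonesim.cli import main

    payload = {
        "target_pct": 15.0,
        "stop_height_m": 7e-3,
        "summaries": [
            {
                "insert_height": h,
                "mean_surface_oxygen": c,
                "mean_surface_oxygen_pct": 100 * c,
                "min_surface_oxygen": 0.8 * c,
                "min_surface_oxygen_pct": 80 * c,
                "mean_surface_shear": s,
                "zone": "unassigned",
            }
            for h, c, s in [(0.0, 0.065, 1.2e-7), (4e-3, 0.127, 1.9e-6), (7e-3, 0.151, 5.7e-6)]
        ],
    }
    sweep_json = tmp_path / "sweep.json"
    sweep_json.write_text(json.dumps(payload))
    runner = CliRunner()
    res = runner.invoke(main, ["report", "--sweep-json", str(sweep_json), "--out", str(tmp_path)])
    assert res.exit_code == 0, res.output
    assert "periportal" in res.output
    assert (tmp_path / "zones.csv").exists()
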