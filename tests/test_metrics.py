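"""Separation metrics, throughput, sweep and grid convergence."""

import pandas as pd
import pytest

from depsep import RunConfig
from depsep.metrics import (
    ConvergenceReport,
    SweepConfig,
    grid_convergence,
    outlet_purity,
    separation_efficiency,
    species_wall_gaps,
    throughput,
)


def table(rows):
    return pd.DataFrame(rows, columns=["id", "species", "outlet"])


class TestEfficiency:
    def test_direct_counts(self):
        rows = [(i, "WBC", "outlet_WBC") for i in range(3)] + [(3, "WBC", "lost")]
        eff = separation_efficiency(table(rows))
        assert eff["WBC"] == pytest.approx(75.0)

    def test_perfect_run_is_100(self):
        rows = [(i, "WBC", "outlet_WBC") for i in range(20)]
        assert separation_efficiency(table(rows))["WBC"] == 100.0

    def test_uninjected_species_absent_not_zero(self, caplog):
        rows = [(0, "WBC", "outlet_WBC")]
        eff = separation_efficiency(table(rows))
        assert "CTC" not in eff
        assert "PLT" not in eff

    def test_permutation_invariant(self):
        rows = [(0, "CTC", "outlet_CTC"), (1, "CTC", "lost"), (2, "CTC", "outlet_CTC")]
        a = separation_efficiency(table(rows))
        b = separation_efficiency(table(rows[::-1]))
        assert a == b


class TestPurity:
    def test_direct_counts(self):
        rows = [
            (0, "CTC", "outlet_CTC"), (1, "CTC", "outlet_CTC"),
            (2, "PLT", "outlet_CTC"), (3, "WBC", "outlet_CTC"),
        ]
        pur = outlet_purity(table(rows))
        assert pur["outlet_CTC"] == pytest.approx(50.0)

    def test_empty_outlet_absent(self):
        rows = [(0, "CTC", "outlet_CTC")]
        pur = outlet_purity(table(rows))
        assert "outlet_WBC" not in pur

    def test_lost_particles_excluded_from_purity(self):
        rows = [(0, "CTC", "outlet_CTC"), (1, "WBC", "lost")]
        pur = outlet_purity(table(rows))
        assert pur["outlet_CTC"] == 100.0


class TestCompleteSeparation:
    def test_iff_perfect_partition(self, optimum_fine):
        rep = optimum_fine.report
        assert rep.complete_separation
        assert rep.min_efficiency() == 100.0
        assert rep.min_purity() == 100.0
        assert rep.lost == 0


class TestThroughput:
    def test_mass_balance_oracle(self, optimum_fine):
        """Outlet throughputs sum to (v_blood + v_buffer) * CW * CD."""
        r = optimum_fine
        total = sum(
            throughput(r.flow, r.geometry, t)
            for t in ("outlet_PLT", "outlet_CTC", "outlet_WBC")
        )
        nominal = (134.0 + 850.0) * 40.0 * 100.0  # um^3/s
        assert total == pytest.approx(nominal, rel=1e-3)

    def test_unknown_tag_rejected(self, optimum_fine):
        with pytest.raises(KeyError):
            throughput(optimum_fine.flow, optimum_fine.geometry, "outlet_X")

    def test_scales_linearly_with_inlet_speeds(self, optimum_fine, run_cache):
        """Stokes linearity: halving both inlet speeds halves each outlet
        throughput."""
        half = run_cache.get(
            "half_speed_coarse",
            RunConfig.for_design(mesh_level="coarse", n_per_species=1,
                                 v_blood=67.0, v_buffer=425.0),
        )
        full = run_cache.get(
            "full_speed_coarse",
            RunConfig.for_design(mesh_level="coarse", n_per_species=1),
        )
        for tag in ("outlet_PLT", "outlet_CTC", "outlet_WBC"):
            a = throughput(full.flow, full.geometry, tag)
            b = throughput(half.flow, half.geometry, tag)
            assert b == pytest.approx(0.5 * a, rel=1e-8)


class TestSweep:
    def test_single_entry_sweep_matches_direct_run(self, run_cache):
        from depsep.metrics import run_sweep

        cfg = SweepConfig(
            channel_widths=(40.0,), voltages=(2.0,), electrode_counts=(4,),
            buffer_velocities=(850.0,), cell_velocities=(134.0,),
            mesh_level="coarse", n_per_species=4,
        )
        reports, summary = run_sweep(cfg)
        assert len(summary) == 1
        direct = run_cache.get(
            "tol_a", RunConfig.for_design(mesh_level="coarse", n_per_species=4)
        )
        (key,) = reports
        assert reports[key].efficiency == direct.report.efficiency
        assert bool(summary["complete_separation"].iloc[0]) == (
            direct.report.complete_separation
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            SweepConfig(voltages=())

    def test_combination_grid_size(self):
        cfg = SweepConfig()
        assert len(list(cfg.combinations())) == 15  # 3 widths x 5 voltages


class TestConvergenceReport:
    def test_identical_level_zero_error(self, optimum_normal):
        rc = optimum_normal.config
        rep = grid_convergence(
            rc, levels=("normal", "fine"),
            _results={"normal": optimum_normal, "fine": optimum_normal},
        )
        assert rep.max_error_finest_pair == 0.0
        assert rep.passed

    def test_report_dict_shape(self, optimum_normal):
        rep = ConvergenceReport(
            speeds={"normal": {"CTC": 1.0}}, errors={"normal/fine": {"CTC": 0.5}}
        )
        d = rep.to_dict()
        assert d["passed"]
        assert d["criterion_pct"] == 1.0


class TestGapDiagnostics:
    def test_gap_ordering_matches_force_ordering(self, optimum_normal):
        """WBC ride furthest from the electrode wall, PLT nearest."""
        gaps = species_wall_gaps(
            optimum_normal.trajectories, optimum_normal.geometry
        )
        assert gaps["WBC"] > gaps["CTC"] > gaps["PLT"]
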