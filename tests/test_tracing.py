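"""Particle tracing: streamline oracle, convergence, outlet assignment."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from depsep import RunConfig, run_pipeline
from depsep.tracing import (
    TracerConfigError,
    TracerSettings,
    Trajectory,
    advance_particles,
    assign_outlets,
)


def integrate_streamline(flow, start, t_end=8.0):
    """Independent streamline integration of the fluid velocity alone."""

    def rhs(t, y):
        u = flow.velocity(y[None, :], clamp=True)[0]
        return u * 1e6  # um/s

    sol = solve_ivp(
        rhs, (0.0, t_end), np.asarray(start, dtype=float),
        rtol=1e-9, atol=1e-6, max_step=5e-3, dense_output=True,
    )
    return sol


class TestStreamlineOracle:
    def test_zero_voltage_matches_streamlines(self, zero_field_coarse):
        """With the drive off, every trajectory follows the streamline
        through its release point to within 0.1 um laterally."""
        r = zero_field_coarse
        checked = 0
        for tr in r.trajectories[::5]:
            sol = integrate_streamline(r.flow, tr.positions[0])
            # compare lateral position at matching x stations mid-channel
            sx, sy = sol.y[0], sol.y[1]
            for xq in (300.0, 500.0, 620.0):
                if tr.positions[:, 0].max() < xq or sx.max() < xq:
                    continue
                y_tr = np.interp(xq, tr.positions[:, 0], tr.positions[:, 1])
                y_or = np.interp(xq, sx, sy)
                assert abs(y_tr - y_or) < 0.1
                checked += 1
        assert checked >= 6

    def test_zero_voltage_all_exit_upper_outlet(self, zero_field_coarse):
        """Without DEP the focused sample stream stays on the electrode
        side and every cell washes out of the PLT (upper) outlet."""
        asg = zero_field_coarse.assignment
        assert (asg["outlet"] == "outlet_PLT").all()


class TestConvergence:
    def test_tolerance_refinement_stable_exits(self):
        """Tightening the integrator tolerance by 10x moves exit points by
        less than 0.1 um (ODE convergence)."""
        cfg = RunConfig.for_design(mesh_level="coarse", n_per_species=4)
        ra = run_pipeline(
            replace(cfg, tracer=TracerSettings(rel_tol=1e-8)), persist=False
        )
        rb = run_pipeline(
            replace(cfg, tracer=TracerSettings(rel_tol=1e-9)), persist=False
        )
        for ta, tb in zip(ra.trajectories, rb.trajectories):
            assert ta.status == tb.status
            if ta.exit_position is not None:
                assert np.linalg.norm(ta.exit_position - tb.exit_position) < 0.1


class TestTrajectoriesWellFormed:
    def test_times_strictly_increasing(self, optimum_normal):
        for tr in optimum_normal.trajectories:
            assert np.all(np.diff(tr.times) > 0)

    def test_positions_inside_until_exit(self, optimum_normal):
        g = optimum_normal.geometry
        import shapely

        for tr in optimum_normal.trajectories[::6]:
            interior = tr.positions[:-1]
            ok = shapely.dwithin(
                shapely.points(interior), g.polygon, 1e-6
            )
            assert np.all(ok)

    def test_mismatched_meshes_rejected(self, optimum_coarse, optimum_normal, catalog):
        with pytest.raises(TracerConfigError):
            advance_particles(
                optimum_coarse.flow,
                optimum_normal.potential,
                optimum_coarse.ensemble,
                catalog,
                optimum_coarse.config.medium,
                optimum_coarse.config.drive,
                TracerSettings(),
                geometry=optimum_coarse.geometry,
            )


class TestInertialMode:
    def test_inertial_matches_overdamped(self, run_cache):
        """The Stokes relaxation time is ~1e-5 s, so inertial and
        overdamped dynamics give the same outlet assignment."""
        over = run_cache.get("tol_a", RunConfig.for_design(mesh_level="coarse", n_per_species=4))
        cfg = replace(
            RunConfig.for_design(mesh_level="coarse", n_per_species=4),
            tracer=TracerSettings(dynamics="inertial"),
        )
        inert = run_pipeline(cfg, persist=False)
        assert list(over.assignment["outlet"]) == list(inert.assignment["outlet"])


class TestAssignOutlets:
    def _traj(self, pid, species, status):
        t = np.array([0.0, 1.0])
        pos = np.zeros((2, 2))
        return Trajectory(
            particle_id=pid, species=species, times=t, positions=pos,
            speeds=np.zeros(2), dep_force_mag=np.zeros(2), status=status,
        )

    def test_mapping(self, default_geometry):
        trs = [
            self._traj(0, "WBC", "exited:outlet_WBC"),
            self._traj(1, "CTC", "frozen_at_wall"),
            self._traj(2, "PLT", "unresolved_at_t_end"),
            self._traj(3, "CTC", "exited:blood_inlet"),
        ]
        table = assign_outlets(trs, default_geometry)
        assert list(table["outlet"]) == ["outlet_WBC", "lost", "lost", "lost"]

    def test_proposed_design_routing(self, optimum_fine):
        """PLT exit the upper outlet (nearest the electrodes), WBC the
        lower outlet (deflected furthest), CTC the middle outlet."""
        asg = optimum_fine.assignment
        for species, outlet in (
            ("PLT", "outlet_PLT"), ("CTC", "outlet_CTC"), ("WBC", "outlet_WBC")
        ):
            sub = asg[asg["species"] == species]
            assert (sub["outlet"] == outlet).all()
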