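"""Creeping-flow solver: analytic oracles and conservation properties."""

import numpy as np
import pytest

from depsep.fem import OutOfDomainError
from depsep.meshing import mesh_rectangle
from depsep.stokes import FlowBC, MediumProps, sample_flow, solve_stokes


class TestPoiseuilleOracle:
    def test_profile_matches_closed_form(self, channel_flow):
        """Fully developed plane Poiseuille: u(y) = 1.5 v (1 - (2y/H - 1)^2)."""
        ys = np.linspace(0.5, 39.5, 25)
        pts = np.column_stack([np.full_like(ys, 120.0), ys])
        u = channel_flow.velocity(pts)
        exact = 1.5 * 100e-6 * (1.0 - (2.0 * ys / 40.0 - 1.0) ** 2)
        assert np.max(np.abs(u[:, 0] - exact)) < 0.01 * exact.max()
        assert np.max(np.abs(u[:, 1])) < 1e-3 * exact.max()

    def test_pressure_gradient_matches_closed_form(self, channel_flow):
        """dp/dx = -12 mu v / H^2 for the same channel."""
        p0 = channel_flow.pressure(np.array([[20.0, 20.0]]))[0]
        p1 = channel_flow.pressure(np.array([[180.0, 20.0]]))[0]
        dpdx = (p1 - p0) / (160e-6)
        exact = -12.0 * 1e-3 * 100e-6 / (40e-6) ** 2
        assert dpdx == pytest.approx(exact, rel=0.01)

    def test_plug_inlet_develops_to_poiseuille(self):
        mesh = mesh_rectangle(
            200.0, 40.0, 2.0,
            tags={"left": "blood_inlet", "right": "outlet_main",
                  "top": "wall", "bottom": "wall"},
        )
        flow = solve_stokes(mesh, FlowBC(v_blood=100.0, v_buffer=0.0), MediumProps())
        u_mid = flow.velocity(np.array([[180.0, 20.0]]))[0, 0]
        assert u_mid == pytest.approx(1.5 * 100e-6, rel=0.01)


class TestDegenerate:
    def test_zero_inlets_give_zero_fields(self):
        mesh = mesh_rectangle(
            80.0, 40.0, 4.0,
            tags={"left": "blood_inlet", "right": "outlet_main",
                  "top": "wall", "bottom": "wall"},
        )
        flow = solve_stokes(mesh, FlowBC(v_blood=0.0, v_buffer=0.0), MediumProps())
        assert np.abs(flow.ux).max() == 0.0
        assert np.abs(flow.uy).max() == 0.0
        assert np.abs(flow.p).max() == 0.0


class TestLinearity:
    def test_scaling_inlet_speeds_scales_solution(self, default_geometry, coarse_mesh):
        f1 = solve_stokes(coarse_mesh, FlowBC(v_blood=134.0, v_buffer=850.0), MediumProps())
        f2 = solve_stokes(coarse_mesh, FlowBC(v_blood=268.0, v_buffer=1700.0), MediumProps())
        scale = np.abs(f1.ux).max()
        assert np.max(np.abs(f2.ux - 2.0 * f1.ux)) < 1e-8 * scale
        assert np.max(np.abs(f2.uy - 2.0 * f1.uy)) < 1e-8 * scale
        assert np.max(np.abs(f2.p - 2.0 * f1.p)) < 1e-8 * np.abs(f1.p).max()


class TestConservation:
    def test_mass_balance_on_device(self, optimum_fine):
        """Sum of outlet fluxes equals the imposed inlet flux to 0.1%."""
        flow = optimum_fine.flow
        inflow = -(flow.boundary_flux("blood_inlet") + flow.boundary_flux("buffer_inlet"))
        outflow = sum(
            flow.boundary_flux(t) for t in ("outlet_PLT", "outlet_CTC", "outlet_WBC")
        )
        nominal = (134.0 + 850.0) * 1e-6 * 40e-6
        assert inflow == pytest.approx(nominal, rel=1e-6)
        assert outflow == pytest.approx(inflow, rel=1e-3)

    def test_weak_divergence_small(self, optimum_normal):
        flow = optimum_normal.flow
        # characteristic velocity gradient u/CW
        scale = np.abs(flow.ux).max() / 40e-6
        assert flow.divergence_norm() < 0.05 * scale

    def test_outlet_pressure_zero(self, optimum_fine):
        """Static 0 Pa outlet condition: pressure vanishes at outlet faces."""
        flow = optimum_fine.flow
        g = optimum_fine.geometry
        p_inlet = flow.pressure(np.array([g.junctions["inlet"]]))[0]
        for tag in ("outlet_PLT", "outlet_CTC", "outlet_WBC"):
            seg = g.named_segment(tag)
            mid = 0.5 * (np.asarray(seg.p0) + np.asarray(seg.p1))
            inward = -np.asarray(g.port_directions[tag])
            pt = mid + 0.5 * inward
            assert abs(flow.pressure(np.array([pt]))[0]) < 5e-3 * abs(p_inlet)


class TestSampling:
    def test_wall_point_has_zero_velocity(self, optimum_coarse):
        mesh = optimum_coarse.mesh
        flow = optimum_coarse.flow
        wall_nodes = mesh.boundary_nodes(["wall"])
        pt = mesh.points[wall_nodes[5]]
        u = flow.velocity(np.array([pt]))[0]
        assert np.linalg.norm(u) < 1e-15

    def test_nodal_interpolation_identity(self, channel_flow):
        mesh = channel_flow.mesh
        k = mesh.n_points // 2
        u = channel_flow.velocity(np.array([mesh.points[k]]))[0]
        assert u[0] == pytest.approx(channel_flow.ux[k], abs=1e-18)

    def test_outside_point_raises(self, channel_flow):
        with pytest.raises(OutOfDomainError):
            sample_flow(channel_flow, (-5.0, 20.0))


class TestFocusing:
    def test_higher_buffer_raises_inlet_pressure(self, coarse_mesh):
        """With equal cell inflow, the faster buffer configuration carries
        the higher inlet-region pressure."""
        lo = solve_stokes(coarse_mesh, FlowBC(v_blood=134.0, v_buffer=850.0), MediumProps())
        hi = solve_stokes(coarse_mesh, FlowBC(v_blood=134.0, v_buffer=1350.0), MediumProps())
        assert hi.p.max() > lo.p.max()

    def test_interface_above_midline(self, optimum_normal):
        """v_buffer > v_blood pushes the stream interface to the electrode
        side of the main channel: most of the flux is buffer."""
        r = optimum_normal
        y_mid = r.geometry.junctions["split1"][1]
        x_mid = 0.5 * (r.geometry.junctions["inlet"][0] + r.geometry.junctions["split1"][0])
        # flux below the midline exceeds flux above it
        ys_lo = np.linspace(y_mid - 19.9, y_mid, 50)
        ys_hi = np.linspace(y_mid, y_mid + 19.9, 50)
        u_lo = r.flow.velocity(np.column_stack([np.full_like(ys_lo, x_mid), ys_lo]))[:, 0]
        u_hi = r.flow.velocity(np.column_stack([np.full_like(ys_hi, x_mid), ys_hi]))[:, 0]
        assert np.trapezoid(u_lo, ys_lo) > np.trapezoid(u_hi, ys_hi)
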