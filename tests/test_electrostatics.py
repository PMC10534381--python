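"""Potential solver and DEP-drive reconstruction."""

import numpy as np
import pytest

from depsep.electrostatics import (
    ConfigurationError,
    ElectrodeDrive,
    PotentialSolution,
    solve_potential,
)
from depsep.fem import P2Space
from depsep.meshing import mesh_rectangle
from depsep.stokes import UM, MediumProps


@pytest.fixture(scope="module")
def plate_mesh():
    return mesh_rectangle(
        100.0, 50.0, 2.0,
        tags={"left": "electrode_1", "right": "electrode_2",
              "top": "wall", "bottom": "wall"},
    )


class TestDrive:
    def test_alternating_pattern_default(self):
        d = ElectrodeDrive(amplitude=2.0, n_electrodes=4)
        assert d.pattern == (1, -1, 1, -1)
        assert d.voltages() == [2.0, -2.0, 2.0, -2.0]

    def test_pattern_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            ElectrodeDrive(amplitude=2.0, n_electrodes=4, pattern=(1, -1))

    def test_single_electrode_mesh_rejected(self):
        m = mesh_rectangle(10.0, 10.0, 5.0, tags={"left": "electrode_1"})
        with pytest.raises(ConfigurationError):
            solve_potential(m, ElectrodeDrive(n_electrodes=1, pattern=(1,)),
                            MediumProps())


class TestParallelPlate:
    def test_uniform_field_closed_form(self, plate_mesh):
        """Opposite plates at +-Va: |E| = 2 Va / gap, uniform to 0.5%."""
        sol = solve_potential(plate_mesh, ElectrodeDrive(amplitude=2.0, n_electrodes=2),
                              MediumProps())
        E = sol.field_at_centroids()
        Em = np.linalg.norm(E, axis=1)
        exact = 2.0 * 2.0 / 100e-6
        assert np.max(np.abs(Em - exact)) < 0.005 * exact

    def test_uniform_field_has_zero_drive(self, plate_mesh):
        sol = solve_potential(plate_mesh, ElectrodeDrive(amplitude=2.0, n_electrodes=2),
                              MediumProps())
        g = sol.dep_drive(np.array([[50.0, 25.0], [30.0, 10.0]]))
        scale = (2.0 * 2.0 / 100e-6) ** 2 / 100e-6
        assert np.max(np.abs(g)) < 1e-6 * scale

    def test_constant_dirichlet_data(self, plate_mesh):
        """All electrodes at +Va: V is constant, E vanishes."""
        sol = solve_potential(
            plate_mesh,
            ElectrodeDrive(amplitude=2.0, n_electrodes=2, pattern=(1, 1)),
            MediumProps(),
        )
        assert np.allclose(sol.V, 2.0, atol=1e-10)
        assert np.max(np.abs(sol.field_at_centroids())) < 1e-6

    def test_current_density_is_sigma_e(self, plate_mesh):
        m = MediumProps(electrical_conductivity=0.2)
        sol = solve_potential(plate_mesh, ElectrodeDrive(amplitude=1.0, n_electrodes=2), m)
        J = sol.current_density_at_centroids()
        E = sol.field_at_centroids()
        assert np.allclose(J, 0.2 * E)


class TestManufactured:
    def test_quadratic_potential_drive_oracle(self, plate_mesh):
        """V = x^2 + y^2 (SI) imposed exactly: grad|E|^2 = 8 (x, y)."""
        space = P2Space(plate_mesh, scale=UM)
        V = space.interpolate(lambda x, y: x * x + y * y)
        sol = PotentialSolution(
            mesh=plate_mesh, space=space, V=V,
            drive=ElectrodeDrive(n_electrodes=2), medium=MediumProps(),
        )
        pts = np.array([[50.0, 25.0], [30.0, 20.0], [70.0, 30.0]])
        got = sol.dep_drive(pts)
        exact = 8.0 * pts * UM
        err = np.linalg.norm(got - exact, axis=1) / np.linalg.norm(exact, axis=1)
        assert err.max() < 0.01


class TestInvariantsOnDevice:
    def test_maximum_principle(self, optimum_fine):
        sol = optimum_fine.potential
        va = sol.drive.amplitude
        assert sol.V.min() >= -va * (1 + 1e-9) - 1e-12
        assert sol.V.max() <= va * (1 + 1e-9) + 1e-12

    def test_polarity_flip_negates_potential_keeps_drive(self, coarse_mesh):
        m = MediumProps()
        a = solve_potential(coarse_mesh, ElectrodeDrive(amplitude=2.0, n_electrodes=4), m)
        b = solve_potential(
            coarse_mesh,
            ElectrodeDrive(amplitude=2.0, n_electrodes=4, pattern=(-1, 1, -1, 1)),
            m,
        )
        assert np.allclose(b.V, -a.V, atol=1e-10)
        assert np.allclose(b.dep_drive_nodal, a.dep_drive_nodal, rtol=1e-8, atol=1e-6)

    def test_drive_scales_with_voltage_squared(self, coarse_mesh):
        """V is linear in Va, so doubling Va multiplies grad|E|^2 by 4."""
        m = MediumProps()
        a = solve_potential(coarse_mesh, ElectrodeDrive(amplitude=2.0, n_electrodes=4), m)
        b = solve_potential(coarse_mesh, ElectrodeDrive(amplitude=4.0, n_electrodes=4), m)
        scale = np.abs(a.dep_drive_nodal).max()
        assert np.max(np.abs(b.dep_drive_nodal - 4.0 * a.dep_drive_nodal)) < 1e-9 * scale

    def test_field_maxima_at_electrode_corners(self, optimum_fine):
        """The strongest |E| in the device sits at the electrode corners."""
        sol = optimum_fine.potential
        mesh = optimum_fine.mesh
        emag = sol.field_magnitude_nodal()
        corners = optimum_fine.geometry.electrode_corners()
        top = mesh.points[np.argmax(emag)]
        d = np.min(np.linalg.norm(corners - top, axis=1))
        assert d < 2.0  # um

    def test_drive_decays_away_from_electrodes(self, optimum_fine):
        """The DEP drive loses its potency away from the electrodes: 20 um
        below the electrode plane it is a small fraction of its value 1 um
        from a corner (the hot spots)."""
        sol = optimum_fine.potential
        g = optimum_fine.geometry
        corners = g.electrode_corners()
        y_face = corners[:, 1].min()
        hot = corners[np.isclose(corners[:, 1], y_face)][2]
        near = np.linalg.norm(sol.dep_drive(np.array([[hot[0], hot[1] - 1.0]]))[0])
        x_mid = corners[:, 0].mean()
        far = np.linalg.norm(sol.dep_drive(np.array([[x_mid, y_face - 20.0]]))[0])
        assert far < 0.05 * near
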