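"""Quasi-static electric potential, field and DEP drive (grad |E|^2).

The spatial problem is the Laplace/steady-current equation
div(sigma grad V) = 0 with Dirichlet amplitudes +-Va on the exposed
electrode faces and zero normal current elsewhere.  The AC frequency
enters only through the Clausius-Mossotti factor, not the field shape.

The DEP drive grad|E|^2 is reconstructed patch-wise: |E|^2 is evaluated
per element from the P2 potential gradient, recovered to vertices by
area-weighted averaging, differentiated element-wise and recovered to
vertices once more, yielding a continuous piecewise-linear vector field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from .fem import FieldSampler, P2Space
from .meshing import Mesh
from .stokes import MediumProps, SolverError, UM

__all__ = ["ElectrodeDrive", "PotentialSolution", "solve_potential", "dep_drive_field"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ElectrodeDrive:
    """Electrode excitation: amplitude (V), alternating polarity, frequency.

    ``frequency`` is the applied signal frequency in Hz; it is used only by
    the Clausius-Mossotti evaluation.  The default 96 kHz is the package's
    calibrated operating point (see docs/methods.md).
    """

    amplitude: float = 2.0
    n_electrodes: int = 4
    frequency: float = 96e3
    pattern: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.amplitude >= 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.frequency < 0:
            raise ConfigurationError("frequency must be >= 0")
        pattern = self.pattern
        if pattern is None:
            pattern = tuple((-1) ** i for i in range(self.n_electrodes))
            object.__setattr__(self, "pattern", pattern)
        if len(pattern) != self.n_electrodes:
            raise ConfigurationError(
                f"polarity pattern length {len(pattern)} != n_electrodes "
                f"{self.n_electrodes}"
            )
        if any(p not in (-1, 1) for p in pattern):
            raise ConfigurationError("polarity pattern entries must be +-1")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    def voltages(self) -> list[float]:
        return [p * self.amplitude for p in self.pattern]


@dataclass
class PotentialSolution:
    """Discrete potential with derived E, J and DEP-drive fields."""

    mesh: Mesh
    space: P2Space
    V: np.ndarray                  # P2 dofs, volts
    drive: ElectrodeDrive
    medium: MediumProps
    sampler: FieldSampler = field(default=None)
    _dep_drive_nodal: np.ndarray | None = None
    _e2_p2: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sampler is None:
            self.sampler = FieldSampler(self.mesh)

    def potential(self, pts_um, clamp: bool = False) -> np.ndarray:
        return self.sampler.eval_p2(self.space, self.V, pts_um, clamp=clamp)

    def field_at_centroids(self) -> np.ndarray:
        """E = -grad V per element (V/m)."""
        return -self.space.gradient_at_centroids(self.V)

    def current_density_at_centroids(self) -> np.ndarray:
        """J = sigma E per element (A/m2)."""
        return self.medium.electrical_conductivity * self.field_at_centroids()

    def _recover_to_vertices(self, elem_vals: np.ndarray) -> np.ndarray:
        """Area-weighted average of element values onto vertices."""
        nv = self.mesh.n_points
        a = self.space.area
        shape = (nv,) + np.shape(elem_vals)[1:]
        num = np.zeros(shape)
        den = np.zeros(nv)
        for k in range(3):
            idx = self.mesh.triangles[:, k]
            np.add.at(num, idx, (a[:, None] * elem_vals) if elem_vals.ndim > 1
                      else a * elem_vals)
            np.add.at(den, idx, a)
        return num / (den[:, None] if elem_vals.ndim > 1 else den)

    @property
    def dep_drive_nodal(self) -> np.ndarray:
        """grad|E|^2 recovered at mesh vertices (V^2/m^3).

        |E|^2 (piecewise quadratic, discontinuous) is L2-projected onto
        the continuous quadratic space, its element-wise gradient is then
        averaged onto vertices with area weights, giving a continuous
        piecewise-linear drive field.
        """
        if self._dep_drive_nodal is None:
            cent = np.full((1, 3), 1.0 / 3.0)
            gb = self.space.gradient_at_bary(self.e2_projected, cent)[:, 0, :]
            self._dep_drive_nodal = self._recover_to_vertices(gb)
        return self._dep_drive_nodal

    @property
    def e2_projected(self) -> np.ndarray:
        """|E|^2 L2-projected onto the continuous quadratic space."""
        if self._e2_p2 is None:
            space = self.space

            def e2_at(lmb):
                g = space.gradient_at_bary(self.V, lmb)  # (t, q, 2)
                return np.sum(g * g, axis=2)

            self._e2_p2 = space.project(e2_at)
        return self._e2_p2

    def dep_drive(self, pts_um, clamp: bool = False) -> np.ndarray:
        """grad|E|^2 (V^2/m^3) at points given in um.

        Continuous piecewise-linear interpolation of the vertex-recovered
        gradient of the projected |E|^2 field; continuity keeps the
        particle integrator's adaptive steps well-behaved.
        """
        return self.sampler.eval_p1(self.dep_drive_nodal, pts_um, clamp=clamp)

    def field_magnitude_nodal(self) -> np.ndarray:
        E = self.field_at_centroids()
        return np.sqrt(self._recover_to_vertices(np.sum(E * E, axis=1)))


def solve_potential(
    mesh: Mesh, drive: ElectrodeDrive, medium: MediumProps
) -> PotentialSolution:
    """Solve the steady-current potential problem on a tagged mesh."""
    electrode_tags = [t for t in mesh.tag_names if t.startswith("electrode")]
    if len(electrode_tags) < 2:
        raise ConfigurationError(
            f"need at least 2 electrode-tagged boundaries, found {len(electrode_tags)}"
        )
    electrode_tags = sorted(electrode_tags, key=lambda t: int(t.split("_")[1]))
    if len(electrode_tags) != drive.n_electrodes:
        raise ConfigurationError(
            f"drive specifies {drive.n_electrodes} electrodes but the mesh "
            f"has {len(electrode_tags)}"
        )
    space = P2Space(mesh, scale=UM)
    # sigma is uniform: it scales J but drops out of the potential problem
    A = space.stiffness(coeff=1.0).tolil()

    V = np.zeros(space.n_dofs)
    fixed = []
    for tag, volt in zip(electrode_tags, drive.voltages()):
        dofs = space.boundary_dofs([tag])
        V[dofs] = volt
        fixed.append(dofs)
    fixed = np.unique(np.concatenate(fixed))

    A = A.tocsr()
    rhs = -A @ V
    keep = np.setdiff1d(np.arange(space.n_dofs), fixed)
    sol = spla.spsolve(A[keep][:, keep].tocsc(), rhs[keep])
    if not np.all(np.isfinite(sol)):
        raise SolverError("potential solve produced non-finite values")
    V[keep] = sol
    return PotentialSolution(mesh=mesh, space=space, V=V, drive=drive, medium=medium)


def dep_drive_field(sol: PotentialSolution):
    """Evaluation closure for grad|E|^2 at arbitrary interior points (um)."""
    return sol.dep_drive
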