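"""Lagrangian cell tracing through the solved flow and field.

Cells are point particles advected by the fluid and deflected by the
dielectrophoretic force.  The default dynamics is overdamped,

    dx/dt = u(x) + F_DEP(x) / (6 pi mu Rp),

because the Stokes relaxation time of a <= 15 um cell in an aqueous
buffer (~1e-5 s) is negligible against the transit time.  An inertial
mode integrating  m dv/dt = 6 pi mu Rp (u - v) + F_DEP  is retained for
sensitivity checks.

All particles are integrated as one adaptive Runge-Kutta system;
terminated particles (outlet exit, wall contact) are masked out.  Wall
contact is detected on the particle centre (within a small tolerance),
matching point-particle tracing; the finite radius enters only through
the force and drag laws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.integrate import RK45

from .dep import CellSpecies, dep_mobility
from .electrostatics import ElectrodeDrive, PotentialSolution
from .geometry import LOCGeometry
from .population import ParticleEnsemble
from .stokes import FlowField, MediumProps

__all__ = ["TracerSettings", "Trajectory", "advance_particles", "assign_outlets"]

UM_PER_M = 1e6

#: default cell mass density (kg/m3) for the inertial mode
CELL_DENSITY = 1050.0


class TracerConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TracerSettings:
    """Integration window, tolerance and dynamics mode."""

    t_end: float = 8.0
    rel_tol: float = 1e-7
    dynamics: str = "overdamped"
    wall_contact_tol: float = 0.1   # um, centre-to-wall freeze distance
    max_step: float = 0.01          # s

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ValueError("t_end must be > 0")
        if not 0 < self.rel_tol <= 1e-3:
            raise ValueError("rel_tol must be in (0, 1e-3]")
        if self.dynamics not in ("overdamped", "inertial"):
            raise ValueError(f"unknown dynamics mode {self.dynamics!r}")


@dataclass
class Trajectory:
    """Time-resolved path of one cell and its terminal status.

    ``status`` is 'exited:<outlet_tag>', 'frozen_at_wall' or
    'unresolved_at_t_end'.  ``times`` are strictly increasing; positions
    are um, speeds m/s, forces N.
    """

    particle_id: int
    species: str
    times: np.ndarray
    positions: np.ndarray      # (k, 2) um
    speeds: np.ndarray         # (k,) m/s, |u + u_DEP|
    dep_force_mag: np.ndarray  # (k,) N
    status: str = "unresolved_at_t_end"
    exit_time: float | None = None
    exit_position: np.ndarray | None = None
    exit_speed: float | None = None

    @property
    def exited(self) -> bool:
        return self.status.startswith("exited:")

    @property
    def outlet(self) -> str | None:
        return self.status.split(":", 1)[1] if self.exited else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.particle_id,
                "species": self.species,
                "t_s": self.times,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "speed_m_per_s": self.speeds,
                "F_dep_N": self.dep_force_mag,
            }
        )


def _port_faces(geometry: LOCGeometry) -> list[tuple[str, np.ndarray, np.ndarray]]:
    faces = []
    for tag in geometry.port_directions:
        seg = geometry.named_segment(tag)
        faces.append((tag, np.asarray(seg.p0), np.asarray(seg.p1)))
    return faces


def _segment_crossing(a, b, faces):
    """First port face crossed by the step segment a->b, with hit point."""
    step = shapely.linestrings([a, b])
    best = None
    for tag, p0, p1 in faces:
        face = shapely.linestrings([p0, p1])
        if shapely.intersects(step, face):
            hit = shapely.intersection(step, face)
            pt = np.asarray(shapely.get_coordinates(hit)[0])
            s = np.linalg.norm(pt - a)
            if best is None or s < best[2]:
                best = (tag, pt, s)
    if best is None:
        return None
    return best[0], best[1]


def advance_particles(
    flow: FlowField,
    potential: PotentialSolution | None,
    ensemble: ParticleEnsemble,
    cells: dict[str, CellSpecies],
    medium: MediumProps,
    drive: ElectrodeDrive | None,
    settings: TracerSettings,
    geometry: LOCGeometry | None = None,
) -> list[Trajectory]:
    """Integrate all cells simultaneously until exit, wall contact or t_end.

    ``potential``/``drive`` may be None for a pure-hydrodynamic
    (streamline) run.  ``geometry`` supplies the port faces used for exit
    detection; it is mandatory for device meshes.
    """
    mesh = flow.mesh
    if potential is not None and potential.mesh is not mesh:
        raise TracerConfigError(
            "flow and potential were solved on different meshes"
        )
    if geometry is None:
        raise TracerConfigError("geometry with tagged port faces is required")

    n = len(ensemble)
    omega = drive.omega if drive is not None else 0.0
    mob = np.zeros(n)        # m/s per (V^2/m^3)
    radii = np.zeros(n)      # m
    for i, s in enumerate(ensemble.species):
        cell = cells[s]
        radii[i] = cell.radius_m
        if potential is not None:
            mob[i] = dep_mobility(cell, medium, omega)
    # force prefactor per particle: F = pref * grad|E|^2
    pref = 6.0 * np.pi * medium.dynamic_viscosity * radii * mob

    faces = _port_faces(geometry)
    exterior = geometry.polygon.exterior
    sampler = flow.sampler

    # fused field evaluation: one point-location per RHS call serves both
    # the velocity (P2 values) and the continuous vertex-recovered DEP
    # drive (P1 values)
    from .fem import p2_values_at

    U = np.column_stack([flow.ux, flow.uy])
    G_nodal = potential.dep_drive_nodal if potential is not None else None
    tris = mesh.triangles

    def fields_at(pts):
        t, lmb, _ = sampler.locate_clamped(pts)
        u = p2_values_at(flow.space, U, t, lmb)
        if G_nodal is None:
            return u, np.zeros_like(u)
        g = np.einsum("nk,nkd->nd", lmb, G_nodal[tris[t]])
        return u, g

    active = np.ones(n, dtype=bool)
    final_recorded = np.zeros(n, dtype=bool)
    status = np.array(["unresolved_at_t_end"] * n, dtype=object)
    exit_time = np.full(n, np.nan)
    exit_pos = np.full((n, 2), np.nan)
    exit_speed = np.full(n, np.nan)

    inertial = settings.dynamics == "inertial"
    masses = CELL_DENSITY * 4.0 / 3.0 * np.pi * radii**3
    drag = 6.0 * np.pi * medium.dynamic_viscosity * radii

    def rhs(t, y):
        x = y.reshape(n, 2)
        u, g = fields_at(x)
        v = (u + mob[:, None] * g) * UM_PER_M  # um/s
        v[~active] = 0.0
        return v.ravel()

    x0 = ensemble.positions.copy()
    if inertial:
        u0 = flow.velocity(x0, clamp=True)
        y0 = np.concatenate([x0.ravel(), u0.ravel()])
    else:
        y0 = x0.ravel()

    # recorded series
    rec_t = [[0.0] for _ in range(n)]
    rec_x = [[x0[i].copy()] for i in range(n)]
    u_init, g_init = fields_at(x0)
    v_init = u_init + mob[:, None] * g_init
    rec_s = [[float(np.linalg.norm(v_init[i]))] for i in range(n)]
    rec_f = [[float(np.linalg.norm(pref[i] * g_init[i]))] for i in range(n)]

    # Overdamped dynamics is non-stiff: adaptive explicit Runge-Kutta.
    # The inertial system's velocity relaxation time m/(6 pi mu R)
    # (~1e-5 s) makes it brutally stiff for explicit steppers, so it uses
    # an exponential integrator instead: over each step the drag term is
    # integrated exactly with the fields frozen at the step start,
    #   v_inf = u + F/drag,  v <- v_inf + (v - v_inf) e^(-dt/tau),
    #   x <- x + v_inf dt + tau (v - v_inf)(1 - e^(-dt/tau)),
    # with the step length capped at ~1 um of travel.
    if inertial:
        tau = masses / drag  # s

        class _ExponentialStepper:
            status = "running"

            def __init__(self):
                self.t = 0.0
                self.y = y0.copy()

            def _drift(self, x):
                u, g = fields_at(x)
                return u + (pref[:, None] / drag[:, None]) * g  # m/s

            def step(self):
                x = self.y[: 2 * n].reshape(n, 2)
                v = self.y[2 * n:].reshape(n, 2)
                v_inf = self._drift(x)
                speed_um = np.linalg.norm(v_inf, axis=1).max() * UM_PER_M
                dt = min(
                    settings.max_step,
                    1.0 / max(speed_um, 1e-12),      # ~1 um of travel
                    settings.t_end - self.t,
                )
                # midpoint re-evaluation of the slow fields (2nd order)
                x_half = x + 0.5 * dt * v_inf * UM_PER_M
                v_inf = self._drift(x_half)
                e = np.exp(-dt / tau)[:, None]
                dx = (v_inf * dt + tau[:, None] * (v - v_inf) * (1.0 - e))
                x_new = x + np.where(active[:, None], dx * UM_PER_M, 0.0)
                v_new = np.where(active[:, None], v_inf + (v - v_inf) * e, v)
                self.y = np.concatenate([x_new.ravel(), v_new.ravel()])
                self.t += dt
                if self.t >= settings.t_end - 1e-15:
                    self.status = "finished"

        solver = _ExponentialStepper()
    else:
        solver = RK45(
            rhs, 0.0, y0, t_bound=settings.t_end, rtol=settings.rel_tol,
            atol=1e-5, max_step=settings.max_step,
        )
    x_prev = x0.copy()
    while solver.status == "running" and active.any():
        solver.step()
        t = solver.t
        if inertial:
            x_new = solver.y[: 2 * n].reshape(n, 2).copy()
        else:
            x_new = solver.y.reshape(n, 2).copy()

        moved = active.copy()
        inside = sampler.inside(x_new[moved])
        dist = shapely.distance(
            shapely.points(x_new[moved]), exterior
        )
        idx_moved = np.where(moved)[0]
        for k, i in enumerate(idx_moved):
            xi_prev, xi_new = x_prev[i], x_new[i]
            terminated = False
            if not inside[k]:
                hit = _segment_crossing(xi_prev, xi_new, faces)
                if hit is not None:
                    tag, pt = hit
                    status[i] = f"exited:{tag}"
                    frac = np.linalg.norm(pt - xi_prev) / max(
                        np.linalg.norm(xi_new - xi_prev), 1e-30
                    )
                    exit_time[i] = rec_t[i][-1] + frac * (t - rec_t[i][-1])
                    exit_pos[i] = pt
                    # speed evaluated at the face crossing point, nudged
                    # just inside so the interpolation is well-defined
                    probe = pt + 1e-3 * (xi_prev - pt)
                    u_probe, g_probe = fields_at(probe[None, :])
                    u_exit, g_exit = u_probe[0], g_probe[0]
                    exit_speed[i] = float(
                        np.linalg.norm(u_exit + mob[i] * g_exit)
                    )
                    x_new[i] = pt
                else:
                    status[i] = "frozen_at_wall"
                    x_new[i] = xi_prev
                terminated = True
            elif dist[k] < settings.wall_contact_tol:
                # centre touched a wall (or an electrode face): freeze,
                # unless the contact point is on a port face (about to exit)
                near_port = any(
                    shapely.dwithin(
                        shapely.points(x_new[i]),
                        shapely.linestrings([p0, p1]),
                        settings.wall_contact_tol * 2,
                    )
                    for _, p0, p1 in faces
                )
                if not near_port:
                    status[i] = "frozen_at_wall"
                    terminated = True
            if terminated:
                active[i] = False

        # write back clipped positions so masked particles stay put
        if inertial:
            y = solver.y
            y[: 2 * n] = x_new.ravel()
        else:
            solver.y[:] = x_new.ravel()

        # record: active particles at every accepted step; terminated ones once
        u_now, g_now = fields_at(x_new)
        for i in range(n):
            if not active[i] and final_recorded[i]:
                continue
            ti = t if active[i] or not np.isfinite(exit_time[i]) else exit_time[i]
            if ti <= rec_t[i][-1]:
                ti = np.nextafter(rec_t[i][-1], np.inf)
            rec_t[i].append(ti)
            rec_x[i].append(x_new[i].copy())
            vi = u_now[i] + mob[i] * g_now[i]
            rec_s[i].append(float(np.linalg.norm(vi)))
            rec_f[i].append(float(np.linalg.norm(pref[i] * g_now[i])))
            if not active[i]:
                final_recorded[i] = True
        x_prev = x_new

    out = []
    for i in range(n):
        out.append(
            Trajectory(
                particle_id=int(ensemble.ids[i]),
                species=str(ensemble.species[i]),
                times=np.asarray(rec_t[i]),
                positions=np.asarray(rec_x[i]),
                speeds=np.asarray(rec_s[i]),
                dep_force_mag=np.asarray(rec_f[i]),
                status=str(status[i]),
                exit_time=float(exit_time[i]) if np.isfinite(exit_time[i]) else None,
                exit_position=exit_pos[i] if np.isfinite(exit_pos[i]).all() else None,
                exit_speed=float(exit_speed[i]) if np.isfinite(exit_speed[i]) else None,
            )
        )
    return out


def assign_outlets(
    trajectories: list[Trajectory], geometry: LOCGeometry
) -> pd.DataFrame:
    """Map every particle to an outlet or 'lost'.

    'lost' covers wall-frozen particles, particles still inside at t_end
    and particles washed back through an inlet.
    """
    outlet_tags = {t for t in geometry.port_directions if t.startswith("outlet")}
    rows = []
    for tr in trajectories:
        if tr.exited and tr.outlet in outlet_tags:
            dest = tr.outlet
        else:
            dest = "lost"
        rows.append(
            {
                "id": tr.particle_id,
                "species": tr.species,
                "outlet": dest,
                "status": tr.status,
                "exit_time_s": tr.exit_time,
                "exit_speed_m_per_s": tr.exit_speed,
            }
        )
    return pd.DataFrame(rows)


def trajectories_to_csv(trajectories: list[Trajectory], path) -> None:
    pd.concat([tr.to_frame() for tr in trajectories]).to_csv(path, index=False)
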