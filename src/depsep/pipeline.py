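"""Run configuration and the sequential simulation pipeline.

The physics is one-way coupled and solved sequentially: build geometry,
mesh it, solve creeping flow, solve the electrode potential, trace the
released cells through both fields, then count outcomes into the
separation report.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import yaml

from .dep import check_force_ordering, load_species_catalog
from .electrostatics import ElectrodeDrive, PotentialSolution, solve_potential
from .geometry import LOCGeometry, LOCParams, build_loc_geometry
from .meshing import Mesh, generate_mesh
from .metrics import SeparationReport, build_report
from .population import ParticleEnsemble, PopulationSpec, generate_ensemble
from .stokes import FlowBC, FlowField, MediumProps, solve_stokes
from .tracing import TracerSettings, Trajectory, advance_particles, assign_outlets

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config", "dump_config"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


# YAML key <-> dataclass field maps, with explicit unit suffixes
_GEOMETRY_KEYS = {
    "inlet_length_um": "inlet_length",
    "main_channel_length_um": "main_channel_length",
    "secondary_channel_length_um": "secondary_channel_length",
    "channel_width_um": "channel_width",
    "channel_depth_um": "channel_depth",
    "outlet_length_um": "outlet_length",
    "inlet_angle_deg": "inlet_angle",
    "outlet_angle_deg": "outlet_angle",
    "electrode_protrusion_um": "electrode_protrusion",
    "electrode_width_um": "electrode_width",
    "electrode_gap_um": "electrode_gap",
    "n_electrodes": "n_electrodes",
}
_MEDIUM_KEYS = {
    "dynamic_viscosity_Pa_s": "dynamic_viscosity",
    "density_kg_per_m3": "density",
    "electrical_conductivity_S_per_m": "electrical_conductivity",
    "relative_permittivity": "relative_permittivity",
}
_DRIVE_KEYS = {
    "amplitude_V": "amplitude",
    "n_electrodes": "n_electrodes",
    "frequency_Hz": "frequency",
    "pattern": "pattern",
}
_FLOW_KEYS = {
    "v_blood_um_per_s": "v_blood",
    "v_buffer_um_per_s": "v_buffer",
    "outlet_pressure_Pa": "outlet_pressure",
    "profile": "profile",
}
_POPULATION_KEYS = {
    "n_per_species": "n_per_species",
    "species": "species",
    "placement": "placement",
    "seed": "seed",
    "release_margin": "release_margin",
    "abundance_weighted": "abundance_weighted",
}
_TRACER_KEYS = {
    "t_end_s": "t_end",
    "rel_tol": "rel_tol",
    "dynamics": "dynamics",
    "wall_contact_tol_um": "wall_contact_tol",
    "max_step_s": "max_step",
}
_SECTIONS = {
    "geometry": (_GEOMETRY_KEYS, LOCParams),
    "medium": (_MEDIUM_KEYS, MediumProps),
    "drive": (_DRIVE_KEYS, ElectrodeDrive),
    "flow": (_FLOW_KEYS, FlowBC),
    "population": (_POPULATION_KEYS, PopulationSpec),
    "tracer": (_TRACER_KEYS, TracerSettings),
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, with consistency validation."""

    loc: LOCParams = field(default_factory=LOCParams)
    medium: MediumProps = field(default_factory=MediumProps)
    drive: ElectrodeDrive = field(default_factory=ElectrodeDrive)
    flow: FlowBC = field(default_factory=FlowBC)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    tracer: TracerSettings = field(default_factory=TracerSettings)
    mesh_level: str = "fine"
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.drive.n_electrodes != self.loc.n_electrodes:
            raise ConfigError(
                f"drive pattern length {self.drive.n_electrodes} does not "
                f"match geometry n_electrodes {self.loc.n_electrodes}"
            )
        if self.mesh_level not in ("coarse", "normal", "fine"):
            raise ConfigError(f"unknown mesh_level {self.mesh_level!r}")

    @classmethod
    def for_design(
        cls,
        n_electrodes: int = 4,
        channel_width: float = 40.0,
        voltage: float = 2.0,
        v_buffer: float = 850.0,
        v_blood: float = 134.0,
        mesh_level: str = "fine",
        n_per_species: int = 20,
        **extra,
    ) -> "RunConfig":
        """Convenience constructor for one design-sweep combination."""
        return cls(
            loc=LOCParams(n_electrodes=n_electrodes, channel_width=channel_width),
            drive=ElectrodeDrive(amplitude=voltage, n_electrodes=n_electrodes),
            flow=FlowBC(v_blood=v_blood, v_buffer=v_buffer),
            population=PopulationSpec(n_per_species=n_per_species),
            mesh_level=mesh_level,
            **extra,
        )

    def with_mesh_level(self, level: str) -> "RunConfig":
        return replace(self, mesh_level=level)

    def to_dict(self) -> dict:
        out: dict = {"mesh_level": self.mesh_level}
        if self.output_dir:
            out["output_dir"] = self.output_dir
        objs = {
            "geometry": self.loc,
            "medium": self.medium,
            "drive": self.drive,
            "flow": self.flow,
            "population": self.population,
            "tracer": self.tracer,
        }
        for section, (keys, _) in _SECTIONS.items():
            obj = objs[section]
            d = {}
            for yk, fk in keys.items():
                v = getattr(obj, fk)
                if isinstance(v, tuple):
                    v = list(v)
                d[yk] = v
            out[section] = d
        return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected with the key name; omitted keys take the
    documented defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known_top = set(_SECTIONS) | {"mesh_level", "output_dir"}
    for k in raw:
        if k not in known_top:
            raise ConfigError(f"unknown configuration section or key: {k!r}")
    kwargs = {}
    section_to_field = {
        "geometry": "loc",
        "medium": "medium",
        "drive": "drive",
        "flow": "flow",
        "population": "population",
        "tracer": "tracer",
    }
    for section, (keys, cls) in _SECTIONS.items():
        data = raw.get(section) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        field_kwargs = {}
        for k, v in data.items():
            if k not in keys:
                raise ConfigError(f"unknown key {k!r} in section {section!r}")
            if isinstance(v, list):
                v = tuple(v)
            field_kwargs[keys[k]] = v
        try:
            kwargs[section_to_field[section]] = cls(**field_kwargs)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid {section} configuration: {exc}") from exc
    if "mesh_level" in raw:
        kwargs["mesh_level"] = raw["mesh_level"]
    if "output_dir" in raw:
        kwargs["output_dir"] = raw["output_dir"]
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path=None) -> str:
    s = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


@dataclass
class PipelineResult:
    """All artifacts of one run."""

    config: RunConfig
    geometry: LOCGeometry
    mesh: Mesh
    flow: FlowField
    potential: PotentialSolution | None
    ensemble: ParticleEnsemble
    trajectories: list[Trajectory]
    assignment: object  # DataFrame
    report: SeparationReport
    timings: dict[str, float] = field(default_factory=dict)


def run_pipeline(config: RunConfig, persist: bool = True) -> PipelineResult:
    """Execute geometry -> mesh -> flow -> potential -> tracing -> metrics.

    When ``config.output_dir`` is set and ``persist`` is true, fields
    (VTK), trajectories (CSV) and the report (JSON) are written there.
    """
    timings: dict[str, float] = {}

    def _stage(name):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()

            def __exit__(self_, et, ev, tb):
                timings[name] = time.perf_counter() - self_.t0
                if et is not None:
                    log.error("pipeline stage %s failed: %s", name, ev)
                return False

        return _T()

    with _stage("geometry"):
        geometry = build_loc_geometry(config.loc)
    with _stage("mesh"):
        mesh = generate_mesh(geometry, config.mesh_level)
    with _stage("stokes"):
        flow = solve_stokes(mesh, config.flow, config.medium)
        log.info(
            "stokes: %d dofs, div rms %.2e", 2 * flow.space.n_dofs, flow.divergence_norm()
        )
    potential = None
    if config.drive.amplitude > 0:
        with _stage("electrostatics"):
            potential = solve_potential(mesh, config.drive, config.medium)
    with _stage("population"):
        catalog = load_species_catalog()
        ensemble = generate_ensemble(config.population, geometry)
        if potential is not None:
            check_force_ordering(catalog, config.medium, config.drive.omega)
    with _stage("tracing"):
        trajectories = advance_particles(
            flow,
            potential,
            ensemble,
            catalog,
            config.medium,
            config.drive if potential is not None else None,
            config.tracer,
            geometry=geometry,
        )
    with _stage("metrics"):
        assignment = assign_outlets(trajectories, geometry)
        report = build_report(assignment, flow, geometry, config=config.to_dict())

    result = PipelineResult(
        config=config,
        geometry=geometry,
        mesh=mesh,
        flow=flow,
        potential=potential,
        ensemble=ensemble,
        trajectories=trajectories,
        assignment=assignment,
        report=report,
        timings=timings,
    )
    if persist and config.output_dir:
        _persist(result)
    return result


def _persist(result: PipelineResult) -> None:
    import os

    from .io import export_fields_vtk, export_mesh_msh
    from .tracing import trajectories_to_csv

    out = result.config.output_dir
    os.makedirs(out, exist_ok=True)
    export_fields_vtk(os.path.join(out, "fields.vtk"), result)
    export_mesh_msh(os.path.join(out, "mesh.msh"), result.mesh)
    trajectories_to_csv(result.trajectories, os.path.join(out, "trajectories.csv"))
    result.assignment.to_csv(os.path.join(out, "assignment.csv"), index=False)
    result.report.to_json(os.path.join(out, "report.json"))
    with open(os.path.join(out, "geometry.json"), "w") as fh:
        fh.write(result.geometry.to_json())
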