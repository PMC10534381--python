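"""Separation performance metrics, the parametric design sweep and the
grid-independence study.

Separation efficiency (per species):  eta = 100 x (cells of the species
recovered at its designated outlet) / (cells of the species injected).
Lost cells (wall-frozen, unresolved, washed back) count against the
denominator.

Purity (per outlet):  100 x targeted / (targeted + unwanted) among the
cells that actually arrived at the outlet; lost cells appear in neither
numerator nor denominator.  Empty outlets and uninjected species are
reported as absent, not as 0%.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import LOCGeometry, SPECIES_TARGET_OUTLET
from .stokes import FlowField

__all__ = [
    "SeparationReport",
    "SweepConfig",
    "ConvergenceReport",
    "separation_efficiency",
    "outlet_purity",
    "throughput",
    "run_sweep",
    "grid_convergence",
]

log = logging.getLogger(__name__)


def separation_efficiency(
    assignment: pd.DataFrame,
    target_map: dict[str, str] | None = None,
) -> dict[str, float]:
    """Per-species efficiency in percent.

    Species with zero injected cells are absent from the result (with a
    warning), never reported as 0%.
    """
    target_map = target_map or SPECIES_TARGET_OUTLET
    out = {}
    for species, target in target_map.items():
        sub = assignment[assignment["species"] == species]
        if len(sub) == 0:
            log.warning("no %s cells injected; efficiency undefined", species)
            continue
        out[species] = 100.0 * float((sub["outlet"] == target).sum()) / len(sub)
    return out


def outlet_purity(
    assignment: pd.DataFrame,
    target_map: dict[str, str] | None = None,
) -> dict[str, float]:
    """Per-outlet purity in percent; empty outlets are absent."""
    target_map = target_map or SPECIES_TARGET_OUTLET
    intended = {v: k for k, v in target_map.items()}
    out = {}
    for outlet, species in intended.items():
        sub = assignment[assignment["outlet"] == outlet]
        if len(sub) == 0:
            log.warning("outlet %s received no cells; purity undefined", outlet)
            continue
        out[outlet] = 100.0 * float((sub["species"] == species).sum()) / len(sub)
    return out


def throughput(flow: FlowField, geometry: LOCGeometry, outlet_tag: str) -> float:
    """Volumetric flow rate through an outlet, um^3/s.

    The 2D outward flux (per unit depth) is multiplied by the channel
    depth CD.
    """
    if outlet_tag not in geometry.port_directions:
        raise KeyError(f"unknown port tag {outlet_tag!r}")
    flux_2d = flow.boundary_flux(outlet_tag)  # m^2/s
    depth = geometry.params.channel_depth * 1e-6  # m
    return flux_2d * depth * 1e18  # m^3/s -> um^3/s


@dataclass
class SeparationReport:
    """Full outcome of one pipeline run.

    Percentages in [0, 100]; throughput in um^3/s; the configuration echo
    carries every geometry/drive/flow/medium/frequency value that produced
    the numbers.
    """

    efficiency: dict[str, float]
    purity: dict[str, float]
    throughput: dict[str, float]
    lost: int
    n_injected: int
    counts: dict[str, dict[str, int]]
    config: dict = field(default_factory=dict)

    @property
    def complete_separation(self) -> bool:
        effs = [self.efficiency.get(s) for s in ("CTC", "WBC", "PLT")]
        purs = [self.purity.get(o) for o in SPECIES_TARGET_OUTLET.values()]
        vals = effs + purs
        return all(v is not None and v >= 100.0 for v in vals) and self.lost == 0

    def min_efficiency(self) -> float:
        return min(self.efficiency.values())

    def min_purity(self) -> float:
        return min(self.purity.values())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["complete_separation"] = self.complete_separation
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def build_report(
    assignment: pd.DataFrame,
    flow: FlowField,
    geometry: LOCGeometry,
    config: dict | None = None,
) -> SeparationReport:
    counts = (
        assignment.groupby(["species", "outlet"]).size().unstack(fill_value=0)
    )
    counts_dict = {
        s: {o: int(v) for o, v in row.items()} for s, row in counts.iterrows()
    }
    thr = {
        tag: throughput(flow, geometry, tag)
        for tag in geometry.port_directions
        if tag.startswith("outlet")
    }
    return SeparationReport(
        efficiency=separation_efficiency(assignment),
        purity=outlet_purity(assignment),
        throughput=thr,
        lost=int((assignment["outlet"] == "lost").sum()),
        n_injected=len(assignment),
        counts=counts_dict,
        config=config or {},
    )


def species_wall_gaps(trajectories, geometry: LOCGeometry, station_x: float | None = None) -> dict[str, float]:
    """Mean distance of each species from the electrode-side (upper) wall,
    measured where the cells cross a station at the end of the electrode
    array (before the first split).

    This is the gap the trajectory plots show between the cell paths and
    the electrode-side wall: it grows with drive voltage (cells pushed
    away from the electrodes) and shrinks with buffer velocity (stream
    focused closer to the wall).  Cells that freeze upstream of the
    station contribute their final distance from the wall.
    """
    import numpy as np

    params = geometry.params
    corners = geometry.electrode_corners()
    if station_x is None:
        station_x = corners[:, 0].max() + 0.25 * params.channel_width
    y_top = geometry.junctions["split1"][1] + params.channel_width / 2.0

    gaps: dict[str, list[float]] = {}
    for tr in trajectories:
        x = tr.positions[:, 0]
        y = tr.positions[:, 1]
        after = np.nonzero(x >= station_x)[0]
        if len(after) and after[0] > 0:
            k = after[0]
            f = (station_x - x[k - 1]) / max(x[k] - x[k - 1], 1e-30)
            yc = y[k - 1] + f * (y[k] - y[k - 1])
        else:
            yc = y[-1]
        gaps.setdefault(tr.species, []).append(y_top - yc)
    return {s: float(np.mean(v)) for s, v in gaps.items()}


@dataclass(frozen=True)
class SweepConfig:
    """Grid of design/operating combinations for the parametric sweep."""

    channel_widths: tuple[float, ...] = (40.0, 50.0, 60.0)
    voltages: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0)
    electrode_counts: tuple[int, ...] = (4,)
    buffer_velocities: tuple[float, ...] = (850.0,)
    cell_velocities: tuple[float, ...] = (134.0,)
    mesh_level: str = "normal"
    n_per_species: int = 20

    def __post_init__(self) -> None:
        for name in (
            "channel_widths",
            "voltages",
            "electrode_counts",
            "buffer_velocities",
            "cell_velocities",
        ):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    def combinations(self):
        return itertools.product(
            self.electrode_counts,
            self.channel_widths,
            self.voltages,
            self.buffer_velocities,
            self.cell_velocities,
        )


def run_sweep(config: SweepConfig):
    """One full pipeline run per combination; failures are recorded and
    the sweep continues.

    Returns (reports, summary) where summary is one row per combination
    with per-species efficiency, per-outlet purity and a
    complete-separation flag.
    """
    from .pipeline import RunConfig, run_pipeline

    reports = {}
    rows = []
    for n_el, cw, va, vb, vc in config.combinations():
        key = (n_el, cw, va, vb, vc)
        row = {
            "n_electrodes": n_el,
            "channel_width_um": cw,
            "voltage_V": va,
            "v_buffer_um_per_s": vb,
            "v_cells_um_per_s": vc,
        }
        try:
            rc = RunConfig.for_design(
                n_electrodes=n_el,
                channel_width=cw,
                voltage=va,
                v_buffer=vb,
                v_blood=vc,
                mesh_level=config.mesh_level,
                n_per_species=config.n_per_species,
            )
            result = run_pipeline(rc)
            rep = result.report
            reports[key] = rep
            for s, v in rep.efficiency.items():
                row[f"eff_{s}_pct"] = v
            for o, v in rep.purity.items():
                row[f"purity_{o}_pct"] = v
            row["lost"] = rep.lost
            row["complete_separation"] = rep.complete_separation
        except Exception as exc:
            log.error("sweep combination %s failed: %s", key, exc)
            row["error"] = str(exc)
        rows.append(row)
    return reports, pd.DataFrame(rows)


@dataclass
class ConvergenceReport:
    """Grid-independence study on per-species outlet speeds.

    ``speeds`` maps refinement level -> species -> mean cell speed (m/s)
    at the species' designated outlet; ``errors`` holds the pairwise
    relative errors (percent) between successive levels, keyed by
    'level_a/level_b'.
    """

    speeds: dict[str, dict[str, float]]
    errors: dict[str, dict[str, float]]
    criterion_pct: float = 1.0

    @property
    def max_error_finest_pair(self) -> float:
        key = list(self.errors)[-1]
        vals = [v for v in self.errors[key].values() if np.isfinite(v)]
        if not vals:
            return np.inf
        return max(vals)

    @property
    def passed(self) -> bool:
        return self.max_error_finest_pair <= self.criterion_pct

    def to_dict(self) -> dict:
        return {
            "speeds_m_per_s": self.speeds,
            "errors_pct": self.errors,
            "criterion_pct": self.criterion_pct,
            "max_error_finest_pair_pct": self.max_error_finest_pair,
            "passed": self.passed,
        }


def grid_convergence(
    run_config,
    levels: tuple[str, ...] = ("coarse", "normal", "fine"),
    criterion_pct: float = 1.0,
    _results: dict | None = None,
) -> ConvergenceReport:
    """Run the pipeline at successive refinement levels and compare the
    mean cell speed of each species at its designated outlet.

    ``_results`` may inject pre-computed pipeline results keyed by level
    (to reuse an existing fine-mesh run).
    """
    from .pipeline import run_pipeline

    if len(levels) < 2:
        raise ValueError("need at least 2 refinement levels")
    speeds: dict[str, dict[str, float]] = {}
    for level in levels:
        if _results and level in _results:
            result = _results[level]
        else:
            rc = run_config.with_mesh_level(level)
            result = run_pipeline(rc)
        per_species: dict[str, float] = {}
        asg = result.assignment
        for species, target in SPECIES_TARGET_OUTLET.items():
            sub = asg[(asg["species"] == species) & (asg["outlet"] == target)]
            v = sub["exit_speed_m_per_s"].dropna()
            per_species[species] = float(v.mean()) if len(v) else np.nan
        speeds[level] = per_species

    errors: dict[str, dict[str, float]] = {}
    for la, lb in zip(levels[:-1], levels[1:]):
        pair = {}
        for species in SPECIES_TARGET_OUTLET:
            va, vb = speeds[la].get(species), speeds[lb].get(species)
            if va is None or vb is None or not np.isfinite(va) or not np.isfinite(vb):
                pair[species] = np.nan  # non-comparable: absent at an outlet
            else:
                pair[species] = 100.0 * abs(vb - va) / abs(vb)
        errors[f"{la}/{lb}"] = pair
    return ConvergenceReport(speeds=speeds, errors=errors, criterion_pct=criterion_pct)
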