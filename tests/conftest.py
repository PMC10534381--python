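"""Shared fixtures: analytic FEM fixtures and cached device runs.

The full-device pipeline runs are session-scoped and shared across test
modules so each distinct configuration is solved exactly once.
"""

from __future__ import annotations

import pytest

from depsep import (
    FlowBC,
    MediumProps,
    RunConfig,
    build_loc_geometry,
    generate_mesh,
    load_species_catalog,
    run_pipeline,
    solve_stokes,
)
from depsep.geometry import LOCParams
from depsep.meshing import mesh_rectangle


@pytest.fixture(scope="session")
def catalog():
    return load_species_catalog()


@pytest.fixture(scope="session")
def medium():
    return MediumProps()


@pytest.fixture(scope="session")
def default_geometry():
    return build_loc_geometry(LOCParams())


@pytest.fixture(scope="session")
def coarse_mesh(default_geometry):
    return generate_mesh(default_geometry, "coarse")


@pytest.fixture(scope="session")
def normal_mesh(default_geometry):
    return generate_mesh(default_geometry, "normal")


@pytest.fixture(scope="session")
def channel_flow():
    """Plane-Poiseuille fixture: straight channel, parabolic inlet."""
    mesh = mesh_rectangle(
        200.0, 40.0, 2.0,
        tags={"left": "blood_inlet", "right": "outlet_main",
              "top": "wall", "bottom": "wall"},
    )
    bc = FlowBC(v_blood=100.0, v_buffer=0.0, profile="parabolic")
    return solve_stokes(mesh, bc, MediumProps())


class _RunCache:
    """Session-wide memo of pipeline results keyed by configuration."""

    def __init__(self):
        self._store = {}

    def get(self, key: str, config: RunConfig):
        if key not in self._store:
            self._store[key] = run_pipeline(config, persist=False)
        return self._store[key]


@pytest.fixture(scope="session")
def run_cache():
    return _RunCache()


def _design(**kw) -> RunConfig:
    return RunConfig.for_design(**kw)


@pytest.fixture(scope="session")
def optimum_fine(run_cache):
    """Proposed design (4 el, +-2 V, CW 40, 850/134) on the fine mesh."""
    return run_cache.get("opt_fine", _design(mesh_level="fine"))


@pytest.fixture(scope="session")
def optimum_normal(run_cache):
    return run_cache.get("opt_normal", _design(mesh_level="normal"))


@pytest.fixture(scope="session")
def optimum_coarse(run_cache):
    return run_cache.get("opt_coarse", _design(mesh_level="coarse"))


@pytest.fixture(scope="session")
def two_electrode_fine(run_cache):
    """Two electrodes at +-4 V, CW 50 um."""
    return run_cache.get(
        "2el_fine",
        _design(mesh_level="fine", n_electrodes=2, voltage=4.0, channel_width=50.0),
    )


@pytest.fixture(scope="session")
def high_buffer_fine(run_cache):
    """Four electrodes at +-2.5 V, buffer 1350 um/s."""
    return run_cache.get(
        "1350_fine", _design(mesh_level="fine", voltage=2.5, v_buffer=1350.0)
    )


@pytest.fixture(scope="session")
def low_buffer_normal(run_cache):
    """Buffer 350 um/s: focusing too weak for separation."""
    return run_cache.get("350_normal", _design(mesh_level="normal", v_buffer=350.0))


@pytest.fixture(scope="session")
def zero_field_coarse(run_cache):
    """Pure hydrodynamic run (Va = 0)."""
    return run_cache.get("va0_coarse", _design(mesh_level="coarse", voltage=0.0))


@pytest.fixture(scope="session")
def va_series_normal(run_cache):
    """Normal-mesh runs at increasing drive voltage, for gap monotonicity."""
    out = {}
    for va in (2.0, 2.5, 3.0):
        out[va] = run_cache.get(f"va{va}_normal", _design(mesh_level="normal", voltage=va))
    return out


@pytest.fixture(scope="session")
def high_buffer_25_normal(run_cache):
    return run_cache.get(
        "1350_25_normal", _design(mesh_level="normal", voltage=2.5, v_buffer=1350.0)
    )
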