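"""Single-shell cell dielectrics, Clausius-Mossotti factor and DEP force.

A biological cell is modelled as a conducting cytoplasm sphere wrapped in
a thin, poorly conducting membrane.  The shelled sphere is homogenised
into one equivalent complex permittivity

    e*_eff = e*_mem (g^3 + 2 D) / (g^3 - D),
    g = R / (R - t),   D = (e*_cyt - e*_mem) / (e*_cyt + 2 e*_mem)

with e* = e - j sigma / omega.  The real Clausius-Mossotti factor

    Re K = Re[(e*_p - e*_m) / (e*_p + 2 e*_m)]  in [-1/2, 1]

sets the sign (nDEP < 0 repels from the electrodes) and magnitude of the
time-averaged dielectrophoretic force

    F_DEP = 2 pi e_m Rp^3 Re[K] grad|E_rms|^2 .

The electrostatic solve returns the amplitude field of the sinusoidal
drive, so grad|E_rms|^2 = grad|E|^2 / 2; the factor is applied here
(``AC_TIME_AVERAGE``) whenever an amplitude-field drive is supplied.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .stokes import MediumProps, EPS0

__all__ = [
    "CellSpecies",
    "ComplexPermittivity",
    "load_species_catalog",
    "shell_effective_permittivity",
    "medium_complex_permittivity",
    "clausius_mossotti_real",
    "dep_force",
    "dep_mobility",
    "cmf_spectrum",
]

log = logging.getLogger(__name__)

#: time-average of sin^2 over one drive period: |E_rms|^2 = |E_amp|^2 / 2
AC_TIME_AVERAGE = 0.5


@dataclass(frozen=True)
class CellSpecies:
    """Size and shelled dielectric properties of one cell type."""

    name: str
    diameter: float                        # um
    membrane_thickness: float              # nm
    cytoplasm_conductivity: float          # S/m
    membrane_conductivity: float           # S/m
    cytoplasm_relative_permittivity: float
    membrane_relative_permittivity: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("diameter must be > 0")
        if self.membrane_thickness_m >= self.radius_m:
            raise ValueError(
                f"membrane thickness {self.membrane_thickness} nm is not "
                f"smaller than the cell radius"
            )
        for f in (
            "cytoplasm_conductivity",
            "membrane_conductivity",
            "cytoplasm_relative_permittivity",
            "membrane_relative_permittivity",
        ):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be > 0")

    @property
    def radius_m(self) -> float:
        return self.diameter * 1e-6 / 2.0

    @property
    def membrane_thickness_m(self) -> float:
        return self.membrane_thickness * 1e-9

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ComplexPermittivity:
    """e* = eps - j sigma / omega at a given angular frequency.

    The DC limit (omega == 0) is a declared special case: the complex
    value is undefined and consumers must use the conductivity branch.
    """

    eps: float      # real permittivity, F/m
    sigma: float    # conductivity, S/m
    omega: float    # rad/s

    @property
    def is_dc(self) -> bool:
        return self.omega == 0.0

    @property
    def value(self) -> complex:
        if self.is_dc:
            raise ZeroDivisionError(
                "complex permittivity undefined at omega = 0; use the "
                "conductivity limit"
            )
        return complex(self.eps, -self.sigma / self.omega)


def load_species_catalog(path=None) -> dict[str, CellSpecies]:
    """Load the shipped (or a user) JSON species catalog."""
    if path is None:
        ref = importlib.resources.files("depsep").joinpath("data/cells.json")
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    out = {}
    for name, p in raw["species"].items():
        out[name] = CellSpecies(
            name=name,
            diameter=p["diameter_um"],
            membrane_thickness=p["membrane_thickness_nm"],
            cytoplasm_conductivity=p["cytoplasm_conductivity_S_per_m"],
            membrane_conductivity=p["membrane_conductivity_S_per_m"],
            cytoplasm_relative_permittivity=p["cytoplasm_relative_permittivity"],
            membrane_relative_permittivity=p["membrane_relative_permittivity"],
        )
    return out


def _shell_reduce(ec: complex, em: complex, g3: float) -> complex:
    D = (ec - em) / (ec + 2.0 * em)
    return em * (g3 + 2.0 * D) / (g3 - D)


def shell_effective_permittivity(cell: CellSpecies, omega: float) -> ComplexPermittivity:
    """Homogenised complex permittivity of the shelled sphere.

    At omega = 0 the same closed form is applied to the conductivities
    alone (conductivity-limit branch) and returned with eps set to the
    high-frequency permittivity reduction for completeness.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    R = cell.radius_m
    t = cell.membrane_thickness_m
    g3 = (R / (R - t)) ** 3
    ec_r = cell.cytoplasm_relative_permittivity * EPS0
    em_r = cell.membrane_relative_permittivity * EPS0
    sc, sm = cell.cytoplasm_conductivity, cell.membrane_conductivity
    if omega == 0.0:
        sigma_eff = (_shell_reduce(complex(sc), complex(sm), g3)).real
        eps_eff = (_shell_reduce(complex(ec_r), complex(em_r), g3)).real
        return ComplexPermittivity(eps=eps_eff, sigma=sigma_eff, omega=0.0)
    ec = complex(ec_r, -sc / omega)
    em = complex(em_r, -sm / omega)
    eff = _shell_reduce(ec, em, g3)
    return ComplexPermittivity(eps=eff.real, sigma=-eff.imag * omega, omega=omega)


def medium_complex_permittivity(medium: MediumProps, omega: float) -> ComplexPermittivity:
    return ComplexPermittivity(
        eps=medium.permittivity,
        sigma=medium.electrical_conductivity,
        omega=omega,
    )


def clausius_mossotti_real(
    particle: ComplexPermittivity, medium: ComplexPermittivity, omega: float
) -> float:
    """Real part of the Clausius-Mossotti factor; bounded in [-1/2, 1]."""
    if particle.omega != omega or medium.omega != omega:
        raise ValueError("inconsistent evaluation frequency across arguments")
    if omega == 0.0:
        # conductivity-only DC limit, never a division by omega
        sp_, sm_ = particle.sigma, medium.sigma
        return (sp_ - sm_) / (sp_ + 2.0 * sm_)
    K = (particle.value - medium.value) / (particle.value + 2.0 * medium.value)
    return float(K.real)


def species_cmf(cell: CellSpecies, medium: MediumProps, omega: float) -> float:
    """Re[K] of one species in the given medium at angular frequency omega."""
    return clausius_mossotti_real(
        shell_effective_permittivity(cell, omega),
        medium_complex_permittivity(medium, omega),
        omega,
    )


def dep_force(
    cell: CellSpecies,
    medium: MediumProps,
    drive_grad_e2: np.ndarray,
    omega: float,
    amplitude_drive: bool = True,
) -> np.ndarray:
    """Time-averaged DEP force (N), 2 pi e_m Rp^3 Re[K] grad|E_rms|^2.

    ``drive_grad_e2`` is grad|E|^2 in V^2/m^3.  With ``amplitude_drive``
    (the default, matching the electrostatics module) the input is built
    from the amplitude field and is halved to obtain the RMS drive.
    """
    K = species_cmf(cell, medium, omega)
    pref = 2.0 * np.pi * medium.permittivity * cell.radius_m**3 * K
    if amplitude_drive:
        pref *= AC_TIME_AVERAGE
    return pref * np.asarray(drive_grad_e2, dtype=float)


def dep_mobility(
    cell: CellSpecies,
    medium: MediumProps,
    omega: float,
    amplitude_drive: bool = True,
) -> float:
    """Overdamped DEP velocity per unit amplitude drive, m/s per V^2/m^3.

    F/(6 pi mu Rp) per grad|E|^2, including the AC time-average factor
    when the drive comes from the amplitude field.
    """
    K = species_cmf(cell, medium, omega)
    mob = (
        medium.permittivity
        * cell.radius_m**2
        * K
        / (3.0 * medium.dynamic_viscosity)
    )
    if amplitude_drive:
        mob *= AC_TIME_AVERAGE
    return mob


def check_force_ordering(
    catalog: dict[str, CellSpecies], medium: MediumProps, omega: float
) -> bool:
    """Verify |F_WBC| > |F_CTC| > |F_PLT| and nDEP for all species.

    Logs a warning when a user configuration breaks the ordering the
    separator design relies on.
    """
    mags = {}
    negs = {}
    for name in ("CTC", "WBC", "PLT"):
        cell = catalog[name]
        K = species_cmf(cell, medium, omega)
        mags[name] = abs(K) * cell.radius_m**3
        negs[name] = K < 0
    ok = mags["WBC"] > mags["CTC"] > mags["PLT"] and all(negs.values())
    if not ok:
        log.warning(
            "DEP force ordering |F_WBC| > |F_CTC| > |F_PLT| (all nDEP) is "
            "violated for this medium/frequency; separation routing may fail"
        )
    return ok


def cmf_spectrum(
    cell: CellSpecies,
    medium: MediumProps,
    frequencies_hz: np.ndarray,
) -> np.ndarray:
    """Re[K] over a frequency grid; exportable as (f, Re K) CSV."""
    out = np.empty(len(frequencies_hz))
    for i, f in enumerate(np.asarray(frequencies_hz, dtype=float)):
        out[i] = species_cmf(cell, medium, 2.0 * np.pi * f)
    return out
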