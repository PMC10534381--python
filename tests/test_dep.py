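"""Single-shell dielectrics, Clausius-Mossotti factor and DEP force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depsep.dep import (
    AC_TIME_AVERAGE,
    CellSpecies,
    check_force_ordering,
    clausius_mossotti_real,
    dep_force,
    medium_complex_permittivity,
    shell_effective_permittivity,
    species_cmf,
)
from depsep.stokes import EPS0, MediumProps


def make_cell(d=10.0, t=7.0, sc=0.5, sm=1e-6, ec=60.0, em=10.0):
    return CellSpecies(
        name="X",
        diameter=d,
        membrane_thickness=t,
        cytoplasm_conductivity=sc,
        membrane_conductivity=sm,
        cytoplasm_relative_permittivity=ec,
        membrane_relative_permittivity=em,
    )


class TestCatalog:
    def test_table_values_loaded(self, catalog):
        assert set(catalog) == {"CTC", "WBC", "PLT"}
        assert catalog["CTC"].diameter == 15.0
        assert catalog["WBC"].cytoplasm_conductivity == 0.18
        assert catalog["PLT"].membrane_thickness == 8.0
        assert catalog["CTC"].membrane_conductivity == 9e-7

    def test_membrane_thicker_than_radius_rejected(self):
        with pytest.raises(ValueError):
            make_cell(d=0.01, t=7.0)


class TestShellModel:
    def test_homogeneous_sphere_limit_exact(self):
        """Membrane identical to cytoplasm: the shell reduction is exact."""
        cell = make_cell(sc=0.4, sm=0.4, ec=50.0, em=50.0)
        w = 2 * np.pi * 1e5
        eff = shell_effective_permittivity(cell, w)
        assert eff.eps == pytest.approx(50.0 * EPS0, rel=1e-12)
        assert eff.sigma == pytest.approx(0.4, rel=1e-12)

    def test_vanishing_membrane_limit(self):
        """t -> 0 recovers the bare cytoplasm complex permittivity within
        1e-4 relative at t = R x 1e-6."""
        R_nm = 10.0 / 2 * 1e3
        cell = make_cell(d=10.0, t=R_nm * 1e-6)
        # evaluate above the interfacial dispersions so the vanishing
        # shell is the only remaining perturbation
        w = 2 * np.pi * 1e9
        eff = shell_effective_permittivity(cell, w)
        bare = complex(60.0 * EPS0, -0.5 / w)
        got = complex(eff.eps, -eff.sigma / w)
        assert abs(got - bare) / abs(bare) < 1e-4

    def test_wbc_dc_conductivity_against_scalar_oracle(self, catalog):
        """DC effective conductivity of the WBC computed by an independent
        scalar evaluation of the closed form."""
        wbc = catalog["WBC"]
        R, t = 6e-6, 7e-9
        g3 = (R / (R - t)) ** 3
        sc, sm = 0.18, 9e-6
        delta = (sc - sm) / (sc + 2 * sm)
        sigma_oracle = sm * (g3 + 2 * delta) / (g3 - delta)
        eff = shell_effective_permittivity(wbc, 0.0)
        assert eff.sigma == pytest.approx(sigma_oracle, rel=1e-12)
        # thin, poorly conducting shell suppresses the DC conductivity
        assert eff.sigma < 0.1 * sc


class TestClausiusMossotti:
    def test_matched_particle_is_zero(self):
        w = 2 * np.pi * 1e5
        m = MediumProps(electrical_conductivity=0.1, relative_permittivity=60.0)
        p = medium_complex_permittivity(m, w)
        assert clausius_mossotti_real(p, p, w) == 0.0

    def test_dc_limit_equals_conductivity_contrast(self, catalog, medium):
        """omega -> 0 tends to (sp - sm)/(sp + 2 sm)."""
        cell = catalog["CTC"]
        k_dc = species_cmf(cell, medium, 0.0)
        k_small = species_cmf(cell, medium, 1e-3)
        eff = shell_effective_permittivity(cell, 0.0)
        sm = medium.electrical_conductivity
        expected = (eff.sigma - sm) / (eff.sigma + 2 * sm)
        assert k_dc == pytest.approx(expected, rel=1e-12)
        assert k_small == pytest.approx(expected, rel=1e-6)

    def test_high_frequency_limit_equals_permittivity_contrast(self, medium):
        cell = make_cell()
        w = 2 * np.pi * 1e12
        eff = shell_effective_permittivity(cell, w)
        k = species_cmf(cell, medium, w)
        ep, em = eff.eps, medium.permittivity
        assert k == pytest.approx((ep - em) / (ep + 2 * em), rel=1e-4)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        d=st.floats(0.5, 40.0),
        t=st.floats(3.0, 12.0),
        sc=st.floats(1e-4, 2.0),
        sm=st.floats(1e-8, 1e-3),
        ec=st.floats(2.0, 120.0),
        em=st.floats(2.0, 30.0),
        sigma_med=st.floats(1e-4, 2.0),
        eps_med=st.floats(2.0, 120.0),
        log_f=st.floats(0.0, 9.0),
    )
    def test_cmf_bounded(self, d, t, sc, sm, ec, em, sigma_med, eps_med, log_f):
        """Re[K] stays in [-1/2, 1] for any physical parameter draw."""
        cell = make_cell(d=d, t=t, sc=sc, sm=sm, ec=ec, em=em)
        med = MediumProps(
            electrical_conductivity=sigma_med, relative_permittivity=eps_med
        )
        k = species_cmf(cell, med, 2 * np.pi * 10**log_f)
        assert -0.5 - 1e-9 <= k <= 1.0 + 1e-9


class TestForce:
    def test_uniform_field_zero_force(self, catalog, medium):
        f = dep_force(catalog["CTC"], medium, np.zeros(2), 2 * np.pi * 96e3)
        assert np.all(f == 0.0)

    def test_cubic_radius_scaling(self, medium):
        """Doubling Rp at identical dielectric contrast (membrane scaled
        with the radius so the shell reduction is unchanged) multiplies
        the force by exactly 8."""
        w = 2 * np.pi * 96e3
        small = make_cell(d=6.0, t=7.0)
        big = make_cell(d=12.0, t=14.0)
        drive = np.array([1e14, 0.0])
        f_small = dep_force(small, medium, drive, w)
        f_big = dep_force(big, medium, drive, w)
        assert f_big[0] == pytest.approx(8.0 * f_small[0], rel=1e-9)

    def test_rms_convention_halves_amplitude_drive(self, catalog, medium):
        w = 2 * np.pi * 96e3
        drive = np.array([1e14, 0.0])
        amp = dep_force(catalog["WBC"], medium, drive, w, amplitude_drive=True)
        rms = dep_force(catalog["WBC"], medium, drive, w, amplitude_drive=False)
        assert amp[0] == pytest.approx(AC_TIME_AVERAGE * rms[0], rel=1e-12)

    def test_default_calibration_all_ndep_and_ordered(self, catalog, medium):
        """At the default buffer/frequency every species is repelled from
        the electrodes and |F_WBC| > |F_CTC| > |F_PLT|."""
        w = 2 * np.pi * 96e3
        ks = {s: species_cmf(catalog[s], medium, w) for s in catalog}
        assert all(k < 0 for k in ks.values())
        mags = {s: abs(ks[s]) * catalog[s].radius_m**3 for s in catalog}
        assert mags["WBC"] > mags["CTC"] > mags["PLT"]
        assert check_force_ordering(catalog, medium, w)

    def test_bad_configuration_logs_warning(self, catalog, caplog):
        import logging

        med = MediumProps(electrical_conductivity=0.01)
        with caplog.at_level(logging.WARNING):
            ok = check_force_ordering(catalog, med, 2 * np.pi * 15e3)
        assert not ok
        assert any("ordering" in r.message for r in caplog.records)


class TestForceAlongTrajectories:
    def test_time_maximum_force_ordering(self, optimum_fine):
        """Along the traced paths the peak DEP force orders
        WBC > CTC > PLT."""
        peaks = {}
        for tr in optimum_fine.trajectories:
            peaks.setdefault(tr.species, []).append(tr.dep_force_mag.max())
        assert np.mean(peaks["WBC"]) > np.mean(peaks["CTC"]) > np.mean(peaks["PLT"])

    def test_force_vanishes_outside_active_stage(self, optimum_fine):
        """|F_DEP|(t) is negligible before the cell reaches the array and
        collapses after it leaves the active stage."""
        g = optimum_fine.geometry
        corners = g.electrode_corners()
        x0, x1 = corners[:, 0].min(), corners[:, 0].max()
        for tr in optimum_fine.trajectories[::7]:
            inside = (tr.positions[:, 0] > x0 - 10) & (tr.positions[:, 0] < x1 + 10)
            if not inside.any() or inside.all():
                continue
            peak = tr.dep_force_mag.max()
            before = tr.positions[:, 0] < x0 - 30
            after = tr.positions[:, 0] > x1 + 30
            if before.any():
                assert tr.dep_force_mag[before].max() < 0.05 * peak
            if after.any():
                assert tr.dep_force_mag[after].max() < 0.05 * peak
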