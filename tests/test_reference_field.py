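"""Reference-field containers, synthesis, integrals and serialization."""

import math

import numpy as np
import pytest

from gcrsim import reference_field as rf
from gcrsim.reference_field import (
    ICRP60,
    QualityFactorModel,
    Spectrum,
    SynthFieldParams,
    dose_equivalent,
    integral_fluence,
    integrate_dose,
    load_field,
    normalized_dose_distribution,
    synth_field,
    tracks_per_cell,
    write_field,
)


class TestQualityFactor:
    def test_piecewise_values(self):
        # arithmetic on the housed ICRP-60 coefficients
        assert ICRP60(5.0) == 1.0
        assert ICRP60(10.0) == pytest.approx(1.0, abs=1e-9)  # continuous at L=10
        assert ICRP60(100.0) == pytest.approx(0.32 * 100 - 2.2)  # 29.8
        assert ICRP60(400.0) == pytest.approx(300.0 / math.sqrt(400.0))  # 15.0

    def test_maximum_near_100(self):
        L = np.geomspace(1.0, 1000.0, 500)
        q = ICRP60.q(L)
        assert L[np.argmax(q)] == pytest.approx(100.0, rel=0.02)

    def test_q_at_least_one_on_support(self):
        assert np.all(ICRP60.q(np.geomspace(0.1, 1000.0, 200)) >= 1.0 - 1e-12)


class TestSpectrum:
    def test_requires_four_points(self):
        with pytest.raises(ValueError, match="4"):
            Spectrum("energy", [1.0, 2.0], [1.0, 1.0])

    def test_requires_monotone_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum("energy", [1.0, 3.0, 2.0, 4.0], [1.0] * 4)

    def test_single_bin_integral_oracle(self):
        # flux concentrated in one narrow triangle: closed-form trapezoid area
        grid = np.array([10.0, 99.0, 100.0, 101.0, 1000.0])
        flux = np.array([0.0, 0.0, 5.0, 0.0, 0.0])
        spec = Spectrum("energy", grid, flux)
        # piecewise-linear in ln(x) of x*f: integral = sum of two triangles
        expected = 0.5 * (math.log(100 / 99) + math.log(101 / 100)) * 100.0 * 5.0
        assert integral_fluence(spec) == pytest.approx(expected, rel=0.005)

    def test_trapezoid_self_convergence(self, field0):
        spec = field0.hydrogen
        coarse = integral_fluence(spec)
        fine_grid = np.geomspace(spec.grid[0], spec.grid[-1], spec.grid.size * 10)
        fine_flux = np.exp(np.interp(np.log(fine_grid), np.log(spec.grid),
                                     np.log(np.maximum(spec.flux, 1e-300))))
        fine = integral_fluence(Spectrum("energy", fine_grid, fine_flux))
        assert coarse == pytest.approx(fine, rel=0.005)


class TestSynthField:
    def test_component_doses_match_requests(self, field0):
        doses = integrate_dose(field0)
        assert doses["hydrogen"] == pytest.approx(86.0, rel=0.01)
        assert doses["helium"] == pytest.approx(22.5, rel=0.01)
        assert doses["hze"] == pytest.approx(8.9, rel=0.01)
        assert doses["total"] == pytest.approx(134.0, rel=0.01)

    def test_same_seed_identical_different_seed_not(self, field0):
        again = synth_field(seed=0)
        assert np.array_equal(field0.hydrogen.flux, again.hydrogen.flux)
        other = synth_field(seed=1)
        assert not np.array_equal(field0.hydrogen.flux, other.hydrogen.flux)

    def test_dose_linearity_in_requested_doses(self, field0):
        params = SynthFieldParams(doses=tuple(
            (k, 2 * v) for k, v in rf.REFERENCE_COMPONENT_DOSES.items()))
        doubled = integrate_dose(synth_field(params, seed=0))
        base = integrate_dose(field0)
        for k in ("hydrogen", "helium", "hze"):
            assert doubled[k] == pytest.approx(2 * base[k], rel=0.01)

    def test_hze_spectrum_support_and_shape(self, field0):
        hze = field0.hze_let
        assert hze.grid[0] == pytest.approx(2.0)
        assert hze.grid[-1] == pytest.approx(1000.0)
        tail = hze.flux[hze.grid > 200.0]
        assert np.all(np.diff(tail) < 0)  # monotone decreasing above 200 keV/um

    def test_nonpositive_dose_rejected(self):
        params = SynthFieldParams(doses=(("pi_em", 15.5), ("neutron", 1.1),
                                         ("hydrogen", -1.0), ("helium", 22.5),
                                         ("hze", 8.9)))
        with pytest.raises(ValueError, match="positive"):
            synth_field(params, seed=0)


class TestIntegrals:
    def test_tracks_per_cell_reference_values(self, field0):
        t = tracks_per_cell(field0, sigma=100.0)
        assert t.tracks_per_year["hydrogen"] == pytest.approx(126.0, rel=0.10)
        assert t.tracks_per_year["helium"] == pytest.approx(7.0, rel=0.15)

    def test_tracks_linear_in_sigma(self, field0):
        t1 = tracks_per_cell(field0, sigma=100.0)
        t2 = tracks_per_cell(field0, sigma=200.0)
        for k in t1.tracks_per_year:
            assert t2.tracks_per_year[k] == pytest.approx(2 * t1.tracks_per_year[k])

    def test_solar_maximum_scaling_exact(self, field0):
        smax = field0.to_solar_maximum()
        d0, d1 = integrate_dose(field0), integrate_dose(smax)
        for k in ("hydrogen", "helium", "hze", "total"):
            assert d1[k] == pytest.approx(d0[k] / 1.85, rel=1e-12)
        assert smax.solar_scale == pytest.approx(1.0 / 1.85)

    def test_dose_equivalent_at_least_dose(self, field0):
        de = dose_equivalent(field0)
        d = integrate_dose(field0)
        for k in ("hydrogen", "helium", "hze"):
            assert de[k] >= d[k] * (1.0 - 1e-9)

    def test_dose_equivalent_equals_dose_below_q_threshold(self):
        # all flux at LET ~1 keV/um (protons near 100 MeV): Q = 1
        grid = np.array([90.0, 95.0, 100.0, 105.0, 110.0])
        flux = np.array([0.0, 0.0, 1e7, 0.0, 0.0])
        f = rf.ReferenceField(
            hydrogen=Spectrum("energy", grid, flux),
            helium=Spectrum("energy", grid, np.zeros(5)),
            neutron=Spectrum("energy", grid, np.zeros(5)),
            hze_let=Spectrum("let", np.array([2.0, 3.0, 4.0, 5.0]), np.zeros(4)),
        )
        assert dose_equivalent(f)["hydrogen"] == pytest.approx(
            integrate_dose(f)["hydrogen"], rel=1e-9)

    def test_zero_flux_zero_dose(self):
        grid = np.geomspace(1.0, 100.0, 8)
        zero = Spectrum("energy", grid, np.zeros(8))
        f = rf.ReferenceField(zero, zero, zero,
                              Spectrum("let", np.geomspace(2, 100, 8), np.zeros(8)))
        assert integrate_dose(f)["total"] == 0.0

    def test_normalized_distribution_arithmetic(self):
        # dropping pi/EM and neutron rows then scaling to 500 mGy
        out = normalized_dose_distribution(target_dose=500.0)
        assert out["hydrogen"] == pytest.approx(366.3, abs=0.05)
        assert out["helium"] == pytest.approx(95.8, abs=0.05)
        assert out["hze"] == pytest.approx(37.9, abs=0.05)
        assert out["pi_em"] == 0.0 and out["neutron"] == 0.0


class TestSerialization:
    def test_csv_round_trip_bit_identical(self, field0, tmp_path):
        p = tmp_path / "field.csv"
        write_field(field0, p)
        back = load_field(p)
        for attr in ("hydrogen", "helium", "neutron", "hze_let"):
            a, b = getattr(field0, attr), getattr(back, attr)
            assert np.array_equal(a.grid, b.grid)
            assert np.array_equal(a.flux, b.flux)
        assert back.component_doses == field0.component_doses

    def test_missing_columns_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x,y\n1,2\n")
        with pytest.raises(ValueError, match="component,abscissa,unit,flux"):
            load_field(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_field(tmp_path / "absent.csv")

    def test_xlsx_fuzzy_loader(self, field0, tmp_path):
        import pandas as pd
        p = tmp_path / "spectra.xlsx"
        with pd.ExcelWriter(p) as xl:
            for sheet, attr in (("Hydrogen flux", "hydrogen"), ("Helium flux", "helium"),
                                ("Neutron flux", "neutron"), ("HZE LET flux", "hze_let")):
                spec = getattr(field0, attr)
                pd.DataFrame({"abscissa": spec.grid, "flux": spec.flux}
                             ).to_excel(xl, sheet_name=sheet, index=False)
        back = load_field(p)
        assert np.allclose(back.hydrogen.flux, field0.hydrogen.flux)
        assert back.hze_let.abscissa_kind == "let"
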