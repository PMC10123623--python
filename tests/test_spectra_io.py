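import numpy as np
import pytest

import laurdanspec as ls
from laurdanspec.spectra_io import (
    SpectraFormatError,
    SpectraValidationError,
    to_wavelength,
)


def _simple_set(n_spots=2, wavelengths=(430.0, 440.0, 450.0)):
    wl = np.array(wavelengths)
    return ls.SpectrumSet(
        [
            ls.Spectrum(wl, np.array([1.0, 2.0, 3.0]) * (k + 1),
                        condition_kind="hydration", condition_value=50.0,
                        spot_id=f"spot{k}")
            for k in range(n_spots)
        ],
        axis_kind="hydration",
    )


class TestReadWrite:
    def test_long_table_groups_into_spectra(self, tmp_path):
        path = tmp_path / "six.csv"
        path.write_text(
            "condition_kind,condition_value,spot,wavelength_nm,intensity\n"
            "hydration,50,a,430,1.0\nhydration,50,a,440,2.0\nhydration,50,a,450,3.0\n"
            "hydration,50,b,430,2.0\nhydration,50,b,440,4.0\nhydration,50,b,450,6.0\n"
        )
        sset = ls.read_spectra(path)
        assert len(sset) == 2
        assert all(s.n_points == 3 for s in sset)
        assert sset.axis_kind == "hydration"

    def test_round_trip_preserves_values_exactly(self, tmp_path):
        original = _simple_set()
        # awkward float values exercise full-precision serialization
        original.spectra[0].intensities[1] = 1.0 / 3.0
        path = tmp_path / "rt.csv"
        ls.write_spectra(original, path)
        back = ls.read_spectra(path)
        assert len(back) == len(original)
        for a, b in zip(original, back):
            np.testing.assert_array_equal(a.wavelengths, b.wavelengths)
            np.testing.assert_array_equal(a.intensities, b.intensities)
            assert (a.condition_value, a.spot_id) == (b.condition_value, b.spot_id)

    def test_tsv_dialect_round_trip(self, tmp_path):
        path = tmp_path / "rt.tsv"
        ls.write_spectra(_simple_set(), path, dialect="tsv")
        assert len(ls.read_spectra(path, dialect="tsv")) == 2

    def test_negative_intensity_names_offending_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(
            "condition_kind,condition_value,spot,wavelength_nm,intensity\n"
            "hydration,50,a,430,1.0\nhydration,50,a,440,-2.5\n"
        )
        with pytest.raises(SpectraValidationError) as err:
            ls.read_spectra(path)
        msg = str(err.value)
        assert "-2.5" in msg and "440" in msg and "50" in msg and "a" in msg

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("condition_value,spot,wavelength_nm\n50,a,430\n")
        with pytest.raises(SpectraFormatError, match="intensity"):
            ls.read_spectra(path)

    def test_non_monotone_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "condition_kind,condition_value,spot,wavelength_nm,intensity\n"
            "hydration,50,a,430,1.0\nhydration,50,a,430,2.0\n"
        )
        with pytest.raises(SpectraValidationError, match="monotone|duplicated"):
            ls.read_spectra(path)

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        ls.write_spectra(ls.SpectrumSet([]), path)
        assert path.read_text().strip() == (
            "condition_kind,condition_value,spot,wavelength_nm,intensity"
        )

    def test_mixed_grids_rejected_at_construction(self):
        a = ls.Spectrum(np.array([430.0, 440.0]), np.array([1.0, 2.0]), spot_id="a")
        b = ls.Spectrum(np.array([430.0, 441.0]), np.array([1.0, 2.0]), spot_id="b")
        with pytest.raises(SpectraValidationError, match="share one wavelength grid"):
            ls.SpectrumSet([a, b])

    def test_duplicate_condition_spot_rejected(self):
        wl = np.array([430.0, 440.0])
        a = ls.Spectrum(wl, np.array([1.0, 2.0]), spot_id="a")
        with pytest.raises(SpectraValidationError, match="duplicate"):
            ls.SpectrumSet([a, a])


class TestCoordinateTransform:
    @pytest.mark.parametrize(
        "lam,expected", [(500.0, 20000.0), (427.0, 1e7 / 427.0)]
    )
    def test_wavenumber_arithmetic(self, lam, expected):
        s = ls.Spectrum(np.array([lam - 1, lam, lam + 1]), np.array([1.0, 2.0, 1.0]))
        wn = ls.to_wavenumber(s)
        assert np.any(np.isclose(wn.wavelengths, expected, rtol=1e-12))
        assert wn.wavelengths[0] < wn.wavelengths[-1]

    def test_involution_preserves_intensities(self, grid):
        rng = np.random.default_rng(3)
        s = ls.Spectrum(grid, rng.uniform(0, 5, grid.size))
        back = to_wavelength(ls.to_wavenumber(s))
        np.testing.assert_allclose(back.wavelengths, s.wavelengths, rtol=1e-14)
        np.testing.assert_array_equal(back.intensities, s.intensities)

    def test_jacobian_conserves_integral(self):
        # sub-nm grid: trapezoidal integrals agree to <= 1e-6 relative
        wl = np.arange(400.0, 600.0, 0.2)
        iy = np.exp(-((wl - 480.0) / 40.0) ** 2)
        s = ls.Spectrum(wl, iy)
        wn = ls.to_wavenumber(s, jacobian=True)
        i_wl = np.trapezoid(s.intensities, s.wavelengths)
        i_nu = np.trapezoid(wn.intensities, wn.wavelengths)
        assert abs(i_nu - i_wl) / i_wl < 1e-6

    def test_jacobian_roundtrip_restores_intensities(self, grid):
        s = ls.Spectrum(grid, np.ones(grid.size))
        back = to_wavelength(ls.to_wavenumber(s, jacobian=True), jacobian=True)
        np.testing.assert_allclose(back.intensities, s.intensities, rtol=1e-12)


class TestResample:
    def test_linear_interpolation_onto_reference(self):
        s = ls.Spectrum(np.array([400.0, 500.0]), np.array([0.0, 10.0]))
        out = ls.resample(s, np.array([425.0, 450.0, 475.0]))
        np.testing.assert_allclose(out.intensities, [2.5, 5.0, 7.5])

    def test_refuses_extrapolation(self):
        s = ls.Spectrum(np.array([400.0, 500.0]), np.array([0.0, 10.0]))
        with pytest.raises(SpectraValidationError, match="extrapolate"):
            ls.resample(s, np.array([390.0, 450.0]))
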