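import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cd2struct import (
    CDSpectrum,
    InvalidParameterError,
    OutOfRangeError,
    concentration_from_absorbance,
    normalize_to_delta_epsilon,
    read_spectrum,
    resample_to_grid,
    write_spectrum,
)

WL = np.array([180.0, 200.0, 220.0, 240.0])


class TestNormalizeToDeltaEpsilon:
    def test_zero_signal_gives_zero_delta_epsilon(self):
        s = normalize_to_delta_epsilon(
            WL, np.zeros(4), path_length_cm=0.005, concentration_mg_ml=1.1, mrw=110
        )
        assert np.all(s.values == 0)

    def test_hand_computed_unit_conversion(self):
        # θ=10 mdeg, MRW=110 g/mol, 50 μm cell, 1.1 mg/mL:
        # Δε = 10·110/(32980·0.005·1.1) = 6.06428... M⁻¹cm⁻¹ (hand conversion
        # via [θ]_MRE = θ·MRW/(10·l·c) = 200000 deg·cm²/dmol, /3298)
        s = normalize_to_delta_epsilon(
            WL, np.full(4, 10.0), path_length_cm=0.005, concentration_mg_ml=1.1, mrw=110
        )
        assert s.values == pytest.approx(10 * 110 / (32980 * 0.005 * 1.1))
        assert s.values == pytest.approx(6.0643, abs=1e-4)

    @given(scale=st.floats(0.5, 4.0))
    def test_linear_in_theta_inverse_in_path_and_concentration(self, scale):
        theta = np.array([5.0, -3.0, 1.5, 0.2])
        base = normalize_to_delta_epsilon(
            WL, theta, path_length_cm=0.01, concentration_mg_ml=1.0, mrw=105
        )
        doubled_theta = normalize_to_delta_epsilon(
            WL, scale * theta, path_length_cm=0.01, concentration_mg_ml=1.0, mrw=105
        )
        scaled_conc = normalize_to_delta_epsilon(
            WL, theta, path_length_cm=0.01, concentration_mg_ml=scale, mrw=105
        )
        scaled_path = normalize_to_delta_epsilon(
            WL, theta, path_length_cm=0.01 * scale, concentration_mg_ml=1.0, mrw=105
        )
        np.testing.assert_allclose(doubled_theta.values, scale * base.values)
        np.testing.assert_allclose(scaled_conc.values, base.values / scale)
        np.testing.assert_allclose(scaled_path.values, base.values / scale)

    @pytest.mark.parametrize("kwargs", [
        {"path_length_cm": 0.0}, {"concentration_mg_ml": -1.0}, {"mrw": 0.0},
    ])
    def test_nonpositive_parameters_rejected(self, kwargs):
        full = {"path_length_cm": 0.01, "concentration_mg_ml": 1.0, "mrw": 110}
        full.update(kwargs)
        with pytest.raises(InvalidParameterError):
            normalize_to_delta_epsilon(WL, np.ones(4), **full)


class TestConcentrationFromAbsorbance:
    def test_zero_absorbance_gives_zero(self):
        assert concentration_from_absorbance(0.0, 3.74) == 0.0

    def test_round_trip_tagged_stock(self):
        # E1% = 3.74, 1 cm: A280 = 0.4114 corresponds to a 1.1 mg/mL stock
        assert concentration_from_absorbance(0.4114, 3.74, 1.0) == pytest.approx(1.1, abs=1e-4)

    def test_isolated_tag_stock(self):
        # E1% = 1.99: A280 = 0.1194 gives the 0.6 mg/mL stock
        assert concentration_from_absorbance(0.1194, 1.99, 1.0) == pytest.approx(0.6)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            concentration_from_absorbance(0.5, 0.0)
        with pytest.raises(InvalidParameterError):
            concentration_from_absorbance(0.5, 1.99, -1.0)


class TestCDSpectrumInvariants:
    def test_descending_input_normalized_ascending_and_remembered(self):
        s = CDSpectrum(WL[::-1].copy(), np.array([1.0, 2.0, 3.0, 4.0]))
        assert s.wavelengths[0] < s.wavelengths[-1]
        assert s.meta["input_descending"] is True
        assert s.values[0] == 4.0  # value stays paired with its wavelength

    def test_non_monotone_rejected(self):
        with pytest.raises(InvalidParameterError):
            CDSpectrum(np.array([180.0, 200.0, 190.0]), np.zeros(3))

    def test_out_of_band_wavelengths_rejected(self):
        with pytest.raises(OutOfRangeError):
            CDSpectrum(np.array([150.0, 200.0]), np.zeros(2))

    def test_insane_amplitude_rejected(self):
        with pytest.raises(InvalidParameterError):
            CDSpectrum(WL, np.array([0.0, 1000.0, 0.0, 0.0]))


class TestResample:
    def test_identity_on_own_grid(self):
        s = CDSpectrum(WL, np.array([1.0, -2.0, 3.0, 0.5]))
        r = resample_to_grid(s, WL)
        np.testing.assert_array_equal(r.values, s.values)

    def test_midpoint_of_a_line(self):
        s = CDSpectrum(np.array([175.0, 185.0]), np.array([0.0, 10.0]))
        r = resample_to_grid(s, np.array([175.0, 180.0, 185.0]))
        assert r.values[1] == pytest.approx(5.0)

    def test_piecewise_linear_round_trip_exact(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=WL.size)
        s = CDSpectrum(WL, vals)
        fine = resample_to_grid(s, np.arange(180.0, 240.5, 0.5))
        back = resample_to_grid(fine, WL)
        np.testing.assert_allclose(back.values, vals, atol=1e-12)

    def test_idempotent_on_own_output_grid(self):
        s = CDSpectrum(WL, np.array([1.0, -2.0, 3.0, 0.5]))
        grid = np.array([185.0, 205.0, 231.0])
        once = resample_to_grid(s, grid)
        twice = resample_to_grid(once, grid)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_extrapolation_refused(self):
        s = CDSpectrum(WL, np.zeros(4))
        with pytest.raises(OutOfRangeError):
            resample_to_grid(s, np.array([170.0, 200.0]))


class TestSpectrumIO:
    def test_round_trip(self, tmp_path):
        s = CDSpectrum(WL, np.array([1.25, -2.5, 3.0, 0.5]), {"name": "x"})
        path = tmp_path / "s.tsv"
        write_spectrum(s, path)
        r = read_spectrum(path)
        np.testing.assert_allclose(r.values, s.values)
        np.testing.assert_allclose(r.wavelengths, s.wavelengths)
        assert r.meta["name"] == "x"

    def test_mdeg_units_converted_on_read(self, tmp_path):
        path = tmp_path / "raw.tsv"
        path.write_text(
            "# units: mdeg\n# path_length_cm: 0.005\n"
            "# concentration_mg_ml: 1.1\n# mrw: 110\n"
            "200 10\n210 10\n"
        )
        s = read_spectrum(path)
        assert s.values == pytest.approx(10 * 110 / (32980 * 0.005 * 1.1))

    def test_mdeg_without_metadata_rejected(self, tmp_path):
        path = tmp_path / "raw.tsv"
        path.write_text("# units: mdeg\n200 10\n210 10\n")
        with pytest.raises(InvalidParameterError):
            read_spectrum(path)
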