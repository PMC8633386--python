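import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metamel import colorimetry as cm
from metamel.colorimetry import Spectrum
from metamel.tables import D65_SPD, WAVELENGTHS, planck_spd

from .oracles import (
    brute_force_cct_duv,
    trapz_illuminance,
    trapz_melanopic_irradiance,
)


def gaussian_mix(*peaks, amp=0.01):
    values = np.zeros(401)
    for peak, fwhm in peaks:
        sigma = fwhm / 2.355
        values += amp * np.exp(-0.5 * ((WAVELENGTHS - peak) / sigma) ** 2)
    return Spectrum(values)


MIXED = gaussian_mix((450, 20), (550, 30), (630, 20))


class TestSpectrum:
    def test_grid_contract(self):
        with pytest.raises(cm.GridError):
            Spectrum(np.ones(400))
        with pytest.raises(ValueError):
            Spectrum(-np.ones(401))
        spd = Spectrum(np.ones(401))
        with pytest.raises(ValueError):
            spd.values[0] = 2.0  # stored values are read-only

    def test_addition_and_scaling(self):
        both = MIXED + MIXED.scaled(2.0)
        assert np.allclose(both.values, 3.0 * MIXED.values)


class TestIlluminance:
    def test_zero_spectrum(self):
        assert cm.illuminance(Spectrum(np.zeros(401))) == 0.0

    def test_single_bin_at_555(self):
        values = np.zeros(401)
        values[555 - 380] = 1.0
        assert cm.illuminance(Spectrum(values)) == pytest.approx(683.002)

    def test_matches_trapezoid_oracle(self):
        ours = cm.illuminance(MIXED)
        ref = trapz_illuminance(MIXED.values)
        assert ours == pytest.approx(ref, rel=2e-3)


class TestMelanopic:
    def test_d65_edi_equals_its_illuminance(self):
        d65_100lx = cm.rescale_to_illuminance(cm.D65, 100.0)
        assert cm.melanopic_edi(d65_100lx) == pytest.approx(100.0, abs=0.5)

    def test_zero_spectrum(self):
        assert cm.melanopic_edi(Spectrum(np.zeros(401))) == 0.0

    def test_matches_integration_oracle(self):
        ours = cm.melanopic_edi(MIXED)
        ref = trapz_melanopic_irradiance(MIXED.values) / cm.MELANOPIC_EFFICACY_D65
        assert ours == pytest.approx(ref, rel=2e-3)

    def test_efficacy_constant_matches_standard_value(self):
        # CIE S 026 tabulates 1.3262 mW/lm for the D65 conversion
        assert cm.MELANOPIC_EFFICACY_D65 == pytest.approx(1.3262e-3, rel=1e-3)

    def test_der_of_d65_is_one(self):
        assert cm.melanopic_der(cm.D65) == pytest.approx(1.0, abs=0.002)

    def test_der_scale_invariance(self):
        assert cm.melanopic_der(MIXED.scaled(7.3)) == cm.melanopic_der(MIXED)

    def test_edi_from_der_and_illuminance(self):
        # a DER-0.8 source at 500 lx delivers a melanopic EDI of 400 lx
        gamma = 0.8
        e_v = 500.0
        assert gamma * e_v == pytest.approx(400.0)
        spd = cm.rescale_to_illuminance(MIXED, e_v)
        assert cm.melanopic_edi(spd) == pytest.approx(
            e_v * cm.melanopic_der(spd), rel=1e-12
        )

    def test_der_undefined_for_zero(self):
        with pytest.raises(cm.DegenerateSpectrumError):
            cm.melanopic_der(Spectrum(np.zeros(401)))

    @given(
        a=st.floats(0.1, 10.0), b=st.floats(0.1, 10.0),
        seed=st.integers(0, 2 ** 16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_edi_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x1, x2 = rng.uniform(0.0, 1.0, (2, 401))
        lhs = cm.melanopic_edi(Spectrum(a * x1 + b * x2))
        rhs = a * cm.melanopic_edi(Spectrum(x1)) + b * cm.melanopic_edi(
            Spectrum(x2)
        )
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestChromaticity:
    def test_equal_energy_point(self):
        chrom = cm.chromaticity(Spectrum(np.ones(401)))
        assert chrom.x == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert chrom.y == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_d65_tabulated_point(self):
        chrom = cm.chromaticity(cm.D65)
        assert chrom.x == pytest.approx(0.3127, abs=1e-3)
        assert chrom.y == pytest.approx(0.3290, abs=1e-3)

    def test_projective_invariance(self):
        a = cm.chromaticity(MIXED)
        b = cm.chromaticity(MIXED.scaled(5.0))
        assert np.allclose(a, b, rtol=1e-13, atol=0.0)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(cm.DegenerateSpectrumError):
            cm.chromaticity(Spectrum(np.zeros(401)))

    def test_uv_prime_xy_round_trip(self):
        chrom = cm.chromaticity(MIXED)
        x, y = cm.xy_from_uv_prime(chrom.u_prime, chrom.v_prime)
        assert (x, y) == (
            pytest.approx(chrom.x, abs=1e-12),
            pytest.approx(chrom.y, abs=1e-12),
        )


class TestCctDuv:
    def test_planckian_points_recovered(self):
        for cct in (2700.0, 3000.0, 5000.0, 7443.0):
            chrom = cm.locus_point(cct)
            got_cct, got_duv = cm.cct_duv(chrom.u_prime, chrom.v_prime)
            assert got_cct == pytest.approx(cct, abs=3.0)
            assert abs(got_duv) < 1e-4

    def test_d65_cct_and_duv(self):
        chrom = cm.chromaticity(cm.D65)
        cct, duv = cm.cct_duv(chrom.u_prime, chrom.v_prime)
        assert cct == pytest.approx(6504.0, abs=10.0)
        assert duv == pytest.approx(0.003, abs=0.001)

    def test_far_point_rejected(self):
        with pytest.raises(cm.CCTRangeError):
            cm.cct_duv(0.30, 0.40)

    def test_matches_brute_force_search(self, rng):
        from metamel.grid import duv_offset, planck_point

        for _ in range(20):
            cct = rng.uniform(2000.0, 10000.0)
            duv = rng.uniform(-0.048, 0.048)
            chrom = duv_offset(planck_point(cct), duv)
            ours = cm.cct_duv(chrom.u_prime, chrom.v_prime)
            ref = brute_force_cct_duv(chrom.u_prime, chrom.v_prime)
            assert ours[0] == pytest.approx(ref[0], abs=3.0)
            assert ours[1] == pytest.approx(ref[1], abs=2e-5)


class TestRescale:
    def test_exact_target(self):
        out = cm.rescale_to_illuminance(MIXED, 250.0)
        assert cm.illuminance(out) == pytest.approx(250.0, rel=1e-14)

    def test_identity(self):
        e_v = cm.illuminance(MIXED)
        out = cm.rescale_to_illuminance(MIXED, e_v)
        assert np.allclose(out.values, MIXED.values)

    def test_preserves_der_and_chromaticity(self):
        out = cm.rescale_to_illuminance(MIXED, 250.0)
        assert cm.melanopic_der(out) == pytest.approx(
            cm.melanopic_der(MIXED), rel=1e-14
        )
        assert np.allclose(
            cm.chromaticity(out), cm.chromaticity(MIXED), rtol=1e-13, atol=0.0
        )

    def test_zero_input_rejected(self):
        with pytest.raises(cm.DegenerateSpectrumError):
            cm.rescale_to_illuminance(Spectrum(np.zeros(401)), 250.0)


class TestMetricsRecord:
    def test_internal_consistency(self):
        rec = cm.spectrum_metrics(cm.rescale_to_illuminance(MIXED, 250.0))
        assert rec.e_mel == pytest.approx(rec.e_v * rec.gamma_mel, rel=1e-12)
        assert rec.e_v == pytest.approx(250.0)


def test_spectra_csv_round_trip(tmp_path):
    path = tmp_path / "spectra.csv"
    spectra = [Spectrum(D65_SPD, name="d65"),
               Spectrum(planck_spd(3000.0), name="p3000")]
    cm.spectra_to_csv(path, spectra)
    back = cm.spectra_from_csv(path)
    assert [s.name for s in back] == ["d65", "p3000"]
    assert np.allclose(back[0].values, D65_SPD)


def test_metrics_json_written(tmp_path):
    path = tmp_path / "metrics.json"
    cm.metrics_to_json(path, [cm.spectrum_metrics(cm.D65)], run="demo")
    import json

    payload = json.loads(path.read_text())
    assert payload["run"] == "demo"
    assert "table_versions" in payload
    assert payload["metrics"][0]["gamma_mel_D65"] == pytest.approx(1.0, abs=2e-3)
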