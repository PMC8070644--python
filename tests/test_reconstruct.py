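import logging

import numpy as np
import pytest

from spare_ppg.core import UniformSignal, segment
from spare_ppg.harmonics import HarmonicTriplet
from spare_ppg.preprocess import bandpass
from spare_ppg.reconstruct import (
    CODE_BITS,
    HarmonicCode,
    compression_ratio,
    decode_window,
    encode_window,
    extract_band,
    read_codes,
    reconstruct_window,
    write_codes,
)
from spare_ppg.spectral import fft_spectrum

FS = 125.0


def tone(freq_bpm, duration_s=20.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return UniformSignal(amp * np.cos(2 * np.pi * freq_bpm / 60.0 * t + phase), fs)


def true_triplet(f1=80.0, hw=10.0):
    return HarmonicTriplet(
        f1, 2 * f1, 3 * f1,
        bands=tuple((k * f1 - hw, k * f1 + hw) for k in (1, 2, 3)),
    )


class TestExtractBand:
    def test_in_band_tone_preserved(self):
        out = extract_band(tone(80.0), 76.0, 84.0)
        mid = out.samples[int(2 * FS) : -int(2 * FS)]
        # rms of a preserved unit tone is 1/sqrt(2)
        assert np.sqrt(np.mean(mid**2)) == pytest.approx(2**-0.5, rel=0.1)

    def test_tone_20bpm_outside_attenuated_40db(self):
        out = extract_band(tone(120.0), 76.0, 84.0)
        mid = out.samples[int(2 * FS) : -int(2 * FS)]
        assert np.sqrt(np.mean(mid**2)) <= 10 ** (-40 / 20) * np.sqrt(0.5)

    def test_zero_input(self):
        out = extract_band(tone(80.0, amp=0.0), 70.0, 90.0)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_invalid_band_errors(self):
        with pytest.raises(ValueError, match="band"):
            extract_band(tone(80.0), 90.0, 80.0)

    def test_too_narrow_band_widened_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="spare_ppg.reconstruct"):
            out = extract_band(tone(80.0), 79.9, 80.1)
        assert "narrower than realizable" in caplog.text
        mid = out.samples[int(2 * FS) : -int(2 * FS)]
        assert np.max(np.abs(mid)) > 0.5  # tone still extracted


class TestReconstructWindow:
    def _window(self, fixture):
        signal, _, _ = fixture
        return segment(bandpass(signal), 8.0)[2].signal

    def test_clean_pulse_train_low_mse(self, fixture_80bpm):
        w = self._window(fixture_80bpm)
        rec = reconstruct_window(w, true_triplet())
        assert np.mean((rec.samples - w.samples) ** 2) < 0.05 * np.var(w.samples)

    def test_out_of_band_tone_removed(self, fixture_80bpm):
        w = self._window(fixture_80bpm)
        t = np.arange(len(w)) / FS_FIXTURE
        spoiled = w.with_samples(
            w.samples + 5.0 * np.cos(2 * np.pi * 350 / 60.0 * t)
        )
        rec_clean = reconstruct_window(w, true_triplet())
        rec_spoiled = reconstruct_window(spoiled, true_triplet())
        assert np.mean((rec_spoiled.samples - rec_clean.samples) ** 2) < (
            0.01 * np.var(w.samples)
        )

    def test_zero_input(self):
        w = UniformSignal(np.zeros(1000), FS)
        rec = reconstruct_window(w, true_triplet())
        np.testing.assert_allclose(rec.samples, 0.0, atol=1e-12)

    def test_output_energy_concentrated_in_bands(self, fixture_80bpm):
        # re-extracting the output with the same bands must keep >= 95 %
        # of its energy: nearly nothing lives outside the band union
        w = self._window(fixture_80bpm)
        trip = true_triplet()
        rec = reconstruct_window(w, trip)
        again = reconstruct_window(rec, trip)
        assert np.sum(again.samples**2) >= 0.95 * np.sum(rec.samples**2)

    def test_requires_bands(self):
        with pytest.raises(ValueError, match="bands"):
            reconstruct_window(tone(80.0), HarmonicTriplet(80, 160, 240))


FS_FIXTURE = 64.0


class TestCodec:
    def test_known_tone_coefficients(self):
        y = tone(84.0, duration_s=8.0, amp=2.0)
        code = encode_window(y, HarmonicTriplet(84.0, 168.0, 252.0))
        assert abs(code.c1) == pytest.approx(2.0, rel=0.01)
        assert abs(code.c2) < 0.05
        assert abs(code.c3) < 0.05

    def test_zero_window(self):
        code = encode_window(tone(80.0, 8.0, amp=0.0), true_triplet())
        assert code.c1 == code.c2 == code.c3 == 0

    def test_phase_recovery(self):
        y = tone(84.0, duration_s=8.0, phase=0.7)
        code = encode_window(y, HarmonicTriplet(84.0, 168.0, 252.0))
        assert np.angle(code.c1) == pytest.approx(0.7, abs=0.05)

    def test_roundtrip_on_exact_harmonic_sum(self):
        f1 = 82.5
        t = np.arange(1000) / FS
        y = np.zeros(1000)
        for k, (a, ph) in enumerate([(1.0, 0.2), (0.5, 1.1), (0.25, -0.6)], start=1):
            y += a * np.cos(2 * np.pi * k * f1 / 60.0 * t + ph)
        sig = UniformSignal(y, FS)
        code = encode_window(sig, HarmonicTriplet(f1, 2 * f1, 3 * f1))
        back = decode_window(code, 8.0, FS)
        assert np.mean((back.samples - y) ** 2) / np.mean(y**2) < 1e-3

    def test_decode_with_only_fundamental(self):
        code = HarmonicCode(80.0, 1.0 + 0j, 0j, 0j)
        out = decode_window(code, 8.0, FS)
        t = np.arange(1000) / FS
        np.testing.assert_allclose(
            out.samples, np.cos(2 * np.pi * 80 / 60.0 * t), atol=1e-9
        )

    def test_roundtrip_of_synthetic_pulse(self, fixture_80bpm):
        signal, _, _ = fixture_80bpm
        w = segment(bandpass(signal), 8.0)[2].signal
        code = encode_window(w, HarmonicTriplet(80.0, 160.0, 240.0))
        back = decode_window(code, 8.0, w.fs)
        rel = np.mean((back.samples - w.samples) ** 2) / np.var(w.samples)
        assert rel < 0.01

    def test_codes_csv_roundtrip(self, tmp_path):
        codes = [
            HarmonicCode(80.0, 1 + 2j, 0.5 - 0.25j, 0.1 + 0j),
            HarmonicCode(92.5, -1 + 0j, 0j, 0.3 + 0.4j),
        ]
        path = tmp_path / "codes.csv"
        write_codes(codes, path)
        back = read_codes(path)
        for a, b in zip(codes, back):
            assert a.f1_bpm == pytest.approx(b.f1_bpm, rel=1e-6)
            for ca, cb in zip(a.coefficients, b.coefficients):
                assert ca == pytest.approx(cb, abs=1e-6)


class TestCompressionRatio:
    def test_printed_reference_points(self):
        assert compression_ratio(8, 125, 16) == pytest.approx(98.6, abs=0.05)
        assert compression_ratio(8, 32, 16) == pytest.approx(94.53, abs=0.005)

    def test_code_equal_to_raw_gives_zero(self):
        raw_bits = 8 * 125 * 16
        assert compression_ratio(8, 125, 16, code_bits=raw_bits) == 0.0

    def test_monotone_in_rate_and_depth(self):
        assert compression_ratio(8, 125, 16) > compression_ratio(8, 64, 16)
        assert compression_ratio(8, 125, 16) > compression_ratio(8, 125, 8)

    def test_default_code_is_seven_singles(self):
        assert CODE_BITS == 7 * 32

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compression_ratio(0, 125, 16)
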