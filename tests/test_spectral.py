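import numpy as np
import pytest

from spare_ppg.spectral import (
    SsrConvergenceError,
    fft_spectrum,
    ssr_spectrum,
    temporal_diff,
    window_spectra,
)
from spare_ppg.ssa import SsaDecomposition, ssa_decompose

FS = 125.0
N = 4096


def tone(freq_bpm, duration_s=8.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.cos(2 * np.pi * freq_bpm / 60.0 * t + phase)


def on_grid(freq_bpm, fs=FS, n=N):
    """Snap a BPM frequency onto the length-n spectral grid."""
    step = fs * 60.0 / n
    return round(freq_bpm / step) * step


def peak_bpm(spec):
    return spec.freqs_bpm[int(np.argmax(spec.amps))]


def top_local_maxima(spec, k=2):
    """Frequencies of the k largest local maxima (leakage-safe)."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(spec.amps)
    best = idx[np.argsort(spec.amps[idx])[-k:]]
    return np.sort(spec.freqs_bpm[best])


class TestTemporalDiff:
    def test_first_and_second_order(self):
        np.testing.assert_array_equal(temporal_diff([1, 3, 6, 10], 1), [2, 3, 4])
        np.testing.assert_array_equal(temporal_diff([1, 3, 6, 10], 2), [1, 1])

    def test_constant_gives_zeros(self):
        np.testing.assert_array_equal(temporal_diff(np.full(9, 4.2), 3), np.zeros(6))

    def test_length_errors(self):
        with pytest.raises(ValueError):
            temporal_diff([1.0, 2.0], 2)
        with pytest.raises(ValueError):
            temporal_diff([1.0, 2.0], 0)


class TestSsrSpectrum:
    def test_zero_input_zero_spectrum(self):
        spec = ssr_spectrum(np.zeros(256), FS, N)
        assert np.all(spec.amps == 0)

    def test_single_tone_sparse_recovery(self):
        f0 = on_grid(90.0)
        spec = ssr_spectrum(tone(f0), FS, N)
        assert peak_bpm(spec) == pytest.approx(f0, abs=1e-9)
        others = spec.amps.copy()
        # bins more than 2 grid steps from the tone must be tiny
        i0 = int(np.argmax(others))
        others[max(i0 - 2, 0) : i0 + 3] = 0
        assert np.max(others) < 0.05 * np.max(spec.amps)

    def test_two_tone_amplitude_ordering(self):
        f1, f2 = on_grid(80.0), on_grid(160.0)
        y = tone(f1) + 0.5 * tone(f2)
        spec = ssr_spectrum(y, FS, N)
        fft = fft_spectrum(y, FS, N)
        np.testing.assert_allclose(
            top_local_maxima(spec), top_local_maxima(fft), atol=1e-9
        )
        i1 = int(np.argmin(np.abs(spec.freqs_bpm - f1)))
        i2 = int(np.argmin(np.abs(spec.freqs_bpm - f2)))
        assert spec.amps[i1] > spec.amps[i2]

    def test_nonconvergence_raises_with_residual(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=256)
        with pytest.raises(SsrConvergenceError) as exc:
            ssr_spectrum(y, FS, N, max_iter=3, tol=1e-14)
        assert exc.value.residual_norm > 0


class TestFftSpectrum:
    def test_two_hz_tone_peaks_at_120_bpm(self):
        spec = fft_spectrum(tone(120.0), FS, N)
        assert peak_bpm(spec) == pytest.approx(120.0, abs=spec.freqs_bpm[1] * 2)

    def test_zero_input(self):
        assert np.all(fft_spectrum(np.zeros(100), FS, N).amps == 0)

    def test_on_grid_tone_energy_bookkeeping(self):
        # for an exactly on-grid tone the single-sided amplitude is 1 and
        # the signal energy is M * amp^2 / 2
        f0 = on_grid(100.0, n=1000)  # grid of the unpadded window
        y = tone(f0)
        spec = fft_spectrum(y, FS, N=1000)
        i0 = int(np.argmax(spec.amps))
        assert spec.amps[i0] == pytest.approx(1.0, rel=1e-6)
        assert np.sum(y**2) == pytest.approx(y.size * spec.amps[i0] ** 2 / 2, rel=1e-6)


class TestWindowSpectra:
    def test_single_component_equals_own_spectrum(self):
        y = tone(on_grid(80.0))
        dec = SsaDecomposition([y], [[0]], [])
        s_orig, s_diff = window_spectra(dec, FS, variant="fast", N=N)
        np.testing.assert_allclose(s_orig.amps, fft_spectrum(y, FS, N).amps)
        assert s_orig.kind == "original" and s_diff.kind == "differentiated"

    def test_disjoint_components_sum(self):
        z1, z2 = tone(on_grid(80.0)), 0.5 * tone(on_grid(200.0))
        dec = SsaDecomposition([z1, z2], [[0], [1]], [])
        s_orig, _ = window_spectra(dec, FS, variant="fast", N=N)
        for z, f in [(z1, 80.0), (z2, 200.0)]:
            own = fft_spectrum(z, FS, N)
            i = int(np.argmax(own.amps))
            assert s_orig.amps[i] == pytest.approx(own.amps[i], rel=0.05)

    def test_differentiation_tilts_amplitude_with_frequency(self):
        # the second difference amplifies each tone by (2 sin(pi f/fs))^2,
        # i.e. the higher harmonic is boosted ~4x relative to the
        # fundamental (the tilt that suppresses aperiodic content)
        f = on_grid(80.0)
        dec = SsaDecomposition([tone(f), tone(2 * f)], [[0], [1]], [])
        s_orig, s_diff = window_spectra(dec, FS, variant="fast", N=N)
        i1 = int(np.argmin(np.abs(s_orig.freqs_bpm - f)))
        i2 = int(np.argmin(np.abs(s_orig.freqs_bpm - 2 * f)))
        gain1 = s_diff.amps[i1] / s_orig.amps[i1]
        gain2 = s_diff.amps[i2] / s_orig.amps[i2]
        theory = lambda fb: (2 * np.sin(np.pi * fb / 60.0 / FS)) ** 2  # noqa: E731
        assert gain2 > gain1
        assert gain2 / gain1 == pytest.approx(theory(2 * f) / theory(f), rel=0.15)

    def test_amplitudes_sum_not_cancel(self):
        z = tone(on_grid(80.0))
        dec = SsaDecomposition([z, -z], [[0], [1]], [])
        s_orig, _ = window_spectra(dec, FS, variant="fast", N=N)
        single = fft_spectrum(z, FS, N).amps
        np.testing.assert_allclose(s_orig.amps, 2 * single, atol=1e-12)

    def test_linear_trend_vanishes_in_sdiff(self):
        trend = np.linspace(0.0, 5.0, 1000)
        dec = SsaDecomposition([trend], [[0]], [])
        s_orig, s_diff = window_spectra(dec, FS, variant="fast", N=N)
        assert np.max(s_diff.amps) < 1e-10 * max(np.max(s_orig.amps), 1.0)

    def test_ssr_fft_peak_agreement_on_grid(self):
        y = tone(on_grid(80.0)) + 0.5 * tone(on_grid(160.0))
        dec = ssa_decompose(y)
        spectra = {
            v: window_spectra(dec, FS, variant=v, N=N)[0] for v in ("spare", "fast")
        }
        np.testing.assert_allclose(
            top_local_maxima(spectra["spare"]),
            top_local_maxima(spectra["fast"]),
            atol=1e-9,
        )
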