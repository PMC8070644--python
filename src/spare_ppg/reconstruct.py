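"""Harmonic-band reconstruction and the seven-value window codec.

The cleaned window is the sum of three narrow bandpass extractions, one
per harmonic, with the band edges estimated from the original spectrum.
Since the bands are only a few BPM wide (a fraction of a Hz), any causal
minimum-order filter meeting a 60 dB stopband would need a settling time
longer than the 8-s window itself; the extraction is therefore done as
zero-phase frequency-domain masking (a brickwall gain with raised-cosine
transitions applied to the reflect-padded window), which is the
realizable limit of a delay-compensated narrow bandpass on short
segments.

The codec side exploits the same three-harmonic model: a full window
collapses to one scalar (the fundamental frequency) plus three complex
coefficients -- seven floating-point values.  At 32 bits each that is
224 bits against 16000 bits for 8 s of 16-bit samples at 125 Hz, a
98.6 % footprint reduction (94.53 % at 32 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import UniformSignal
from .harmonics import HarmonicTriplet

__all__ = [
    "HarmonicCode",
    "extract_band",
    "reconstruct_window",
    "encode_window",
    "decode_window",
    "compression_ratio",
    "write_codes",
    "read_codes",
]

logger = logging.getLogger(__name__)

_STOP_DB = 60.0
_PASS_DB = 1.0
_MIN_HALF_WIDTH_BPM = 1.0  # narrowest realizable band half-width
CODE_BITS = 7 * 32  # seven IEEE single-precision values


@dataclass(frozen=True)
class HarmonicCode:
    """Seven-value representation of one window: f1 plus c1..c3."""

    f1_bpm: float
    c1: complex
    c2: complex
    c3: complex

    def __post_init__(self) -> None:
        if not self.f1_bpm > 0:
            raise ValueError("fundamental frequency must be positive")

    @property
    def coefficients(self) -> tuple[complex, complex, complex]:
        return (self.c1, self.c2, self.c3)


def extract_band(
    window_signal: UniformSignal, band_lo_bpm: float, band_hi_bpm: float
) -> UniformSignal:
    """Zero-phase narrow bandpass extraction of one harmonic component.

    The window is reflect-padded to three times its length and filtered
    in the frequency domain with a unit-gain passband and raised-cosine
    transitions of 20 % of the band width (floor 1 BPM); stopband
    rejection beyond the transitions is total and the group delay is
    zero by construction.  Bands narrower than realizable are widened to
    the minimum width and a warning is logged.
    """
    fs = window_signal.fs
    nyq_bpm = fs / 2 * 60.0
    if not 0 < band_lo_bpm < band_hi_bpm < nyq_bpm:
        raise ValueError(
            f"band ({band_lo_bpm}, {band_hi_bpm}) BPM must lie inside "
            f"(0, {nyq_bpm}) BPM"
        )
    if band_hi_bpm - band_lo_bpm < 2 * _MIN_HALF_WIDTH_BPM:
        center = 0.5 * (band_lo_bpm + band_hi_bpm)
        logger.warning(
            "band (%.2f, %.2f) BPM narrower than realizable; widening to +/- %.1f BPM",
            band_lo_bpm, band_hi_bpm, _MIN_HALF_WIDTH_BPM,
        )
        band_lo_bpm = center - _MIN_HALF_WIDTH_BPM
        band_hi_bpm = center + _MIN_HALF_WIDTH_BPM
    x = window_signal.samples
    n = x.size
    pad = n
    xp = np.pad(x, pad, mode="reflect") if n > 1 else x
    N = xp.size
    f_bpm = np.abs(np.fft.fftfreq(N, 1.0 / fs)) * 60.0
    trans = max(0.2 * (band_hi_bpm - band_lo_bpm), _MIN_HALF_WIDTH_BPM)
    mask = ((f_bpm >= band_lo_bpm) & (f_bpm <= band_hi_bpm)).astype(float)
    lo_t = (f_bpm > band_lo_bpm - trans) & (f_bpm < band_lo_bpm)
    mask[lo_t] = 0.5 * (1 + np.cos(np.pi * (band_lo_bpm - f_bpm[lo_t]) / trans))
    hi_t = (f_bpm > band_hi_bpm) & (f_bpm < band_hi_bpm + trans)
    mask[hi_t] = 0.5 * (1 + np.cos(np.pi * (f_bpm[hi_t] - band_hi_bpm) / trans))
    y = np.fft.ifft(np.fft.fft(xp) * mask).real
    out = y[pad : pad + n] if n > 1 else y
    return window_signal.with_samples(out)


def reconstruct_window(
    window_signal: UniformSignal, triplet: HarmonicTriplet
) -> UniformSignal:
    """Sum of the three narrow-band extractions at the triplet's bands."""
    if len(triplet.bands) != 3:
        raise ValueError("triplet carries no bands; estimate peak widths first")
    total = np.zeros(len(window_signal))
    for lo, hi in triplet.bands:
        total += extract_band(window_signal, lo, hi).samples
    return window_signal.with_samples(total)


def encode_window(
    window_signal: UniformSignal, triplet: HarmonicTriplet
) -> HarmonicCode:
    """Project the window onto complex exponentials at k * f1, k = 1..3.

    The coefficients are computed by direct correlation at the exact
    (generally off-grid) harmonic frequencies, scaled so a pure cosine
    of amplitude A at k * f1 yields |c_k| = A and arg(c_k) its phase.
    """
    y = window_signal.samples
    M = y.size
    t = np.arange(M) / window_signal.fs
    coeffs = []
    for k in (1, 2, 3):
        f_hz = k * triplet.f1 / 60.0
        coeffs.append(2.0 / M * np.sum(y * np.exp(-2j * np.pi * f_hz * t)))
    return HarmonicCode(triplet.f1, *coeffs)


def decode_window(code: HarmonicCode, duration_s: float, fs: float) -> UniformSignal:
    """Rebuild a window from its seven-value code."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    for k, c in enumerate(code.coefficients, start=1):
        y += (c * np.exp(2j * np.pi * k * code.f1_bpm / 60.0 * t)).real
    return UniformSignal(y, fs)


def compression_ratio(
    duration_s: float,
    fs: float,
    bits_per_sample: int,
    code_bits: int = CODE_BITS,
) -> float:
    """Percent memory-footprint reduction of the codec vs. raw samples."""
    if duration_s <= 0 or fs <= 0 or bits_per_sample <= 0 or code_bits <= 0:
        raise ValueError("all arguments must be positive")
    raw_bits = duration_s * fs * bits_per_sample
    return 100.0 * (1.0 - code_bits / raw_bits)


def write_codes(codes: list[HarmonicCode], path: str | Path) -> None:
    """Write one CSV record per window (index, f1, re/im of c1..c3)."""
    rows = []
    for i, c in enumerate(codes):
        rows.append(
            {
                "window": i,
                "f1_bpm": np.float32(c.f1_bpm),
                "c1_re": np.float32(c.c1.real), "c1_im": np.float32(c.c1.imag),
                "c2_re": np.float32(c.c2.real), "c2_im": np.float32(c.c2.imag),
                "c3_re": np.float32(c.c3.real), "c3_im": np.float32(c.c3.imag),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_codes(path: str | Path) -> list[HarmonicCode]:
    df = pd.read_csv(path)
    return [
        HarmonicCode(
            float(r.f1_bpm),
            complex(r.c1_re, r.c1_im),
            complex(r.c2_re, r.c2_im),
            complex(r.c3_re, r.c3_im),
        )
        for r in df.itertuples()
    ]
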