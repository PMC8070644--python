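"""Bandpass prefiltering and the kurtosis signal-quality gate.

The raw PPG is bandpass filtered to 0.5-5 Hz before any other stage, to
remove baseline wander and components that cannot belong to the
pulsewave.  Cleaning then runs only on windows whose sample kurtosis
reaches the Gaussian value of 3: a clean quasi-sinusoidal pulse train is
platykurtic (kurtosis ~1.5-2), whereas motion spikes and noise push the
fourth moment up to and beyond the Gaussian level.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import PipelineConfig, UniformSignal, WindowSegment

__all__ = ["bandpass", "design_fir_bandpass", "kurtosis", "needs_cleaning"]

# transition widths of the prefilter, Hz (sharp low edge to separate
# baseline wander from the slowest plausible pulse rate)
_TRANS_LO_HZ = 0.2
_TRANS_HI_HZ = 1.0
_STOP_DB = 60.0
_PASS_RIPPLE_DB = 1.0


def design_fir_bandpass(
    fs: float,
    lo_hz: float,
    hi_hz: float,
    trans_lo_hz: float = _TRANS_LO_HZ,
    trans_hi_hz: float = _TRANS_HI_HZ,
) -> np.ndarray:
    """Design a minimum-order linear-phase FIR bandpass (Kaiser window).

    Stopband attenuation is 60 dB beyond the transition bands; an odd
    number of taps is forced so the group delay is an integer number of
    samples and can be compensated exactly by shifting.
    """
    if not lo_hz < hi_hz:
        raise ValueError("lo_hz must be below hi_hz")
    if hi_hz >= fs / 2:
        raise ValueError(
            f"upper band edge {hi_hz} Hz must lie below the Nyquist "
            f"frequency {fs / 2} Hz"
        )
    width = min(trans_lo_hz, trans_hi_hz)
    numtaps, beta = sps.kaiserord(_STOP_DB, width / (fs / 2))
    numtaps |= 1  # odd length -> integer group delay
    return sps.firwin(
        numtaps,
        [lo_hz, hi_hz],
        window=("kaiser", beta),
        pass_zero=False,
        fs=fs,
    )


def bandpass(
    signal: UniformSignal,
    lo_hz: float = 0.5,
    hi_hz: float = 5.0,
) -> UniformSignal:
    """Zero-lag 0.5-5 Hz style bandpass of a PPG record.

    The signal is reflect-padded by one filter length, filtered with a
    linear-phase FIR, shifted back by the (integer) group delay and
    trimmed, so the output is aligned sample-for-sample with the input.
    """
    taps = design_fir_bandpass(signal.fs, lo_hz, hi_hz)
    delay = (taps.size - 1) // 2
    pad = taps.size
    x = np.pad(signal.samples, pad, mode="reflect")
    y = sps.lfilter(taps, 1.0, x)
    out = y[pad + delay : pad + delay + len(signal)]
    return signal.with_samples(out)


def kurtosis(window: WindowSegment | UniformSignal | np.ndarray) -> float:
    """Pearson (non-excess) kurtosis m4 / m2**2 of the window samples.

    Returns 3 for Gaussian data; raises on zero variance, where the
    statistic is undefined.
    """
    if isinstance(window, WindowSegment):
        x = window.signal.samples
    elif isinstance(window, UniformSignal):
        x = window.samples
    else:
        x = np.asarray(window, dtype=float)
    if x.size < 4:
        raise ValueError("kurtosis needs at least 4 samples")
    if np.var(x) == 0:
        raise ValueError("kurtosis undefined for zero-variance input")
    return float(stats.kurtosis(x, fisher=False, bias=True))


def needs_cleaning(
    window: WindowSegment,
    threshold: float | None = None,
    config: PipelineConfig | None = None,
) -> bool:
    """True when the window's kurtosis reaches the cleaning threshold.

    Windows below the threshold are regular enough to output directly;
    equality triggers cleaning (the pass-through condition is strictly
    "less than").  ``threshold`` overrides the configured value.
    """
    if threshold is None:
        threshold = (config or PipelineConfig()).kurtosis_threshold
    return kurtosis(window) >= threshold
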