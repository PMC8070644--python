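"""End-to-end orchestration of the spectral peak recovery pipeline.

Stage order per window: prefilter -> kurtosis gate -> subspace
decomposition -> spectral estimation (sparse or FFT) -> harmonic triplet
selection against the ECG meanHR -> per-harmonic narrow-band
reconstruction.  Windows that the gate judges clean, and windows without
an HR reference, are passed through (prefiltered) unchanged and flagged
in the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import PipelineConfig, UniformSignal, attach_mean_hr, segment
from .delineate import delineate
from .harmonics import (
    HarmonicTriplet,
    candidate_sets,
    find_spectral_peaks,
    select_triplet,
    triplet_bands,
)
from .preprocess import bandpass, kurtosis
from .reconstruct import reconstruct_window
from .spectral import window_spectra
from .ssa import ssa_decompose

__all__ = ["WindowLog", "spare_filter", "estimate_hr_series"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowLog:
    """Per-window processing record."""

    index: int
    kurtosis: float
    gate_fired: bool
    mean_hr_bpm: float | None
    processed: bool
    triplet: HarmonicTriplet | None = None
    reason: str = ""


def _clamp_bands(
    triplet: HarmonicTriplet, lo_bpm: float, hi_bpm: float, min_half: float
) -> HarmonicTriplet:
    """Keep harmonic bands inside the prefilter passband (BPM)."""
    bands = []
    for (b_lo, b_hi), f in zip(triplet.bands, triplet.freqs):
        b_lo, b_hi = max(b_lo, lo_bpm), min(b_hi, hi_bpm)
        if b_hi - b_lo < 2 * min_half:  # degenerate after clipping
            center = min(max(f, lo_bpm + min_half), hi_bpm - min_half)
            b_lo, b_hi = center - min_half, center + min_half
        bands.append((b_lo, b_hi))
    return HarmonicTriplet(
        triplet.f1, triplet.f2, triplet.f3,
        bands=tuple(bands), fallback_used=triplet.fallback_used,
    )


def spare_filter(
    ppg: UniformSignal,
    beat_times: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[UniformSignal, list[WindowLog]]:
    """Clean a motion-corrupted PPG record.

    Returns the cleaned signal (same length as the input: processed
    windows concatenated, any partial tail passed through prefiltered)
    and the per-window log of gate decisions and selected triplets.
    """
    config = config or PipelineConfig()
    filtered = bandpass(ppg, config.band_lo_hz, config.band_hi_hz)
    windows = attach_mean_hr(
        segment(filtered, config.window_s), np.asarray(beat_times, dtype=float)
    )
    out = filtered.samples.copy()
    n_win = int(round(config.window_s * ppg.fs))
    nyq_bpm = ppg.fs / 2 * 60.0
    logs: list[WindowLog] = []
    for w in windows:
        k = kurtosis(w)
        fired = k >= config.kurtosis_threshold
        if not fired:
            logs.append(WindowLog(w.index, k, False, w.mean_hr_bpm, False,
                                  reason="clean"))
            logger.info("window %d: kurtosis %.2f below gate, passed through",
                        w.index, k)
            continue
        if not w.has_hr:
            logs.append(WindowLog(w.index, k, True, None, False,
                                  reason="missing HR reference"))
            logger.info("window %d: gate fired but no HR reference; passed "
                        "through", w.index)
            continue
        decomp = ssa_decompose(
            w.signal.samples,
            n_keep=config.n_eigentriples,
            sigma_ratio=config.sigma_ratio,
        )
        s_orig, s_diff = window_spectra(
            decomp, ppg.fs, variant=config.variant, N=config.n_grid
        )
        peaks = find_spectral_peaks(s_diff)
        sets = candidate_sets(
            peaks,
            w.mean_hr_bpm,
            p=config.p_candidates,
            fund_tol_bpm=config.fund_tol_bpm,
            amp_frac=config.amp_frac,
        )
        triplet = select_triplet(sets, w.mean_hr_bpm, config.ratio_tol)
        triplet = triplet_bands(s_orig, triplet, config.min_half_width_bpm)
        triplet = _clamp_bands(
            triplet,
            config.band_lo_hz * 60.0,
            min(config.band_hi_hz * 60.0, 0.99 * nyq_bpm),
            config.min_half_width_bpm,
        )
        rec = reconstruct_window(w.signal, triplet)
        start = w.index * n_win
        out[start : start + n_win] = rec.samples
        logs.append(WindowLog(w.index, k, True, w.mean_hr_bpm, True,
                              triplet=triplet))
        logger.info(
            "window %d: kurtosis %.2f, triplet (%.1f, %.1f, %.1f) BPM%s",
            w.index, k, triplet.f1, triplet.f2, triplet.f3,
            " [fallback]" if triplet.fallback_used else "",
        )
    return filtered.with_samples(out), logs


def estimate_hr_series(
    cleaned: UniformSignal, window_s: float = 8.0, step_s: float = 2.0
) -> np.ndarray:
    """Per-window HR (BPM) from the pulse periods of a delineated signal.

    Sliding windows of ``window_s`` advance by ``step_s``; each window's
    HR is 60 / mean(pulse periods whose midpoint lies inside).  Windows
    with no usable period are NaN.
    """
    if cleaned.duration_s < window_s:
        return np.empty(0)
    annot = delineate(cleaned)
    if annot.n_beats >= 2:
        peaks = annot.peaks
        pp = np.diff(peaks)
        mids = 0.5 * (peaks[:-1] + peaks[1:])
    else:
        pp = np.empty(0)
        mids = np.empty(0)
    t_end = cleaned.t0 + cleaned.duration_s
    starts = []
    s = cleaned.t0
    while s + window_s <= t_end + 1e-9:
        starts.append(s)
        s += step_s
    hr = np.full(len(starts), np.nan)
    for i, s in enumerate(starts):
        inside = (mids >= s) & (mids < s + window_s)
        if inside.any():
            hr[i] = 60.0 / float(np.mean(pp[inside]))
    return hr
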