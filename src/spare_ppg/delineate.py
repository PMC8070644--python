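"""Pulsewave delineation: per-beat fiducial points and biomarkers.

For each detected pulse the four fiducial points are located:

* systolic peak -- prominent local maximum of the signal;
* onset -- the local minimum preceding the peak (foot of the upstroke);
* maximum-slope point -- maximum of the first derivative on the
  upstroke between onset and peak;
* dicrotic point -- the most prominent local minimum between the peak
  and the next onset, falling back to the maximum of the second
  derivative when the notch is too shallow to form a minimum.

Peak detection uses an adaptive prominence threshold (a fraction of the
window's amplitude range), so delineation is amplitude-scale invariant.
The same delineator is applied to both arms of every comparison
(reference and processed signal), which is what makes the detection
scores meaningful even though the delineator itself is a generic
derivative-based design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import UniformSignal

__all__ = ["FiducialAnnotation", "delineate", "biomarkers", "write_annotation"]

logger = logging.getLogger(__name__)

_PROMINENCE_FRAC = 0.3
_MIN_PP_S = 60.0 / 220.0  # refractory distance: no pulse above 220 BPM


@dataclass(frozen=True)
class FiducialAnnotation:
    """Per-beat fiducial times (s) and the amplitudes needed downstream.

    Arrays are parallel, one entry per detected beat; a NaN dicrotic or
    width marks a beat where that feature could not be located.
    """

    onsets: np.ndarray
    slopes: np.ndarray
    peaks: np.ndarray
    dicrotics: np.ndarray
    onset_amps: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_amps: np.ndarray = field(default_factory=lambda: np.empty(0))
    half_widths: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_beats(self) -> int:
        return self.peaks.size

    def times(self, fiducial: str) -> np.ndarray:
        """Sorted finite times of one fiducial ('onset', 'slope', 'peak',
        'dicrotic')."""
        arr = {
            "onset": self.onsets,
            "slope": self.slopes,
            "peak": self.peaks,
            "dicrotic": self.dicrotics,
        }[fiducial]
        return np.sort(arr[np.isfinite(arr)])


def _empty_annotation() -> FiducialAnnotation:
    e = np.empty(0)
    return FiducialAnnotation(e, e, e, e, e, e, e)


def delineate(
    signal: UniformSignal, prominence_frac: float = _PROMINENCE_FRAC
) -> FiducialAnnotation:
    """Locate the four fiducial points of every pulse in the signal."""
    x = signal.samples
    fs = signal.fs
    if signal.duration_s < 2.0:
        raise ValueError("delineation needs at least 2 s of signal")
    rng = float(np.max(x) - np.min(x))
    if rng == 0.0:
        logger.warning("flat signal: no pulses found")
        return _empty_annotation()

    distance = max(1, int(round(_MIN_PP_S * fs)))
    peak_idx, _ = find_peaks(x, prominence=prominence_frac * rng, distance=distance)
    if peak_idx.size == 0:
        logger.warning("no pulses found")
        return _empty_annotation()

    min_idx, min_props = find_peaks(-x, prominence=0.0)
    min_prom = min_props.get("prominences", np.zeros(min_idx.size))
    dx = np.diff(x)

    onsets_i = np.empty(peak_idx.size, dtype=int)
    slopes_i = np.empty(peak_idx.size, dtype=int)
    dicrotic_t = np.full(peak_idx.size, np.nan)
    for b, p in enumerate(peak_idx):
        left = peak_idx[b - 1] if b > 0 else 0
        cands = min_idx[(min_idx > left) & (min_idx < p)]
        onsets_i[b] = cands[-1] if cands.size else left + int(np.argmin(x[left:p]))
        o = onsets_i[b]
        slopes_i[b] = o + int(np.argmax(dx[o:p])) if p > o else o

    for b, p in enumerate(peak_idx):
        right = onsets_i[b + 1] if b + 1 < peak_idx.size else x.size - 1
        if right - p < 2:
            continue
        sel = (min_idx > p) & (min_idx < right)
        if sel.any():
            # most prominent local min between peak and next onset
            j = min_idx[sel][int(np.argmax(min_prom[sel]))]
            dicrotic_t[b] = j
        else:
            # shallow notch: maximum of the second derivative
            d2 = np.diff(x, n=2)
            seg = d2[p : right - 1]
            if seg.size:
                dicrotic_t[b] = p + 1 + int(np.argmax(seg))
    dicrotic_t = signal.t0 + dicrotic_t / fs

    # width at half pulse amplitude, interpolated between samples
    half_widths = np.full(peak_idx.size, np.nan)
    for b, p in enumerate(peak_idx):
        o = onsets_i[b]
        level = x[o] + 0.5 * (x[p] - x[o])
        right = onsets_i[b + 1] if b + 1 < peak_idx.size else x.size - 1
        tl = _cross_time(x, p, o, level, fs, backward=True)
        tr = _cross_time(x, p, right, level, fs, backward=False)
        if tl is not None and tr is not None:
            half_widths[b] = tr - tl

    t0 = signal.t0
    return FiducialAnnotation(
        onsets=t0 + onsets_i / fs,
        slopes=t0 + slopes_i / fs,
        peaks=t0 + peak_idx / fs,
        dicrotics=dicrotic_t,
        onset_amps=x[onsets_i],
        peak_amps=x[peak_idx],
        half_widths=half_widths,
    )


def _cross_time(
    x: np.ndarray, start: int, stop: int, level: float, fs: float, backward: bool
) -> float | None:
    """Time where x crosses ``level`` walking from start toward stop."""
    step = -1 if backward else 1
    for i in range(start, stop, step):
        j = i + step
        if (x[i] - level) * (x[j] - level) <= 0 and x[i] != x[j]:
            frac = (level - x[i]) / (x[j] - x[i])
            return (i + step * frac) / fs
    return None


def biomarkers(annotation: FiducialAnnotation) -> pd.DataFrame:
    """Per-beat biomarkers from an annotation.

    PRT (pulse rising time) = peak - onset; PDT (pulse decreasing time)
    = next onset - peak; PP (pulse period) = peak-to-peak interval;
    PA (pulse amplitude) = peak amplitude - onset amplitude; PW (pulse
    width) = width at half PA.  Last-beat entries needing a successor
    are NaN.
    """
    if annotation.n_beats < 2:
        raise ValueError("need at least two beats for biomarkers")
    n = annotation.n_beats
    prt = annotation.peaks - annotation.onsets
    pdt = np.full(n, np.nan)
    pdt[:-1] = annotation.onsets[1:] - annotation.peaks[:-1]
    pp = np.full(n, np.nan)
    pp[:-1] = np.diff(annotation.peaks)
    pa = annotation.peak_amps - annotation.onset_amps
    return pd.DataFrame(
        {"PRT": prt, "PDT": pdt, "PA": pa, "PP": pp, "PW": annotation.half_widths}
    )


def write_annotation(annotation: FiducialAnnotation, path) -> None:
    """CSV with one row per beat: (beat, onset_s, slope_s, peak_s, dicrotic_s)."""
    pd.DataFrame(
        {
            "beat": np.arange(annotation.n_beats),
            "onset_s": annotation.onsets,
            "slope_s": annotation.slopes,
            "peak_s": annotation.peaks,
            "dicrotic_s": annotation.dicrotics,
        }
    ).to_csv(path, index=False)
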