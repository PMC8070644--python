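"""Harmonic relation estimation.

Given the per-window spectra and the ECG-derived mean heart rate
(meanHR), locate the fundamental, second and third harmonic peaks of the
pulsewave and estimate each peak's frequency band.  Candidate peaks are
taken from the differentiated spectrum ``s_diff`` (robust to aperiodic
drift); widths are read off the original spectrum ``s_orig``.

The fundamental candidates are the peaks within 10 BPM of meanHR
(amplitude-pruned at 20 % of the set maximum); second/third candidates
are the p = 3 peaks nearest 2x / 3x meanHR.  The selected triplet is the
one whose frequency ratios best approximate 2 and 3; if even the best
triplet misses the second-harmonic ratio by more than 0.3 (or a set is
empty), the method falls back to the exact harmonic ladder anchored at
meanHR itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import SpectralEstimate

__all__ = [
    "SpectralPeak",
    "HarmonicTriplet",
    "harmonic_frequency",
    "find_spectral_peaks",
    "candidate_sets",
    "select_triplet",
    "estimate_peak_width",
    "triplet_bands",
]

# a located s_diff peak may sit a few bins off the s_orig maximum
_SNAP_TOL_BPM = 5.0


@dataclass(frozen=True)
class SpectralPeak:
    """A local maximum of a spectrum, with an optional band around it."""

    freq_bpm: float
    amp: float
    band_lo_bpm: float | None = None
    band_hi_bpm: float | None = None


@dataclass(frozen=True)
class HarmonicTriplet:
    """Fundamental, second and third harmonic frequencies (BPM) and bands."""

    f1: float
    f2: float
    f3: float
    bands: tuple[tuple[float, float], ...] = ()
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if not self.f1 < self.f2 < self.f3:
            raise ValueError(
                f"harmonics must be ordered, got ({self.f1}, {self.f2}, {self.f3})"
            )
        if self.fallback_used and (self.f2 != 2 * self.f1 or self.f3 != 3 * self.f1):
            raise ValueError("fallback triplet must be the exact harmonic ladder")

    @property
    def freqs(self) -> tuple[float, float, float]:
        return (self.f1, self.f2, self.f3)


def harmonic_frequency(fund_bpm: float, n: int) -> float:
    """Frequency of the n-th harmonic of a fundamental, in BPM."""
    if fund_bpm <= 0 or n < 1:
        raise ValueError("need a positive fundamental and harmonic index >= 1")
    return n * fund_bpm


def find_spectral_peaks(s: SpectralEstimate) -> list[SpectralPeak]:
    """All local maxima of the spectrum, sorted by frequency.

    Plateaus count as a single peak at the plateau center.
    """
    if len(s) < 3:
        return []
    idx, _ = find_peaks(s.amps, plateau_size=1)
    return [SpectralPeak(float(s.freqs_bpm[i]), float(s.amps[i])) for i in idx]


def candidate_sets(
    peaks: list[SpectralPeak],
    mean_hr_bpm: float,
    p: int = 3,
    fund_tol_bpm: float = 10.0,
    amp_frac: float = 0.20,
) -> tuple[list[SpectralPeak], list[SpectralPeak], list[SpectralPeak]]:
    """Candidate peak sets for the three harmonics.

    Returns ``(Fund, Second, Third)``: peaks within ``fund_tol_bpm`` of
    meanHR (those below ``amp_frac`` of the set's largest amplitude are
    pruned), and the ``p`` peaks nearest 2x and 3x meanHR (ordered by
    distance).  Sets may be empty.
    """
    fund = [p_ for p_ in peaks if abs(p_.freq_bpm - mean_hr_bpm) < fund_tol_bpm]
    if fund:
        a_max = max(p_.amp for p_ in fund)
        fund = [p_ for p_ in fund if p_.amp >= amp_frac * a_max]

    def nearest(target: float) -> list[SpectralPeak]:
        return sorted(peaks, key=lambda q: abs(q.freq_bpm - target))[:p]

    return fund, nearest(2 * mean_hr_bpm), nearest(3 * mean_hr_bpm)


def select_triplet(
    sets: tuple[list[SpectralPeak], list[SpectralPeak], list[SpectralPeak]],
    mean_hr_bpm: float,
    ratio_tol: float = 0.3,
) -> HarmonicTriplet:
    """Pick the candidate triplet in the best harmonic relationship.

    Minimizes ``|f2/f1 - 2| + |f3/f1 - 3|`` over the cartesian product
    of the three sets (ties broken by larger summed amplitude).  Falls
    back to ``(meanHR, 2 meanHR, 3 meanHR)`` when a set is empty or the
    winner's second-harmonic ratio is off by more than ``ratio_tol``.
    """
    if mean_hr_bpm is None:
        raise ValueError("meanHR is required to select the harmonic triplet")
    fund, second, third = sets
    best = None
    for pf in fund:
        for ps in second:
            for pt in third:
                f1, f2, f3 = pf.freq_bpm, ps.freq_bpm, pt.freq_bpm
                if not f1 < f2 < f3:
                    continue
                obj = abs(f2 / f1 - 2.0) + abs(f3 / f1 - 3.0)
                amp = pf.amp + ps.amp + pt.amp
                if best is None or (obj, -amp) < (best[0], -best[1]):
                    best = (obj, amp, f1, f2, f3)
    if best is not None:
        _, _, f1, f2, f3 = best
        if abs(f2 / f1 - 2.0) <= ratio_tol:
            return HarmonicTriplet(f1, f2, f3)
    return HarmonicTriplet(
        mean_hr_bpm, 2.0 * mean_hr_bpm, 3.0 * mean_hr_bpm, fallback_used=True
    )


def estimate_peak_width(
    s_orig: SpectralEstimate,
    freq_bpm: float,
    min_half_width_bpm: float = 2.0,
) -> tuple[float, float]:
    """Band of a spectral peak from sign changes of the spectrum's slope.

    The query frequency (typically located on the differentiated
    spectrum) is first snapped to the nearest local maximum of
    ``s_orig`` within a few BPM; each band edge is the nearest local
    minimum of the amplitude (zero crossing of its first difference) on
    that side, clipped to the grid.  A minimum half-width keeps the
    downstream bandpass realizable.
    """
    freqs, amps = s_orig.freqs_bpm, s_orig.amps
    if not freqs[0] <= freq_bpm <= freqs[-1]:
        raise ValueError(f"frequency {freq_bpm} BPM outside the spectral grid")
    i = int(np.argmin(np.abs(freqs - freq_bpm)))
    # snap to the nearest local max within the tolerance
    peak_idx, _ = find_peaks(amps, plateau_size=1)
    if peak_idx.size:
        j = peak_idx[np.argmin(np.abs(freqs[peak_idx] - freq_bpm))]
        if abs(freqs[j] - freq_bpm) <= _SNAP_TOL_BPM:
            i = int(j)
    d = np.diff(amps)
    # left edge: last index l <= i-1 where the difference turns non-positive
    lo = 0
    for k in range(i - 1, -1, -1):
        if d[k] <= 0:
            lo = k + 1
            break
    hi = freqs.size - 1
    for k in range(i, d.size):
        if d[k] >= 0:
            hi = k
            break
    band_lo = min(float(freqs[lo]), freq_bpm - min_half_width_bpm)
    band_hi = max(float(freqs[hi]), freq_bpm + min_half_width_bpm)
    return max(band_lo, float(freqs[0])), min(band_hi, float(freqs[-1]))


def triplet_bands(
    s_orig: SpectralEstimate,
    triplet: HarmonicTriplet,
    min_half_width_bpm: float = 2.0,
) -> HarmonicTriplet:
    """Attach per-harmonic bands (from ``s_orig``) to a triplet."""
    bands = tuple(
        estimate_peak_width(s_orig, f, min_half_width_bpm) for f in triplet.freqs
    )
    return HarmonicTriplet(
        triplet.f1, triplet.f2, triplet.f3, bands=bands,
        fallback_used=triplet.fallback_used,
    )
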