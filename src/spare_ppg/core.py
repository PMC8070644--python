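"""Shared domain types, windowing, configuration, and signal file I/O.

Every processing stage operates on :class:`UniformSignal` (a uniformly
sampled real-valued time series) cut into fixed-length
:class:`WindowSegment` objects, each optionally annotated with the mean
heart rate derived from simultaneous ECG RR intervals.  Frequencies are
expressed in BPM (beats per minute, 1 Hz = 60 BPM) throughout, because
heart-rate references and harmonic candidates live on that scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UniformSignal",
    "WindowSegment",
    "SpectralEstimate",
    "PipelineConfig",
    "segment",
    "attach_mean_hr",
    "read_signal_csv",
    "write_signal_csv",
    "read_record",
    "write_record",
    "read_beat_times",
    "write_beat_times",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples:
        Signal values in arbitrary units.
    fs:
        Sampling rate in Hz, strictly positive.
    t0:
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds (number of samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "UniformSignal":
        """Return a copy carrying ``samples`` with the same fs and t0."""
        return UniformSignal(np.asarray(samples, dtype=float), self.fs, self.t0)


# heart-rate sanity bounds in BPM used when attaching an ECG reference
_HR_LO_BPM = 30.0
_HR_HI_BPM = 220.0


@dataclass
class WindowSegment:
    """A fixed-duration slice of a signal, optionally with an HR reference.

    ``mean_hr_bpm`` is ``None`` when fewer than two ECG beats fell inside
    the window (the pipeline then passes the window through unprocessed).
    """

    signal: UniformSignal
    index: int
    duration_s: float = 8.0
    mean_hr_bpm: float | None = None

    def __post_init__(self) -> None:
        expected = self.duration_s * self.signal.fs
        if abs(len(self.signal) - expected) > 1:
            raise ValueError(
                f"window {self.index}: {len(self.signal)} samples inconsistent "
                f"with duration {self.duration_s} s at fs={self.signal.fs}"
            )
        if self.mean_hr_bpm is not None and not (
            _HR_LO_BPM < self.mean_hr_bpm < _HR_HI_BPM
        ):
            raise ValueError(
                f"mean_hr_bpm={self.mean_hr_bpm} outside plausible "
                f"({_HR_LO_BPM}, {_HR_HI_BPM}) BPM range"
            )

    @property
    def has_hr(self) -> bool:
        return self.mean_hr_bpm is not None


@dataclass(frozen=True)
class SpectralEstimate:
    """A nonnegative single-sided amplitude spectrum on a BPM grid.

    ``kind`` tags whether the spectrum was computed from the original
    window ("original") or from its second temporal difference
    ("differentiated"); the two play different roles downstream (peak
    width vs. peak location).
    """

    freqs_bpm: np.ndarray
    amps: np.ndarray
    kind: str = "original"

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs_bpm, dtype=float)
        amps = np.asarray(self.amps, dtype=float)
        if freqs.shape != amps.shape or freqs.ndim != 1:
            raise ValueError("freqs_bpm and amps must be 1-D and equally long")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs_bpm must be strictly increasing")
        if np.any(amps < 0):
            raise ValueError("amplitudes must be nonnegative")
        if self.kind not in ("original", "differentiated"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "freqs_bpm", freqs)
        object.__setattr__(self, "amps", amps)

    def __len__(self) -> int:
        return self.freqs_bpm.size


@dataclass
class PipelineConfig:
    """Tunable constants of the full pipeline.

    Defaults are the operating point of the method: a 0.5-5 Hz prefilter
    band, 8-s windows, the Gaussian kurtosis value 3 as quality gate,
    the 10 largest eigentriples in the subspace decomposition, 3
    harmonic candidates per set, a 10 BPM fundamental search tolerance,
    20 % amplitude pruning, and a 0.3 tolerance on the second-harmonic
    frequency ratio.
    """

    band_lo_hz: float = 0.5
    band_hi_hz: float = 5.0
    window_s: float = 8.0
    kurtosis_threshold: float = 3.0
    n_eigentriples: int = 10
    p_candidates: int = 3
    fund_tol_bpm: float = 10.0
    amp_frac: float = 0.20
    ratio_tol: float = 0.3
    delineation_tol_s: float = 0.15
    variant: str = "spare"
    # secondary numerical knobs (see docs/methods.md)
    sigma_ratio: float = 0.1  # eigentriple grouping closeness rho
    n_grid: int = 4096  # spectral grid size N
    min_half_width_bpm: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "band_lo_hz",
            "band_hi_hz",
            "window_s",
            "kurtosis_threshold",
            "fund_tol_bpm",
            "amp_frac",
            "ratio_tol",
            "delineation_tol_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.band_lo_hz < self.band_hi_hz:
            raise ValueError("band_lo_hz must be below band_hi_hz")
        if self.variant not in ("spare", "fast"):
            raise ValueError(f"variant must be 'spare' or 'fast', got {self.variant!r}")


def segment(
    signal: UniformSignal, window_s: float, step_s: float | None = None
) -> list[WindowSegment]:
    """Cut ``signal`` into fixed-length windows.

    Windows cover ``[t0 + k*step_s, t0 + k*step_s + window_s)``; a final
    partial window is dropped.  ``step_s`` defaults to ``window_s``
    (non-overlapping tiling).
    """
    if step_s is None:
        step_s = window_s
    if not 0 < step_s <= window_s:
        raise ValueError("step_s must satisfy 0 < step_s <= window_s")
    n_win = int(round(window_s * signal.fs))
    n_step = int(round(step_s * signal.fs))
    if n_win > len(signal):
        raise ValueError(
            f"signal of {signal.duration_s:.3f} s is shorter than one "
            f"{window_s} s window"
        )
    windows = []
    for k, start in enumerate(range(0, len(signal) - n_win + 1, n_step)):
        sub = UniformSignal(
            signal.samples[start : start + n_win],
            signal.fs,
            signal.t0 + start / signal.fs,
        )
        windows.append(WindowSegment(sub, index=k, duration_s=window_s))
    return windows


def attach_mean_hr(
    windows: Sequence[WindowSegment], rr_beat_times: Sequence[float]
) -> list[WindowSegment]:
    """Annotate each window with the ECG-derived mean heart rate.

    The reference is 60 / mean(RR intervals whose midpoint falls inside
    the window).  Windows containing fewer than two beats (hence no
    usable interval) are left with ``mean_hr_bpm = None``.
    """
    beats = np.asarray(rr_beat_times, dtype=float)
    if beats.size and np.any(np.diff(beats) <= 0):
        raise ValueError("beat times must be strictly increasing")
    out = []
    for w in windows:
        lo = w.signal.t0
        hi = w.signal.t0 + w.duration_s
        if beats.size >= 2:
            mids = 0.5 * (beats[:-1] + beats[1:])
            rr = np.diff(beats)
            inside = (mids >= lo) & (mids < hi)
        else:
            inside = np.zeros(0, dtype=bool)
        if inside.any():
            mean_hr = 60.0 / float(np.mean(rr[inside]))
        else:
            mean_hr = None
        out.append(
            WindowSegment(w.signal, w.index, w.duration_s, mean_hr_bpm=mean_hr)
        )
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_signal_csv(path: str | Path) -> UniformSignal:
    """Read a two-column (time_s, value) CSV.

    The sampling rate is inferred from the median time step; the time
    grid must be uniform to within 1 % of that step.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    x = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    step = float(np.median(dt))
    if step <= 0 or np.any(np.abs(dt - step) > 0.01 * step):
        raise ValueError(f"{path}: time grid is not uniform")
    return UniformSignal(x, fs=1.0 / step, t0=float(t[0]))


def write_signal_csv(signal: UniformSignal, path: str | Path) -> None:
    pd.DataFrame({"time_s": signal.times, "value": signal.samples}).to_csv(
        path, index=False
    )


def read_record(prefix: str | Path) -> UniformSignal:
    """Read a two-file plain-text record: ``<prefix>.hea`` + ``<prefix>.csv``.

    The header is ``key value`` lines and must define ``fs`` (Hz); ``t0``
    (seconds) is optional.  The CSV holds one sample value per line.
    """
    prefix = Path(prefix)
    header: dict[str, float] = {}
    for line in Path(f"{prefix}.hea").read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(" ")
        header[key] = float(val)
    if "fs" not in header:
        raise ValueError(f"{prefix}.hea: missing required 'fs' entry")
    samples = np.loadtxt(f"{prefix}.csv", dtype=float, ndmin=1)
    return UniformSignal(samples, fs=header["fs"], t0=header.get("t0", 0.0))


def write_record(signal: UniformSignal, prefix: str | Path) -> None:
    prefix = Path(prefix)
    Path(f"{prefix}.hea").write_text(f"fs {signal.fs}\nt0 {signal.t0}\n")
    np.savetxt(f"{prefix}.csv", signal.samples, fmt="%.10g")


def read_beat_times(path: str | Path) -> np.ndarray:
    """Read a one-column CSV of beat times in seconds."""
    beats = np.atleast_1d(np.loadtxt(path, dtype=float, delimiter=","))
    if beats.size and np.any(np.diff(beats) <= 0):
        raise ValueError(f"{path}: beat times must be strictly increasing")
    return beats


def write_beat_times(beats: Iterable[float], path: str | Path) -> None:
    np.savetxt(path, np.asarray(list(beats), dtype=float), fmt="%.6f")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a ``key = value`` configuration file into a PipelineConfig."""
    values: dict[str, object] = {}
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, eq, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if not eq or key not in fields:
            raise ValueError(f"{path}: unknown or malformed line {raw!r}")
        typ = fields[key].type
        if typ == "str" or key == "variant":
            values[key] = val
        elif typ == "int":
            values[key] = int(val)
        else:
            values[key] = float(val)
    return PipelineConfig(**values)  # type: ignore[arg-type]


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = [
        f"{f.name} = {getattr(config, f.name)}"
        for f in dataclasses.fields(PipelineConfig)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
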