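# spare-ppg

Spectral peak recovery for motion-corrupted photoplethysmogram (PPG)
signals, reconstructing the **full pulsewave** — not just the heart rate
— from a single PPG channel plus the mean heart rate derived from a
simultaneous ECG.

## Who this is for

Wearable-sensing and biosignal researchers who need PPG-derived
biomarkers (pulse rising/decreasing time, amplitude, width, dicrotic
timing) from recordings taken during movement, where motion artifacts
normally make everything but coarse heart-rate tracking impossible.

## The method

A quasi-periodic pulsewave with period T₀ admits a Fourier series

y(t) = a₀ + Σₙ aₙ cos(2πnt/T₀) + Σₙ bₙ sin(2πnt/T₀),

and in practice the first three harmonics carry nearly all of the PPG's
energy (at a resting 80 BPM the fourth harmonic sits at 320 BPM,
beyond the 0.5–5 Hz physiological band). The pipeline therefore cleans
each 8-s window by re-estimating and re-extracting exactly those three
components:

1. **Prefilter** — minimum-order linear-phase FIR bandpass, 0.5–5 Hz,
   60 dB stopband, delay-compensated.
2. **Quality gate** — a window is processed only when its Pearson
   kurtosis m₄/m₂² reaches 3 (the Gaussian value); clean pulse trains
   are platykurtic and pass through untouched.
3. **Decomposition** — singular spectrum analysis (SSA): SVD of the
   Hankel trajectory matrix (L = M/2), keep the 10 largest
   eigentriples, group by singular-value closeness, diagonal-average
   each group back to a time series.
4. **Spectral estimation** — per component, either a sparse
   ℓ1-regularized inversion of an M×N Fourier dictionary
   (x̂ = argmin ‖y − Φx‖² + λ‖x‖₁, solved by FISTA; the `spare`
   variant) or a zero-padded FFT (the `fast` variant). Component
   spectra are summed as amplitudes; peak *locations* are read from the
   spectrum of the second temporal difference (s_diff), peak *widths*
   from the undifferentiated spectrum (s_orig).
5. **Harmonic selection** — candidate peaks near meanHR, 2·meanHR and
   3·meanHR (the ECG reference) are combined into the triplet
   minimizing |f₂/f₁ − 2| + |f₃/f₁ − 3|; if the best triplet violates
   |f₂/f₁ − 2| ≤ 0.3 the exact ladder (meanHR, 2·meanHR, 3·meanHR) is
   used as a fallback.
6. **Reconstruction** — the three bands are extracted with zero-phase
   narrow bandpass masks and summed.

The same three-harmonic model yields a codec: one window compresses to
7 floating-point values (f₁ plus three complex coefficients), a 98.6 %
footprint reduction against 8 s of 16-bit samples at 125 Hz (94.53 % at
32 Hz).

The package also ships the evaluation apparatus: a Lanczos-kernel
motion-artifact generator with controllable σ, a pulsewave delineator
(onset, maximum slope, systolic peak, dicrotic point), tolerance-matched
detection scoring, and HR error metrics (AEmean, REmean, AEmedian).

## Worked example

```python
import numpy as np
from spare_ppg import (PipelineConfig, NoiseSpec, generate_ppg,
                       spare_filter, estimate_hr_series)
from spare_ppg.noisegen import corrupt
from spare_ppg.preprocess import bandpass
from spare_ppg.evaluate import mse, hr_errors

# 60 s of synthetic PPG at 64 Hz, constant 80 BPM, known beat times
clean, beats, true_hr = generate_ppg(60.0, fs=64.0, hr_trajectory_bpm=80.0, seed=0)

# corrupt with a motion artifact of sigma = 450 (moderate activity)
noisy = corrupt(clean, NoiseSpec(sigma=450.0, seed=1))

# run the FFT variant of the pipeline with the ECG beat reference
cleaned, logs = spare_filter(noisy, beats, PipelineConfig(variant="fast"))

reference = bandpass(clean)
print(f"windows cleaned : {sum(l.processed for l in logs)}/{len(logs)}")
print(f"MSE vs clean    : {mse(cleaned, reference):8.1f}  (pipeline)")
print(f"                  {mse(bandpass(noisy), reference):8.1f}  (prefilter only)")
for rec in logs:
    if rec.triplet:
        t = rec.triplet
        print(f"window {rec.index}: triplet ({t.f1:5.1f}, {t.f2:5.1f}, {t.f3:5.1f}) BPM")
```

prints

```
windows cleaned : 4/7
MSE vs clean    :     91.5  (pipeline)
                     256.1  (prefilter only)
window 0: triplet ( 80.6, 161.2, 240.0) BPM
window 4: triplet ( 81.6, 160.3, 247.5) BPM
window 5: triplet ( 79.7, 161.2, 240.0) BPM
window 6: triplet ( 80.6, 161.2, 240.9) BPM
```

The quality gate fired on four of the seven windows; on each of those
the recovered fundamental lies within ~1.6 BPM of the true 80 BPM, and
the reconstruction error against the clean signal is roughly a third of
what the prefilter alone leaves behind. The downstream HR series
improves accordingly (windows the gate judged clean keep their
corrupted content, which dominates the residual error):

```
HR error (pipeline      ): AEmean  36.92 BPM, REmean  46.16 %, AEmedian  40.00 BPM
HR error (prefilter only): AEmean  65.47 BPM, REmean  81.84 %, AEmedian  68.61 BPM
```

A command-line interface mirrors the library (`spare synth`,
`spare noise`, `spare filter`, `spare delineate`, `spare evaluate`,
`spare compress` / `spare decompress`); see `spare --help`.

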