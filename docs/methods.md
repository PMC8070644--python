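# Methods

## Signal model and scope

The pulsewave is modeled as locally periodic: within an 8-s window the
PPG is a sum of sinusoids at integer multiples of the pulse rate, and
the first three harmonics carry the reconstructable content. The window
length trades frequency resolution (longer is better) against local
periodicity (heart rate drifts); 8 s is the standard operating point in
the heart-rate-tracking literature and is used everywhere here. All
frequencies are handled in BPM (1 Hz = 60 BPM) because the external
reference — the mean heart rate from ECG RR intervals — lives on that
scale. Windows are processed non-overlapping and concatenated; an
overlap-add scheme was deliberately left out because stitching is not
part of the method's definition, and concatenation is the minimal
choice (window-boundary discontinuities are possible and visible in
reconstruction error at the edges).

The ECG side is an input, not a processing stage: beat times (or
per-window mean HR) are assumed available. meanHR per window is
60 / mean(RR intervals whose midpoint falls in the window); windows
containing fewer than two beats carry no reference and are passed
through unprocessed, flagged in the log, since harmonic selection is
anchored on meanHR.

## Prefilter and quality gate

The prefilter is a minimum-order linear-phase FIR (Kaiser design),
0.5–5 Hz passband, 60 dB stopband, transition 0.2 Hz at the low edge
and 1 Hz at the high edge, applied after reflect padding and
delay-compensated by an integer shift (taps forced odd). Linear phase
matters because pulse morphology is the deliverable. Note the filter's
impulse response is ~18 s; measurements of its steady-state response
need probes much longer than the filter.

The gate computes the Pearson kurtosis m₄/m₂² of each prefiltered
window and cleans only windows at or above 3 (the Gaussian value;
equality triggers cleaning because the pass-through condition is
strictly "below threshold"). Two facts shape its behavior:

* a clean quasi-sinusoidal pulse train is platykurtic (the default
  synthetic waveform measures ≈ 2.56), so clean windows pass through;
* sample kurtosis of a *smooth* correlated Gaussian process over 8 s is
  biased below 3 (few effective degrees of freedom), so the gate is
  deliberately insensitive to smooth near-Gaussian disturbance and
  fires mainly on spiky, impulsive corruption — which is exactly the
  in-band residue that survives the prefilter when the artifact's
  energy is dominated by baseline wander plus sharp transients.

## Sparse spectral estimation

Each SSA component (embedding L = ⌊M/2⌋, 10 retained eigentriples,
grouping of consecutive eigentriples whose singular-value ratio is
≥ 0.9, ratio configurable) is mapped to an amplitude spectrum on an
N = 4096 grid (≈ 0.94 BPM at 64 Hz, 1.83 BPM at 125 Hz) — fine enough
to resolve the 10-BPM fundamental search window and the 0.3 ratio
tolerance. The sparse estimator solves

x̂ = argmin ‖y − Φx‖₂² + λ‖x‖₁,  Φ[m, n] = e^{j2πmn/N},

with complex x. Because ΦΦᴴ = N·I, the gradient step size 1/(2N) is
exact and FISTA (with adaptive restart; all products are FFTs)
converges in a few hundred to a couple of thousand iterations;
convergence is declared when the iterate's relative change falls below
1e-5, and failure raises an error carrying the residual norm. λ
defaults to 0.1·‖Φᴴy‖∞, a scale-free choice that zeroes the broadband
floor while keeping genuine tones; neither the penalty nor λ is
prescribed by the method's definition, so both are configurable. The
fast variant replaces the solver with a zero-padded FFT (identical
amplitude convention: an on-grid unit sinusoid reads 1).

Component spectra are combined as sums of nonnegative amplitudes, not
complex sums — they are used only for peak location and width. Peak
locations come from the spectrum of the second temporal difference of
each component (head-padded with zeros to keep grids aligned). The
second difference multiplies a tone at frequency f by (2 sin(πf/fs))²,
i.e. amplification grows ~quadratically with frequency while constant
and linear drift vanish; the statement that differentiation "linearly"
boosts harmonics holds per differentiation order, and the second-order
gain ratio between 2f and f is ≈ 4, which the tests assert.

## Harmonic selection and bands

Candidates: all strict local maxima of s_diff (plateaus count once, at
their center). Fundamental candidates are the peaks within 10 BPM of
meanHR, pruned of peaks below 20 % of the set's largest amplitude;
second/third candidates are the p = 3 peaks nearest 2× and 3× meanHR
(not amplitude-pruned — the pruning rule is defined only for the
fundamental set). The selected triplet minimizes
|f₂/f₁ − 2| + |f₃/f₁ − 3|, ties broken by larger summed amplitude; only
the second-harmonic ratio participates in the accept/reject tolerance
(0.3), a literal reading of the method. On rejection or empty sets the
fallback (meanHR, 2·meanHR, 3·meanHR) is used and flagged.

Peak widths are estimated on s_orig: the query frequency is snapped to
the nearest local maximum within 5 BPM, and each band edge is the
nearest sign change of the spectrum's first difference. A minimum
half-width of 2 BPM keeps bands realizable, and bands are clipped to
the prefilter passband (the third harmonic of rates above 100 BPM
falls partly beyond the 5 Hz edge and is clipped to it).

## Narrow-band extraction

Any causal minimum-order filter with a 60 dB stopband around a few-BPM
band has a settling time far exceeding 8 s (a compliant Butterworth
design was measured to output essentially zero over a whole window),
so the extraction uses zero-phase frequency-domain masking: the window
is reflect-padded to 3× its length, multiplied in the frequency domain
by a unit-gain passband with raised-cosine transitions of 20 % of the
band width (floor 1 BPM), and inverse-transformed. Stopband rejection
beyond the transition is total and the delay is zero. The irreducible
error is spectral leakage of the 8-s truncation: reconstructing a
clean three-harmonic window with ±10 BPM bands leaves ≈ 5 % of the
window variance as error, concentrated at the window edges. Bands
narrower than ±1 BPM are widened to that minimum with a logged warning.

## Codec

A window encodes to f₁ plus three complex coefficients obtained by
direct correlation with complex exponentials at exactly k·f₁ (k = 1, 2,
3) — not FFT bins, since f₁ is generally off-grid. Decoding evaluates
Σ Re[c_k e^{j2πk(f₁/60)t}]. Stored as 7 IEEE single-precision values
(224 bits), giving the 98.6 % / 94.53 % footprint reductions for
8 s × 16 bit at 125 / 32 Hz. Round-trip error on an exact three-harmonic
window is below 0.1 %.

## Synthetic fixtures and the artifact generator

`synthetic.generate_ppg` integrates a heart-rate trajectory into an
instantaneous phase and emits the three-harmonic waveform with relative
amplitudes (1.0, 0.5, 0.25) and phases (0, 0.3, 0.3) — chosen once to
give a realistic morphology: fast upstroke (rising time shorter than
falling time), a narrow systolic peak, a shallow dicrotic notch on
every beat, and kurtosis ≈ 2.56, safely below the gate. Beat times are
the integer crossings of the phase, so ground truth is exact. These are
fixtures emulating the harmonic model, not validated physiology: real
PPG has more harmonics, beat-to-beat amplitude variability,
respiratory modulation and baseline drift, none of which are present.
Passing tests on these fixtures demonstrates correct mechanism, not
clinical performance.

The artifact generator interpolates i.i.d. zero-mean Gaussian control
points (std σ, spaced `stride` samples) with a truncated windowed-sinc
kernel L(n) = sinc(n/stride)·sinc(n/T) supported on T samples
(defaults T = 500, stride = 100). As printed, the kernel formula with
integer arguments degenerates to a unit impulse; the implemented
reading — argument in control-spacing units with taper n/T — is the
only one consistent with its described behavior (smooth between
kernel-boundary overlaps, spiky at them, endpoints of the kernel not
near zero). The noise passes exactly through each control draw, scales
exactly linearly in σ, and its stationary std is σ·√(Σ L²/stride)
(≈ 0.96 σ at the defaults), verified against Monte-Carlo.

Fixture amplitude scale: the default is 15 signal units, set so that at
the benchmark rate (64 Hz) and the generator's sample-unit defaults,
the artifact residue surviving the prefilter at σ = 400–500 (the
"moderate activity" range) is spiky and comparable to the pulse
amplitude — the regime in which corruption meaningfully damages
delineation and the kurtosis gate trips on about half of the corrupted
windows. At much larger signal scales the same σ leaves delineation
intact (nothing to clean); with smooth in-band noise the gate cannot
trip at all (see the gate discussion above).

## Evaluation harness

Fiducial detections are matched one-to-one to the reference delineation
within ±0.15 s (two-pointer sweep; provably maximum-cardinality on
sorted sequences, cross-checked against exhaustive enumeration), giving
sensitivity, positive predictivity and their geometric mean.
Reconstruction MSE and HR series errors (AEmean; REmean in percent;
AEmedian) are computed against the prefiltered clean signal and the
true window rates. The delineator itself is a generic derivative-based
design (prominence threshold 0.3 of the window range, refractory
distance 60/220 s; onset = preceding local minimum, slope = maximum
first derivative on the upstroke, dicrotic = most prominent local
minimum between peak and next onset with a second-derivative fallback).
Since both arms of every comparison use the same delineator, the
scores measure signal recovery, not delineator quality.

Benchmark problem sizes: 60-s fixtures at 64 Hz, σ grid
{0, 0.5, 1, 4, 12, 40, 130, 450, 1500, 5000}, five noise seeds. The
parameter-recovery checks use three fixtures with rates drawn from
60–110 BPM for the FFT variant and one fixture for the sparse variant
(the sparse solver is ~50× slower; one fixture keeps the check under
two minutes while exercising the identical code path).

## Known limitations

* Quality gating by kurtosis is blind to smooth Gaussian-like in-band
  corruption; such windows pass through uncleaned by design.
* Non-overlapping window processing can leave discontinuities at
  window boundaries.
* The three-harmonic model discards genuine PPG content above the
  third harmonic; reconstruction fidelity is bounded by that model
  error (~5 % variance on the synthetic fixture).
* Fallback triplets inherit any bias in the ECG-derived meanHR.
* WFDB binary records are not read; signal I/O is two-column CSV or a
  plain-text header + one-column CSV record.
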