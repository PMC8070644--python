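"""Realistic synthetic motion-artifact generator.

Motion artifacts in wrist PPG look like slow baseline wander punctuated
by sharp spikes.  The generator reproduces both behaviors by drawing
independent zero-mean Gaussian control points (standard deviation
sigma), spacing them ``stride`` samples apart, and interpolating with a
truncated windowed-sinc (Lanczos-type) kernel of length ``T`` samples:

    L(n) = sinc(n / stride) * sinc(n / T),   n over the T-sample support.

The first factor gives the interpolation property (the noise passes
exactly through each control draw); the second tapers the kernel, but --
because the support is only T samples -- leaves the kernel's endpoints
well away from zero, so wherever neighboring kernels' boundaries overlap
the superposition jumps, producing the spiky excursions.  Between
boundaries the noise varies gently.  The amplitude scales exactly
linearly with sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UniformSignal

__all__ = ["NoiseSpec", "lanczos_kernel", "generate_noise", "corrupt", "noise_std_factor"]


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the artifact generator.

    sigma is in signal units; T (kernel length) and stride (kernel
    spacing) are in samples, with T an integer multiple of stride.
    """

    sigma: float
    T: int = 500
    stride: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.T <= 0 or self.stride <= 0:
            raise ValueError("T and stride must be positive integers")
        if self.T % self.stride != 0:
            raise ValueError(
                f"T={self.T} must be an integer multiple of stride={self.stride}"
            )

    @property
    def a(self) -> int:
        """Kernel half-width in control-spacing units (T / stride)."""
        return self.T // self.stride


def _kernel_offsets(T: int) -> np.ndarray:
    # T-sample support, centered: n = -(floor((T-1)/2)) .. ceil((T-1)/2)
    return np.arange(T) - (T - 1) // 2


def lanczos_kernel(T: int, stride: int) -> np.ndarray:
    """The T-sample interpolation kernel for control spacing ``stride``.

    Unit value at the center, zero at every nonzero integer multiple of
    ``stride`` inside the support, even-symmetric over the support.
    """
    if T % stride != 0:
        raise ValueError(f"T={T} must be an integer multiple of stride={stride}")
    n = _kernel_offsets(T)
    return np.sinc(n / stride) * np.sinc(n / T)


def generate_noise(M: int, spec: NoiseSpec) -> np.ndarray:
    """A length-M artifact realization.

    Control points sit at samples 0, stride, 2*stride, ...; draws are
    extended a kernel half-width beyond both ends so coverage does not
    fade at the boundaries.  With the same seed the output scales
    exactly linearly in sigma.
    """
    if M < 1:
        raise ValueError("M must be positive")
    rng = np.random.default_rng(spec.seed)
    a = spec.a
    n_ctrl = int(np.ceil(M / spec.stride)) + 1
    i0 = -a  # first control index (extension before sample 0)
    z = rng.standard_normal(n_ctrl + 2 * a)
    kernel = lanczos_kernel(spec.T, spec.stride)
    offsets = _kernel_offsets(spec.T)
    noise = np.zeros(M)
    for idx, zi in enumerate(z):
        center = (i0 + idx) * spec.stride
        pos = center + offsets
        ok = (pos >= 0) & (pos < M)
        noise[pos[ok]] += zi * kernel[ok]
    return spec.sigma * noise


def noise_std_factor(spec: NoiseSpec) -> float:
    """Closed-form ratio of the noise's stationary std to sigma.

    The variance at sample n is sigma^2 * sum_i L(n - i*stride)^2;
    averaging over the stride phases gives sigma^2 / stride * sum_n
    L(n)^2 over the whole support.
    """
    kernel = lanczos_kernel(spec.T, spec.stride)
    return float(np.sqrt(np.sum(kernel**2) / spec.stride))


def corrupt(signal: UniformSignal, spec: NoiseSpec) -> UniformSignal:
    """Additively corrupt a signal with a generated artifact realization."""
    return signal.with_samples(signal.samples + generate_noise(len(signal), spec))
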