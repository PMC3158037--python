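"""Assembly of localized spectral, causal temporal, and 2-D receptive fields.

The efficient-coding solution only fixes the *magnitude* of the filter's
modulation transfer function (the gain profile); the remaining unitary/phase
freedom is spent on locality and causality:

* spectral receptive fields (SRFs) use the symmetric choice K = Uᵀ·G·U,
  which centers each output neuron's filter on its own input channel;
* temporal receptive fields (TRFs) take the even, acausal kernel implied by
  a zero-phase inverse transform of the gains and convert it to its causal
  minimum-phase counterpart by reflecting the roots of the tap polynomial
  into the unit disk — the unique causal filter with the same magnitude
  response and maximally front-loaded energy;
* 2-D spectro-temporal kernels (STRFs) causalize each temporal slice of the
  gain grid (one per spectral modulation frequency) the same way, then
  inverse-transform across spectral modulation frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coding import CorrelationModel, NoiseSpec, optimal_gain
from .ensembles import ModulationPowerSpectrum

__all__ = [
    "LinearFilter1D",
    "STRFKernel",
    "build_srf",
    "srf_matrix",
    "acausal_kernel_from_gains",
    "minimum_phase",
    "build_trf",
    "build_strf",
    "apply_strf",
]


@dataclass
class LinearFilter1D:
    """A 1-D filter over discrete lags (time) or offsets (frequency).

    ``origin_index`` marks the tap corresponding to zero lag; a causal
    filter has origin_index 0 and no taps at negative lag.
    """

    coeffs: np.ndarray
    axis_step: float               # seconds or octaves per tap
    causal: bool
    origin_index: int = 0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("filter coefficients must be finite")

    @property
    def lags(self) -> np.ndarray:
        return (np.arange(len(self.coeffs)) - self.origin_index) * self.axis_step

    def magnitude_response(self, n: int | None = None) -> np.ndarray:
        """|DFT| of the taps, optionally zero-padded to length n."""
        return np.abs(np.fft.fft(self.coeffs, n=n))


@dataclass
class STRFKernel:
    """2-D spectro-temporal kernel over (frequency offset, latency).

    Rows are frequency offsets around the neuron's preferred frequency
    ``f0`` (octaves); columns are latencies t ≥ 0 when causal.
    """

    kernel: np.ndarray             # [n_freq_offsets, n_latencies]
    freq_step: float               # octaves per row
    time_step: float               # seconds per column
    f0: float                      # octaves
    causal: bool = True

    @property
    def freq_offsets(self) -> np.ndarray:
        n = self.kernel.shape[0]
        return (np.arange(n) - n // 2) * self.freq_step

    @property
    def latencies(self) -> np.ndarray:
        return np.arange(self.kernel.shape[1]) * self.time_step


# ---------------------------------------------------------------------------
# spectral receptive fields


def srf_matrix(correlation: CorrelationModel, gains) -> np.ndarray:
    """Full encoding matrix K = Uᵀ·G·U (symmetric for real inputs).

    The multiplexing step re-uses the decorrelating rotation, which places
    each output neuron's receptive field on its own input channel — the
    most local choice available within the unitary freedom.
    """
    g = np.asarray(gains, dtype=float)
    U = correlation.eigenvectors
    if g.shape != (U.shape[0],):
        raise ValueError("gains length must match the eigenvector count")
    return (U.T * g) @ U


def build_srf(correlation: CorrelationModel, gains, freq_step: float = 0.02):
    """Spectral receptive fields, one per output channel.

    Row j of K = Uᵀ·G·U is the SRF of output neuron j over input frequency
    channels; at high SNR it has a central excitatory peak with inhibitory
    side lobes (contrast enhancement / decorrelation).
    """
    K = srf_matrix(correlation, gains)
    return [
        LinearFilter1D(coeffs=row, axis_step=freq_step, causal=False, origin_index=j)
        for j, row in enumerate(K)
    ]


# ---------------------------------------------------------------------------
# minimum-phase causalization


def acausal_kernel_from_gains(gains, axis_step: float = 1e-3) -> LinearFilter1D:
    """Even, acausal kernel whose |DFT| equals the given gain profile.

    ``gains`` is a real nonnegative vector over FFT-ordered frequencies and
    must be symmetric under frequency negation; the zero-phase inverse DFT
    is then real and even about the central tap.
    """
    g = np.asarray(gains, dtype=float)
    if g.ndim != 1:
        raise ValueError("gains must be 1-D")
    if not np.allclose(g, np.roll(g[::-1], 1), atol=1e-10 * max(g.max(), 1.0)):
        raise ValueError("gains must be symmetric in +/- frequency")
    h = np.fft.fftshift(np.fft.ifft(g).real)
    return LinearFilter1D(
        coeffs=h, axis_step=axis_step, causal=False, origin_index=len(h) // 2
    )


def _trim_taps(coeffs: np.ndarray, rel_tol: float) -> tuple[np.ndarray, int]:
    """Strip leading/trailing taps below rel_tol·max; return (taps, shift)."""
    peak = np.abs(coeffs).max()
    if peak == 0:
        raise ValueError("cannot causalize an all-zero filter")
    keep = np.flatnonzero(np.abs(coeffs) >= rel_tol * peak)
    return coeffs[keep[0] : keep[-1] + 1], int(keep[0])


def _poly_from_roots_leja(roots: np.ndarray) -> np.ndarray:
    """Monic polynomial from roots, multiplied in Leja order.

    Clustered unit-circle roots (band-limited gain profiles have many) make
    the naive sequential product ill-conditioned; Leja ordering — each next
    root maximises its distance product to those already used — keeps the
    partial products balanced and the reconstruction accurate to near
    machine precision even at degree ~100.
    """
    if roots.size == 0:
        return np.ones(1)
    remaining = roots.copy()
    i = int(np.argmax(np.abs(remaining)))
    remaining[[0, i]] = remaining[[i, 0]]
    # dist[j] accumulates prod over chosen roots of |remaining[j] - chosen|
    dist = np.ones(len(remaining))
    for k in range(1, len(remaining)):
        dist[k:] *= np.abs(remaining[k:] - remaining[k - 1])
        j = k + int(np.argmax(dist[k:]))
        remaining[[k, j]] = remaining[[j, k]]
        dist[[k, j]] = dist[[j, k]]
    return np.poly(remaining)


def minimum_phase(
    filt: LinearFilter1D, trim_rel_tol: float = 1e-12, unit_circle_tol: float = 1e-8
) -> LinearFilter1D:
    """Causal minimum-phase counterpart of a finitely-supported filter.

    Procedure: (1) shift the taps to causal support; (2) find the complex
    roots of the tap polynomial (via the companion matrix); (3) reflect each
    root of modulus > 1 to its conjugate reciprocal and rescale so the
    magnitude response is unchanged.  Roots within ``unit_circle_tol`` of
    the unit circle are left in place.  The result is the causal filter with
    this magnitude response whose energy is maximally concentrated at early
    lags; the operation is idempotent.
    """
    h, _ = _trim_taps(filt.coeffs, trim_rel_tol)
    if len(h) == 1:
        return LinearFilter1D(
            coeffs=h.copy(), axis_step=filt.axis_step, causal=True, origin_index=0
        )
    roots = np.roots(h)
    if not np.all(np.isfinite(roots)):
        raise ArithmeticError("root finding failed for the tap polynomial")
    mod = np.abs(roots)
    outside = mod > 1.0 + unit_circle_tol
    reflected = roots.copy()
    reflected[outside] = 1.0 / np.conj(roots[outside])
    # |e^{iω} − r| = |r|·|e^{iω} − 1/conj(r)| keeps the magnitude response
    scale = h[0] * np.prod(mod[outside]) if np.any(outside) else h[0]
    coeffs = np.atleast_1d(_poly_from_roots_leja(reflected)) * scale
    if np.abs(coeffs.imag).max() > 1e-6 * np.abs(coeffs).max():
        raise ArithmeticError("minimum-phase reconstruction is not real")
    return LinearFilter1D(
        coeffs=coeffs.real, axis_step=filt.axis_step, causal=True, origin_index=0
    )


def _fix_sign(coeffs: np.ndarray) -> np.ndarray:
    """Flip the overall sign so the largest-magnitude tap is positive."""
    peak = coeffs.flat[np.argmax(np.abs(coeffs))]
    return -coeffs if peak < 0 else coeffs


def build_trf(
    power_spectrum,
    noise: NoiseSpec,
    tradeoff: float,
    time_step: float = 1e-3,
    trim_rel_tol: float = 1e-9,
) -> LinearFilter1D:
    """Causal temporal receptive field from a translation-invariant ensemble.

    ``power_spectrum`` is S(ω) over FFT-ordered temporal modulation
    frequencies.  The optimal gains are computed per frequency, turned into
    the even acausal kernel, and causalized to minimum phase; the returned
    filter's magnitude response equals the gain profile.
    """
    S = np.asarray(power_spectrum, dtype=float)
    g = optimal_gain(S, noise, tradeoff)
    if not np.any(g > 0):
        raise ValueError("gain profile is identically zero at this SNR")
    acausal = acausal_kernel_from_gains(g, axis_step=time_step)
    trimmed, _ = _trim_taps(acausal.coeffs, trim_rel_tol)
    causal = minimum_phase(
        LinearFilter1D(
            coeffs=trimmed,
            axis_step=time_step,
            causal=False,
            origin_index=len(trimmed) // 2,
        )
    )
    causal.coeffs = _fix_sign(causal.coeffs)
    return causal


# ---------------------------------------------------------------------------
# 2-D spectro-temporal kernels


def build_strf(
    mod_power: ModulationPowerSpectrum,
    noise: NoiseSpec,
    tradeoff: float,
    f0: float = 0.0,
    trim_rel_tol: float = 1e-9,
) -> STRFKernel:
    """Causal 2-D STRF whose |2-D DFT| equals the optimal gain grid.

    For each spectral modulation frequency ω_f, the temporal gain slice
    g(ω_f, ·) is inverse-transformed to an even acausal temporal filter and
    causalized to minimum phase; the causal slices are then
    inverse-transformed across ω_f, yielding a kernel that is strictly zero
    at negative latency and localized around the preferred frequency f0.
    """
    g = optimal_gain(mod_power.power, noise, tradeoff)
    nf, nt = g.shape
    if not np.any(g > 0):
        raise ValueError("gain grid is identically zero at this SNR")
    dwf = float(np.abs(np.diff(np.sort(mod_power.spectral_freqs))).min())
    dwt = float(np.abs(np.diff(np.sort(mod_power.temporal_freqs))).min())
    freq_step = 1.0 / (nf * dwf)   # octaves
    time_step = 1.0 / (nt * dwt)   # seconds

    H = np.zeros((nf, nt))
    for i in range(nf):
        slice_g = g[i]
        if not np.any(slice_g > 0):
            continue
        acausal = acausal_kernel_from_gains(slice_g, axis_step=time_step)
        trimmed, _ = _trim_taps(acausal.coeffs, trim_rel_tol)
        causal = minimum_phase(
            LinearFilter1D(
                coeffs=trimmed,
                axis_step=time_step,
                causal=False,
                origin_index=len(trimmed) // 2,
            )
        )
        H[i, : len(causal.coeffs)] = causal.coeffs
    kernel = np.fft.fftshift(np.fft.ifft(H, axis=0).real, axes=0)
    kernel = _fix_sign(kernel)
    return STRFKernel(
        kernel=kernel,
        freq_step=freq_step,
        time_step=time_step,
        f0=float(f0),
        causal=True,
    )


def apply_strf(spectrogram, kernel: STRFKernel) -> np.ndarray:
    """Convolve a mean-subtracted spectrogram with a causal STRF.

    r(t) = Σ_f Σ_{t′≥0} STRF(f − f0, t′) · S(f, t − t′); the kernel's
    frequency offsets are mapped onto the spectrogram channels nearest its
    preferred frequency f0.  A zero-mean input gives a zero-mean response.
    """
    sg_step = float(np.median(np.diff(spectrogram.freq_axis)))
    if not np.isclose(sg_step, kernel.freq_step, rtol=1e-6):
        raise ValueError(
            f"frequency-step mismatch: spectrogram {sg_step} vs kernel {kernel.freq_step}"
        )
    if len(spectrogram.time_axis) > 1:
        sg_dt = float(np.median(np.diff(spectrogram.time_axis)))
        if not np.isclose(sg_dt, kernel.time_step, rtol=1e-6):
            raise ValueError(
                f"time-step mismatch: spectrogram {sg_dt} vs kernel {kernel.time_step}"
            )
    n_channels, n_frames = spectrogram.power.shape
    f0_idx = int(np.argmin(np.abs(spectrogram.freq_axis - kernel.f0)))
    nf = kernel.kernel.shape[0]
    response = np.zeros(n_frames)
    for i in range(nf):
        c = f0_idx + (i - nf // 2)
        if 0 <= c < n_channels:
            response += np.convolve(spectrogram.power[c], kernel.kernel[i])[:n_frames]
    return response
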