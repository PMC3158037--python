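"""Quantitative descriptors of gain profiles and receptive-field kernels.

Measurements used to characterise how the optimal filters adapt to input
statistics: modulation transfer functions (MTFs) and their peak/cutoff
frequencies, band-pass vs low-pass classification, excitatory/inhibitory
lobe counts and widths, and a whitening-flatness diagnostic for the
high-SNR regime where the optimal gain approaches g ∝ S^(−1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coding import NoiseSpec
from .filters import LinearFilter1D, STRFKernel

__all__ = [
    "MTF",
    "FilterMetrics",
    "mtf_of",
    "peak_and_cutoff",
    "classify_shape",
    "lobe_metrics",
    "whitening_flatness",
    "average_mtf",
]


@dataclass
class MTF:
    """Magnitude of a kernel's Fourier transform over modulation frequency.

    1-D: ``magnitude[i]`` at ``axes[0][i]`` (Hz or cycles/octave).
    2-D: ``magnitude[i, j]`` at spectral modulation ``axes[0][i]``
    (cycles/octave) and temporal modulation ``axes[1][j]`` (Hz).
    Axes are centered (negative to positive frequency).
    """

    magnitude: np.ndarray
    axes: tuple
    normalization: str = "none"


@dataclass
class FilterMetrics:
    """Shape descriptors of a gain profile / MTF / kernel."""

    peak_mod_freq: tuple | float | None = None
    cutoff_freq: tuple | float | None = None
    shape_class: str | None = None           # "band-pass" | "low-pass"
    n_excitatory_lobes: int | None = None
    n_inhibitory_lobes: int | None = None
    main_lobe_width: float | None = None
    inhibitory_strength_ratio: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# modulation transfer functions


def mtf_of(kernel, pad: int | None = None, normalize_peak: float | None = None) -> MTF:
    """MTF (|DFT| magnitude) of a 1-D filter or a 2-D STRF kernel.

    ``pad`` zero-pads the transform for a denser grid; ``normalize_peak``
    rescales so the maximum equals the given value (used for population
    averaging across kernels).
    """
    if isinstance(kernel, LinearFilter1D):
        n = pad or len(kernel.coeffs)
        if n == 0:
            raise ValueError("empty kernel")
        mag = np.abs(np.fft.fft(kernel.coeffs, n=n))
        freqs = np.fft.fftfreq(n, d=kernel.axis_step)
        order = np.argsort(freqs)
        mag, freqs = mag[order], freqs[order]
        axes = (freqs,)
    elif isinstance(kernel, STRFKernel):
        nf, nt = kernel.kernel.shape
        pf, pt = (pad or nf), (pad or nt)
        mag = np.abs(np.fft.fft2(kernel.kernel, s=(pf, pt)))
        ff = np.fft.fftfreq(pf, d=kernel.freq_step)
        ft = np.fft.fftfreq(pt, d=kernel.time_step)
        of, ot = np.argsort(ff), np.argsort(ft)
        mag = mag[np.ix_(of, ot)]
        axes = (ff[of], ft[ot])
    else:
        raise TypeError("kernel must be a LinearFilter1D or STRFKernel")
    norm = "none"
    if normalize_peak is not None:
        peak = mag.max()
        if peak == 0:
            raise ValueError("cannot normalize an all-zero MTF")
        mag = mag * (normalize_peak / peak)
        norm = f"peak={normalize_peak}"
    return MTF(magnitude=mag, axes=axes, normalization=norm)


def peak_and_cutoff(mtf: MTF, rel_threshold: float = 0.05) -> FilterMetrics:
    """Locate the MTF peak and per-axis cutoff on the nonnegative quadrant.

    Peak: argmax over nonnegative frequencies, ties resolved toward the
    lowest frequency.  Cutoff per axis: the largest frequency at which the
    magnitude (maximised over the other axis, for 2-D) still reaches
    ``rel_threshold`` times the global maximum.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must be in (0, 1)")
    mag = mtf.magnitude
    if mag.max() == 0:
        raise ValueError("all-zero MTF")
    if mag.ndim == 1:
        (freqs,) = mtf.axes
        sel = freqs >= 0
        f, m = freqs[sel], mag[sel]
        peak = float(f[np.argmax(m)])  # argmax returns first = lowest freq
        above = m >= rel_threshold * mag.max()
        cutoff = float(f[np.flatnonzero(above).max()])
        return FilterMetrics(peak_mod_freq=peak, cutoff_freq=cutoff)
    ff, ft = mtf.axes
    sf, st = ff >= 0, ft >= 0
    quad = mag[np.ix_(sf, st)]
    i, j = np.unravel_index(int(np.argmax(quad)), quad.shape)
    peak = (float(ff[sf][i]), float(ft[st][j]))
    thr = rel_threshold * mag.max()
    prof_f = quad.max(axis=1)
    prof_t = quad.max(axis=0)
    cut_f = float(ff[sf][np.flatnonzero(prof_f >= thr).max()])
    cut_t = float(ft[st][np.flatnonzero(prof_t >= thr).max()])
    return FilterMetrics(peak_mod_freq=peak, cutoff_freq=(cut_f, cut_t))


def classify_shape(magnitude, margin: float = 0.10) -> str:
    """Band-pass vs low-pass classification of a 1-D gain/MTF profile.

    ``magnitude`` is over nonnegative frequency indices (index 0 = DC).
    Band-pass iff some interior frequency exceeds the zero-frequency value
    by more than ``margin`` (relative); otherwise low-pass.
    """
    m = np.asarray(magnitude, dtype=float)
    if np.any(m < 0):
        raise ValueError("magnitude must be nonnegative")
    if len(m) < 2 or m.max() == 0:
        return "low-pass"
    if m[1:].max() > m[0] * (1.0 + margin):
        return "band-pass"
    return "low-pass"


# ---------------------------------------------------------------------------
# lobe structure of kernels


def _runs_of_sign(v: np.ndarray, floor: float, min_run: int):
    """Maximal same-sign runs whose peak |value| reaches the floor."""
    sign = np.sign(v)
    runs = []
    start = 0
    for i in range(1, len(v) + 1):
        if i == len(v) or sign[i] != sign[start]:
            seg = v[start:i]
            if (
                sign[start] != 0
                and len(seg) >= min_run
                and np.abs(seg).max() >= floor
            ):
                runs.append((start, i, float(sign[start])))
            start = i
    return runs


def lobe_metrics(
    kernel, noise_floor: float = 0.05, min_run: int = 2
) -> FilterMetrics:
    """Excitatory/inhibitory lobe counts, main-lobe width, inhibition ratio.

    Lobes are maximal contiguous same-sign runs whose peak magnitude reaches
    ``noise_floor`` times the global maximum and that span at least
    ``min_run`` taps.  The main-lobe width is the full width at half maximum
    of the largest-|peak| lobe, in axis units.  The inhibitory strength
    ratio is Σ|negative|/Σ|positive| over detected lobes.

    For a 2-D STRF the metrics are computed on its profile at the kernel's
    peak: lobes along frequency at the peak latency.
    """
    if isinstance(kernel, LinearFilter1D):
        v = kernel.coeffs
        step = kernel.axis_step
    elif isinstance(kernel, STRFKernel):
        i, j = np.unravel_index(
            int(np.argmax(np.abs(kernel.kernel))), kernel.kernel.shape
        )
        v = kernel.kernel[:, j]
        step = kernel.freq_step
    else:
        v = np.asarray(kernel, dtype=float)
        step = 1.0
    peak = np.abs(v).max()
    if peak == 0:
        return FilterMetrics(
            n_excitatory_lobes=0,
            n_inhibitory_lobes=0,
            main_lobe_width=0.0,
            inhibitory_strength_ratio=0.0,
        )
    floor = noise_floor * peak
    runs = _runs_of_sign(v, floor, min_run)
    n_exc = sum(1 for r in runs if r[2] > 0)
    n_inh = sum(1 for r in runs if r[2] < 0)
    pos_mass = sum(np.abs(v[a:b]).sum() for a, b, s in runs if s > 0)
    neg_mass = sum(np.abs(v[a:b]).sum() for a, b, s in runs if s < 0)
    ratio = float(neg_mass / pos_mass) if pos_mass > 0 else np.inf

    width = 0.0
    if runs:
        a, b, _ = max(runs, key=lambda r: np.abs(v[r[0] : r[1]]).max())
        seg = np.abs(v[a:b])
        width = float(np.count_nonzero(seg >= 0.5 * seg.max()) * step)
    return FilterMetrics(
        n_excitatory_lobes=n_exc,
        n_inhibitory_lobes=n_inh,
        main_lobe_width=width,
        inhibitory_strength_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# whitening diagnostics


def whitening_flatness(
    gains, powers, noise: NoiseSpec, snr_threshold: float = 100.0
):
    """Max relative deviation of g²·S over the high-SNR passband.

    At high SNR the optimal gain whitens: g²·S is constant.  The deviation
    is max |g²S − mean| / mean over channels with S/N ≥ ``snr_threshold``
    and g > 0.  Returns None (not applicable) if that passband is empty.
    """
    g = np.asarray(gains, dtype=float)
    S = np.asarray(powers, dtype=float)
    if g.shape != S.shape:
        raise ValueError("gains and powers must have matching shapes")
    band = (S / noise.input_noise_var >= snr_threshold) & (g > 0)
    if not np.any(band):
        return None
    p = (g**2 * S)[band]
    return float(np.abs(p - p.mean()).max() / p.mean())


def average_mtf(kernels, normalize_peak: float = 1.0, pad: int | None = None) -> MTF:
    """Population-average MTF: per-kernel peak normalization, then mean."""
    mtfs = [mtf_of(k, pad=pad, normalize_peak=normalize_peak) for k in kernels]
    mags = np.stack([m.magnitude for m in mtfs])
    return MTF(
        magnitude=mags.mean(axis=0),
        axes=mtfs[0].axes,
        normalization=f"per-kernel peak={normalize_peak}, averaged",
    )
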