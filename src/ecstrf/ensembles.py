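"""Synthetic stimulus ensembles and spectrogram front-end.

The efficient-coding theory of auditory receptive fields is stated for
Gaussian stimulus ensembles with a prescribed second-order structure.  This
module generates such ensembles:

* a *spectral* ensemble of zero-mean input spectra ``x(f)`` obtained by
  Gaussian-smoothing white noise across frequency channels and scaling each
  channel by a power profile that decays with frequency,
* a *temporal* ensemble built the same way but with circular smoothing, so
  that the correlation depends on the lag only (translation invariance),
* a separable two-dimensional modulation power spectrum
  ``S(omega_f, omega_t)`` over spectral (cycles/octave) and temporal (Hz)
  modulation frequencies, and
* a spectrogram front-end that maps a mono waveform onto a log-frequency
  (octave) axis via a windowed Fourier transform.

All randomness flows through :class:`numpy.random.Generator` seeded
explicitly; identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy.io import wavfile as _wavfile

__all__ = [
    "SpectralEnsemble",
    "Spectrogram",
    "ModulationPowerSpectrum",
    "make_spectral_ensemble",
    "make_temporal_ensemble",
    "analytic_correlation_matrix",
    "modulation_power_2d",
    "spectrogram_from_waveform",
]

#: power of the highest-frequency channel relative to the lowest one under
#: the default decay profile (~10%)
DEFAULT_DECAY_RATE = float(np.log(10.0) / 2.0)


@dataclass
class SpectralEnsemble:
    """Zero-mean Gaussian input spectra with controlled correlation.

    ``samples[i]`` is one draw of the input vector ``x`` over ``n_channels``
    frequency (or time) channels.  The generator is
    ``x = intensity_scale * A @ W_norm @ z`` with ``z`` standard normal,
    ``W_norm`` the row-normalised Gaussian smoothing matrix and ``A`` a
    diagonal per-channel scale decaying with channel index.
    """

    samples: np.ndarray            # [n_samples, n_channels]
    freq_axis: np.ndarray          # channel centers, octaves
    intensity_scale: float
    decay_rate: float
    smoothing_length: float        # channel units
    seed: int
    circular: bool = False         # temporal (translation-invariant) variant

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def axis_step(self) -> float:
        return float(self.freq_axis[1] - self.freq_axis[0])


@dataclass
class Spectrogram:
    """Mean-subtracted log-frequency power spectrogram ``S(f, t)``.

    ``power`` holds the fluctuation around the per-channel baseline
    ``mean_power`` (the ensemble average that the receptive-field model
    subtracts before filtering).
    """

    power: np.ndarray              # [n_channels, n_frames], mean-subtracted
    mean_power: np.ndarray         # [n_channels]
    freq_axis: np.ndarray          # log2(Hz), octaves
    time_axis: np.ndarray          # seconds
    window: dict = field(default_factory=dict)
    log_compressed: bool = False

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    @property
    def n_frames(self) -> int:
        return self.power.shape[1]


@dataclass
class ModulationPowerSpectrum:
    """Signal power over (spectral, temporal) modulation frequency.

    ``power[i, j]`` is the signal power of the moving-ripple channel at
    spectral modulation ``spectral_freqs[i]`` (cycles/octave) and temporal
    modulation ``temporal_freqs[j]`` (Hz), both in FFT ordering.
    """

    power: np.ndarray              # [n_f, n_t], FFT ordering on both axes
    spectral_freqs: np.ndarray     # cycles/octave, FFT ordering
    temporal_freqs: np.ndarray     # Hz, FFT ordering
    corr_params: tuple             # (lambda_f, lambda_t) correlation ranges
    scale: float                   # overall SNR scale factor


# ---------------------------------------------------------------------------
# smoothing matrices


def gaussian_smoothing_matrix(
    n_channels: int, smoothing_length: float, circular: bool = False
) -> np.ndarray:
    """Row-L2-normalised Gaussian smoothing matrix.

    Entry (a, b) is ``exp(-d²/(2 λ_s²))`` with ``d = a - b`` (or the circular
    distance when ``circular``), each row scaled to unit L2 norm so that the
    smoothed channel has unit variance before any per-channel scaling.
    """
    if smoothing_length <= 0:
        raise ValueError("smoothing_length must be positive")
    idx = np.arange(n_channels)
    d = idx[:, None] - idx[None, :]
    if circular:
        d = (d + n_channels // 2) % n_channels - n_channels // 2
    w = np.exp(-0.5 * (d / smoothing_length) ** 2)
    w /= np.linalg.norm(w, axis=1, keepdims=True)
    return w


def channel_scale_profile(n_channels: int, decay_rate: float) -> np.ndarray:
    """Per-channel amplitude scale A, decaying exponentially with index."""
    if decay_rate < 0:
        raise ValueError("decay_rate must be nonnegative")
    return np.exp(-decay_rate * np.arange(n_channels) / n_channels)


def _default_freq_axis(n_channels: int, freq_step: float) -> np.ndarray:
    return np.arange(n_channels) * freq_step


# ---------------------------------------------------------------------------
# ensemble generators


def make_spectral_ensemble(
    n_channels: int,
    n_samples: int,
    intensity_scale: float = 10.0,
    decay_rate: float = DEFAULT_DECAY_RATE,
    smoothing_length: float = 5.0,
    seed: int = 0,
    freq_step: float = 0.02,
) -> SpectralEnsemble:
    """Draw ``n_samples`` correlated Gaussian input spectra.

    Each sample is ``intensity_scale * A @ W_norm @ z`` where ``z`` is iid
    standard normal, ``W_norm`` is the (truncated, non-circular) Gaussian
    smoothing matrix with length ``smoothing_length`` channels and ``A`` the
    decaying per-channel scale.  ``freq_step`` sets the octave spacing of the
    recorded frequency axis.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    w = gaussian_smoothing_matrix(n_channels, smoothing_length, circular=False)
    a = channel_scale_profile(n_channels, decay_rate)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_channels))
    samples = intensity_scale * (z @ w.T) * a[None, :]
    return SpectralEnsemble(
        samples=samples,
        freq_axis=_default_freq_axis(n_channels, freq_step),
        intensity_scale=float(intensity_scale),
        decay_rate=float(decay_rate),
        smoothing_length=float(smoothing_length),
        seed=int(seed),
        circular=False,
    )


def make_temporal_ensemble(
    n_steps: int,
    n_samples: int,
    smoothing_length: float = 5.0,
    intensity_scale: float = 10.0,
    seed: int = 0,
    time_step: float = 1e-3,
) -> SpectralEnsemble:
    """Translation-invariant Gaussian ensemble over ``n_steps`` time bins.

    The per-channel scale is constant and the smoothing wraps around, so the
    correlation ⟨x(t)x(t′)⟩ depends on the lag t−t′ only and the analytic
    correlation matrix is circulant (diagonalised by the DFT).
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    w = gaussian_smoothing_matrix(n_steps, smoothing_length, circular=True)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, n_steps))
    samples = intensity_scale * (z @ w.T)
    return SpectralEnsemble(
        samples=samples,
        freq_axis=np.arange(n_steps) * time_step,
        intensity_scale=float(intensity_scale),
        decay_rate=0.0,
        smoothing_length=float(smoothing_length),
        seed=int(seed),
        circular=True,
    )


def analytic_correlation_matrix(
    n_channels: int,
    intensity_scale: float = 10.0,
    decay_rate: float = DEFAULT_DECAY_RATE,
    smoothing_length: float = 5.0,
    circular: bool = False,
) -> np.ndarray:
    """Exact correlation matrix implied by the generator (no sampling noise).

    Returns ``R = intensity_scale² · A · W_norm · W_normᵀ · A``, the
    infinite-sample limit of the empirical second-moment matrix.
    """
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    w = gaussian_smoothing_matrix(n_channels, smoothing_length, circular=circular)
    a = channel_scale_profile(n_channels, 0.0 if circular else decay_rate)
    core = w @ w.T
    return (intensity_scale**2) * (a[:, None] * core * a[None, :])


def ensemble_correlation(ensemble: SpectralEnsemble) -> np.ndarray:
    """Analytic correlation matrix for an ensemble's recorded parameters."""
    return analytic_correlation_matrix(
        ensemble.n_channels,
        intensity_scale=ensemble.intensity_scale,
        decay_rate=ensemble.decay_rate,
        smoothing_length=ensemble.smoothing_length,
        circular=ensemble.circular,
    )


# ---------------------------------------------------------------------------
# 2-D modulation power spectrum


def modulation_power_2d(
    spectral_freqs: np.ndarray,
    temporal_freqs: np.ndarray,
    corr_params: tuple = (1.0, 0.03),
    scale: float = 1.0,
) -> ModulationPowerSpectrum:
    """Separable modulation power spectrum over a 2-D ripple grid.

    ``S(ω_f, ω_t) ∝ exp(−λ_f·|ω_f| − λ_t·|ω_t|)`` where the correlation
    ranges ``corr_params = (λ_f, λ_t)`` (octaves, seconds) set how fast the
    power falls off with spectral and temporal modulation frequency: longer
    input correlation concentrates the power at low modulation frequencies.
    The envelope is normalised so the total power over the grid equals
    ``scale`` times the number of grid points, making the total independent
    of the correlation ranges (equal-total-power construction).

    Both frequency axes are expected in FFT ordering (symmetric about 0).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    lam_f, lam_t = corr_params
    if lam_f < 0 or lam_t < 0:
        raise ValueError("correlation ranges must be nonnegative")
    wf = np.asarray(spectral_freqs, dtype=float)
    wt = np.asarray(temporal_freqs, dtype=float)
    _check_symmetric_axis(wf)
    _check_symmetric_axis(wt)
    env = np.exp(-lam_f * np.abs(wf)[:, None] - lam_t * np.abs(wt)[None, :])
    env *= env.size / env.sum()
    return ModulationPowerSpectrum(
        power=scale * env,
        spectral_freqs=wf,
        temporal_freqs=wt,
        corr_params=(float(lam_f), float(lam_t)),
        scale=float(scale),
    )


def _check_symmetric_axis(freqs: np.ndarray, tol: float = 1e-9) -> None:
    """Require that for every frequency on the axis, −frequency is present."""
    s = np.sort(freqs)
    # the most negative FFT frequency on an even grid has no positive partner
    pos = np.sort(s[s > tol])
    neg = np.sort(-s[s < -tol])
    m = min(len(pos), len(neg))
    if abs(len(pos) - len(neg)) > 1 or not np.allclose(pos[:m], neg[:m], atol=tol):
        raise ValueError("frequency grid must be symmetric about the origin")


# ---------------------------------------------------------------------------
# spectrogram front-end


def spectrogram_from_waveform(
    waveform: np.ndarray,
    sample_rate: float,
    window_len: float = 0.025,
    hop: float = 0.010,
    n_channels: int = 64,
    log_compress: bool = False,
    f_min: float = 100.0,
    f_max: float | None = None,
) -> Spectrogram:
    """Windowed-Fourier power spectrogram on a log-frequency (octave) axis.

    The waveform is analysed with a Hann-windowed short-time Fourier
    transform; linear-frequency power bins are pooled onto ``n_channels``
    log-spaced channel centers between ``f_min`` and ``f_max`` (default
    Nyquist), emulating the roughly logarithmic frequency analysis of the
    cochlea.  Optionally the power is log-compressed; finally the
    per-channel temporal mean is subtracted and stored separately, so
    ``power`` holds the fluctuations the receptive-field model acts on.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if x.size == 0:
        raise ValueError("empty waveform")
    nperseg = int(round(window_len * sample_rate))
    if nperseg < 2 or nperseg > x.size:
        raise ValueError("window_len must fit inside the waveform")
    hop_samples = max(1, int(round(hop * sample_rate)))
    noverlap = nperseg - hop_samples
    freqs, times, stft = _signal.stft(
        x,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        boundary=None,
        padded=False,
    )
    power_lin = np.abs(stft) ** 2  # [n_bins, n_frames]

    if f_max is None:
        f_max = sample_rate / 2.0
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    centers_oct = np.linspace(np.log2(f_min), np.log2(f_max), n_channels)
    # pool each positive-frequency bin into the nearest log-spaced channel
    usable = freqs > 0
    bin_oct = np.log2(freqs[usable])
    assign = np.clip(
        np.searchsorted(
            (centers_oct[:-1] + centers_oct[1:]) / 2.0, bin_oct
        ),
        0,
        n_channels - 1,
    )
    pooled = np.zeros((n_channels, power_lin.shape[1]))
    np.add.at(pooled, assign, power_lin[usable])

    if log_compress:
        pooled = np.log1p(pooled)
    mean_power = pooled.mean(axis=1)
    return Spectrogram(
        power=pooled - mean_power[:, None],
        mean_power=mean_power,
        freq_axis=centers_oct,
        time_axis=times,
        window={"type": "hann", "length": window_len, "hop": hop},
        log_compressed=bool(log_compress),
    )


def read_wav_mono(path) -> tuple[np.ndarray, float]:
    """Read a PCM WAV file, average channels to mono, scale to [-1, 1]."""
    rate, data = _wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)
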