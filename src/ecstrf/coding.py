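"""Decorrelation, optimal gain control, and the information–cost objective.

The encoding model is linear with two noise sources: the input vector
``x`` (signal power ``S_k`` per decorrelated channel) is corrupted by iid
input noise of variance ``N`` before encoding and by iid encoding noise of
variance ``N_e`` after, ``O = K(x + n) + n_e``.  The optimal transform K
factorises into (1) a principal-component rotation U that decorrelates the
inputs, (2) a diagonal gain ``g_k`` per decorrelated channel, and (3) a free
unitary multiplexing step.  The gain trades the neural cost (total output
power) against the transmitted Shannon information,

    E = sum_k [g_k²(S_k + N) + N_e]  -  λ · sum_k I_k ,

with the per-channel Gaussian information

    I_k = ½·log[(g_k²(S_k + N) + N_e) / (g_k² N + N_e)] .

Internally the objective uses natural logarithms (nats), which keeps the
stationarity algebra clean; reported information is converted to bits
(1 nat = 1/ln 2 bits).  Minimising E channel-by-channel in ``u = g²`` gives
the closed form implemented by :func:`optimal_gain`:

    g*² = max{0, (N_e / (2N(S+N))) · [sqrt(S² + 2λNS/N_e) − (S + 2N)]} ,

which is positive exactly when λ > 2·N_e·(1 + N/S).  At high SNR the gain
approaches the whitening profile g² ∝ 1/S; at low SNR it cuts off, so the
gain profile over modulation frequency shifts from band-pass to low-pass as
intensity drops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ensembles import SpectralEnsemble, ensemble_correlation

__all__ = [
    "NoiseSpec",
    "CorrelationModel",
    "CodingSolution",
    "GainProfile",
    "estimate_correlation",
    "analytic_correlation",
    "fourier_decorrelate",
    "channel_information",
    "channel_objective",
    "optimal_gain",
    "gain_profile",
    "total_objective",
    "encode",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class NoiseSpec:
    """Variances of the two iid Gaussian noise sources.

    ``input_noise_var`` (N) corrupts each input channel before encoding;
    ``encoding_noise_var`` (N_e) is added to each output channel after.
    """

    input_noise_var: float = 1.0
    encoding_noise_var: float = 1.0

    def __post_init__(self):
        if self.input_noise_var <= 0 or self.encoding_noise_var <= 0:
            raise ValueError("noise variances must be strictly positive")


@dataclass
class CorrelationModel:
    """Input correlation matrix with its eigensystem.

    ``eigenvectors[k]`` (row k) is the k-th principal axis; the rows form
    the decorrelating rotation U.  ``eigenvalues[k]`` is the signal power
    S_k of decorrelated channel k, sorted descending.
    """

    R: np.ndarray
    eigenvalues: np.ndarray        # descending, clipped at 0
    eigenvectors: np.ndarray       # rows orthonormal (the U / Ko transform)
    translation_invariant: bool = False
    power_spectrum: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass
class GainProfile:
    """Elementwise-optimal gains with peak and cutoff locations.

    ``peak_index`` is the argmax of the gain (tuple for 2-D profiles);
    ``cutoff_index`` the largest index (per axis, for 2-D) with g > 0, or
    -1 if the gain vanishes everywhere.
    """

    gains: np.ndarray
    peak_index: tuple | int
    cutoff_index: tuple | int

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.gains, dtype=dtype)


@dataclass
class CodingSolution:
    """Full evaluation of the efficient-coding objective at given gains."""

    gains: np.ndarray
    information: np.ndarray        # bits per channel
    output_power: np.ndarray       # g²(S+N) + N_e per channel
    cost: float                    # sum of output powers
    total_information: float       # bits
    objective: float               # cost − λ·information  (nats convention)
    tradeoff: float
    noise: NoiseSpec

    @property
    def total_information_nats(self) -> float:
        return self.total_information * LN2


# ---------------------------------------------------------------------------
# correlation models


def _fix_eigenvector_signs(vecs: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Make the first nonzero component of each row positive."""
    out = vecs.copy()
    for row in out:
        nz = np.flatnonzero(np.abs(row) > tol)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return out


def _zero_crossings(v: np.ndarray) -> int:
    s = np.sign(v[np.abs(v) > 1e-10 * np.max(np.abs(v))])
    return int(np.sum(s[1:] != s[:-1]))


def _order_degenerate_blocks(vals: np.ndarray, vecs: np.ndarray) -> np.ndarray:
    """Within numerically-degenerate eigenvalue blocks, order eigenvectors by
    ascending zero-crossing count (small index ↔ few oscillations)."""
    order = np.arange(len(vals))
    scale = max(vals[0], 1e-300)
    i = 0
    while i < len(vals):
        j = i + 1
        while j < len(vals) and abs(vals[j] - vals[i]) <= 1e-9 * scale:
            j += 1
        if j - i > 1:
            block = order[i:j]
            cross = [_zero_crossings(vecs[b]) for b in block]
            order[i:j] = block[np.argsort(cross, kind="stable")]
        i = j
    return order


def correlation_model_from_matrix(
    R: np.ndarray, translation_invariant: bool = False
) -> CorrelationModel:
    """Eigendecompose a symmetric correlation matrix into a CorrelationModel.

    Eigenvalues are sorted descending and clipped at zero (sampling noise can
    produce tiny negatives); eigenvector signs are fixed so the first nonzero
    component is positive, and degenerate blocks are ordered by oscillation
    count.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be a square matrix")
    if not np.allclose(R, R.T, atol=1e-8 * max(1.0, np.abs(R).max())):
        raise ValueError("R must be symmetric")
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order].T          # rows are eigenvectors
    if vals[0] > 0 and vals[-1] < -1e-10 * vals[0]:
        warnings.warn(
            "correlation matrix has eigenvalues below -1e-10·max; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    vals = np.clip(vals, 0.0, None)
    order2 = _order_degenerate_blocks(vals, vecs)
    vals, vecs = vals[order2], vecs[order2]
    vecs = _fix_eigenvector_signs(vecs)
    ps = None
    if translation_invariant:
        ps = np.real(np.fft.fft(R[0]))
    return CorrelationModel(
        R=R,
        eigenvalues=vals,
        eigenvectors=vecs,
        translation_invariant=translation_invariant,
        power_spectrum=ps,
    )


def estimate_correlation(ensemble: SpectralEnsemble) -> CorrelationModel:
    """Empirical second-moment matrix R_ab = ⟨x_a x_b⟩ from ensemble samples.

    The generator is zero-mean by construction, so no mean is re-subtracted.
    """
    if ensemble.n_samples < 2:
        raise ValueError("need at least 2 samples to estimate a correlation")
    x = ensemble.samples
    R = (x.T @ x) / x.shape[0]
    return correlation_model_from_matrix(R, translation_invariant=False)


def analytic_correlation(ensemble: SpectralEnsemble) -> CorrelationModel:
    """Exact correlation model implied by an ensemble's generator parameters."""
    R = ensemble_correlation(ensemble)
    return correlation_model_from_matrix(
        R, translation_invariant=ensemble.circular
    )


def fourier_decorrelate(lag_correlation: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Power spectrum of a translation-invariant ensemble.

    For shift-invariant correlation the decorrelating rotation is the Fourier
    transform, and the channel signal powers are the DFT of the
    lag-correlation function (1-D) or offset-correlation array (2-D).
    The lag function must be (conjugate-)symmetric, i.e. c(-τ) = c(τ) under
    the circular convention; negative spectral values beyond tolerance are
    clipped with a warning.
    """
    c = np.asarray(lag_correlation, dtype=float)
    rev = c
    for ax in range(c.ndim):
        rev = np.flip(np.roll(rev, -1, axis=ax), axis=ax)
    scale = np.abs(c).max() or 1.0
    if not np.allclose(c, rev, atol=tol * scale):
        raise ValueError("lag correlation is not symmetric under lag negation")
    S = np.real(np.fft.fftn(c))
    if S.min() < -tol * max(S.max(), 1.0):
        warnings.warn(
            "power spectrum has negative values beyond tolerance; clipping",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.clip(S, 0.0, None)


# ---------------------------------------------------------------------------
# per-channel gain optimisation


def channel_information(g, S, noise: NoiseSpec):
    """Shannon information (bits) transmitted by one Gaussian channel.

    I = ½·log2[(g²(S+N) + N_e) / (g²N + N_e)].  Vectorised over g and S.
    """
    g2 = np.square(np.asarray(g, dtype=float))
    S = np.asarray(S, dtype=float)
    N, Ne = noise.input_noise_var, noise.encoding_noise_var
    return 0.5 * np.log2((g2 * (S + N) + Ne) / (g2 * N + Ne))


def channel_objective(g, S, noise: NoiseSpec, tradeoff: float):
    """Per-channel objective e(g) = output power − λ·information (nats)."""
    if tradeoff <= 0:
        raise ValueError("tradeoff must be positive")
    g2 = np.square(np.asarray(g, dtype=float))
    S = np.asarray(S, dtype=float)
    N, Ne = noise.input_noise_var, noise.encoding_noise_var
    info_nats = 0.5 * np.log((g2 * (S + N) + Ne) / (g2 * N + Ne))
    return g2 * (S + N) + Ne - tradeoff * info_nats


def optimal_gain(S, noise: NoiseSpec, tradeoff: float):
    """Closed-form optimal gain g* ≥ 0 for channels of signal power S.

    Solves d e/d(g²) = 0 for the per-channel objective, with the boundary
    optimum g* = 0 whenever the tradeoff does not exceed the positivity
    threshold 2·N_e·(1 + N/S).  Vectorised over S.
    """
    if tradeoff <= 0:
        raise ValueError("tradeoff must be positive")
    S = np.asarray(S, dtype=float)
    N, Ne = noise.input_noise_var, noise.encoding_noise_var
    with np.errstate(invalid="ignore"):
        disc = np.sqrt(S * S + 2.0 * tradeoff * N * S / Ne)
        g2 = (Ne / (2.0 * N * (S + N))) * (disc - (S + 2.0 * N))
    g2 = np.where(S > 0, np.clip(g2, 0.0, None), 0.0)
    return np.sqrt(g2)


def _nonneg_quadrant_peak_cutoff(g: np.ndarray):
    """Peak/cutoff indices treating index k as the modulation-frequency index
    (1-D) or the FFT-ordered nonnegative quadrant (2-D)."""
    if g.ndim == 1:
        if not np.any(g > 0):
            return 0, -1
        peak = int(np.argmax(g))
        cutoff = int(np.max(np.flatnonzero(g > 0)))
        return peak, cutoff
    # 2-D: restrict to the nonnegative-frequency quadrant in FFT ordering
    nf, nt = g.shape
    qf, qt = nf // 2 + 1, nt // 2 + 1
    quad = g[:qf, :qt]
    if not np.any(quad > 0):
        return (0, 0), (-1, -1)
    peak = np.unravel_index(int(np.argmax(quad)), quad.shape)
    nz = np.nonzero(quad > 0)
    cutoff = (int(nz[0].max()), int(nz[1].max()))
    return (int(peak[0]), int(peak[1])), cutoff


def gain_profile(powers, noise: NoiseSpec, tradeoff: float) -> GainProfile:
    """Elementwise-optimal gains over a 1-D power ladder or 2-D power grid.

    Also locates the gain peak (the best modulation frequency at this SNR)
    and the cutoff (largest index with exactly positive gain — the closed
    form reaches 0 exactly below threshold).
    """
    powers = np.asarray(powers, dtype=float)
    if np.any(powers < 0):
        raise ValueError("powers must be nonnegative")
    g = optimal_gain(powers, noise, tradeoff)
    if not np.any(g > 0):
        warnings.warn("all gains are zero at this SNR", RuntimeWarning, stacklevel=2)
    peak, cutoff = _nonneg_quadrant_peak_cutoff(g)
    return GainProfile(gains=g, peak_index=peak, cutoff_index=cutoff)


def total_objective(
    correlation: CorrelationModel,
    gains,
    noise: NoiseSpec,
    tradeoff: float,
) -> CodingSolution:
    """Evaluate cost, information and the total objective E over all channels."""
    gains = np.asarray(gains, dtype=float)
    S = correlation.eigenvalues
    if gains.shape != S.shape:
        raise ValueError(
            f"gains shape {gains.shape} does not match eigenvalue count {S.shape}"
        )
    N, Ne = noise.input_noise_var, noise.encoding_noise_var
    out_power = gains**2 * (S + N) + Ne
    info_bits = channel_information(gains, S, noise)
    cost = float(out_power.sum())
    total_bits = float(info_bits.sum())
    objective = cost - tradeoff * total_bits * LN2
    return CodingSolution(
        gains=gains,
        information=info_bits,
        output_power=out_power,
        cost=cost,
        total_information=total_bits,
        objective=objective,
        tradeoff=float(tradeoff),
        noise=noise,
    )


def encode(samples, K, noise: NoiseSpec, seed: int) -> np.ndarray:
    """Encode input samples as O = K(x + n) + n_e with fresh Gaussian noise.

    ``samples`` is [n_samples, n_inputs]; K maps inputs to outputs.
    Deterministic for a fixed seed.
    """
    x = np.asarray(samples, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.shape[1] != x.shape[1]:
        raise ValueError("K columns must match the sample dimension")
    rng = np.random.default_rng(seed)
    n = rng.normal(0.0, np.sqrt(noise.input_noise_var), size=x.shape)
    ne = rng.normal(
        0.0, np.sqrt(noise.encoding_noise_var), size=(x.shape[0], K.shape[0])
    )
    return (x + n) @ K.T + ne
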