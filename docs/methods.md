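# Methods

## Model and assumptions

The package treats auditory encoding as a linear map from a mean-subtracted
spectrogram fluctuation to output activity, `O = K(x + n) + n_e`, under three
assumptions: (i) input signal and both noise sources are zero-mean Gaussian,
so second-order statistics fully determine information; (ii) input noise `n`
and encoding noise `n_e` are iid across channels with variances `N` and
`N_e`; (iii) the encoding objective is `E = cost − λ·information`, with cost
the summed output power `Σ⟨O_k²⟩`.  Under these assumptions the optimal
transform factorises into decorrelation (eigenvectors of the input
correlation `R`), per-channel gain control, and a free unitary multiplexing
step; the gain has the closed form given in the README, with the soft
threshold `λ > 2N_e(1 + N/S)` below which a channel is silenced.  Both the
cost and the information are invariant under the unitary step, which is
therefore spent on locality and causality rather than efficiency.

Information is optimised internally in nats (the stationarity algebra is
clean with `λ/2` factors) and reported in bits; the stored `objective` uses
the nats convention, `E = cost − λ·I_nats`, and `CodingSolution` exposes
both unit systems.  The conversion is covered by a unit test.

## Synthetic ensembles

The spectral generator draws `x = α·A·W·z` with `z` standard normal:

* `W` — Gaussian smoothing matrix, entry `exp(−(a−b)²/2λ_s²)`, each row
  normalised to unit L2 norm so every pre-scale channel has unit variance;
  `λ_s` (channel units) sets the correlation range.  The smoothing is
  truncated (non-circular) for the spectral generator — edge channels
  genuinely differ — and circular for the temporal generator, which makes
  its correlation exactly translation invariant and its eigensystem the
  DFT.
* `A` — per-channel scale `exp(−decay_rate·a/n)`, a one-parameter monotone
  stand-in for the decay of natural sound power with frequency.  The
  default `decay_rate = ln(10)/2` puts the highest-frequency channel's
  power at ~10% of the lowest.
* `α` — overall intensity scale; scaling `α` is the model's proxy for sound
  level, since SNR is `S_k/N`.

The analytic correlation `R = α²·A·W·Wᵀ·A` is exact (no sampling noise) and
is the infinite-sample limit of the empirical estimator; tests verify the
Monte-Carlo convergence at n = 10², 10³, 10⁴.

The 2-D modulation power spectrum is a separable exponential envelope,
`S(ω_f, ω_t) ∝ exp(−λ_f|ω_f| − λ_t|ω_t|)`, where the correlation ranges
`λ_f` (octaves) and `λ_t` (seconds) are the decay rates in modulation
frequency: longer-range correlation concentrates power at low modulation
frequencies.  The envelope is normalised to a fixed total power so that
correlation-range comparisons are at equal energy.

What these generators emulate is the second-order structure the theory
needs: decaying power with frequency, finite correlation ranges, and 2-D
modulation spectra decaying in both modulation frequencies.  What they do
not emulate: non-Gaussian (higher-order) structure of natural sounds,
non-stationarity, harmonic stacks, or any phase structure of the waveform.
Passing tests therefore demonstrate the optimality and adaptation logic of
the code under the stated Gaussian conditions, not a fit to any natural
corpus.

## Study conditions (defaults)

The reference conditions, fixed once: 250 frequency channels, 250 samples,
`λ_s = 5` channels, `α = 10`, `N = N_e = 1`.  The correlation-adaptation
comparison uses `λ_s = 2` vs `10` at equal total power (trace-matched); the
intensity ladder spans ×0.03–×10.  Temporal/2-D grids use 64 taps at 1 ms
and 64 spectral rows at 0.02 octave — sizes at which every pipeline stage
runs in seconds while the modulation grids resolve the band-pass/low-pass
distinction and the lobe structure.

The tradeoff default is `λ = 4·N_e`.  Two considerations pin it: the
reference-intensity gain must be band-pass with an interior peak (it is,
`k0 = 36` of 250), and within that band-pass window `λ = 4N_e` minimises
the deviation of `g²S` from flatness at the edge of the high-SNR passband
(the edge deviation is ≈ `(1 + λ²/2(λ−2N_e))·N/S`, minimised at `λ = 4N_e`),
giving the cleanest whitening plateau.  `λ` is exposed in every API and in
the YAML config.

The low-SNR setting of the correlation comparison is ×0.1.  The claim
"longer correlation range ⇒ smaller cutoff" holds exactly while the gain
threshold power lies below the crossing point of the two ensembles'
eigenvalue curves; at extreme attenuation the threshold rises above the
crossing and the ordering genuinely inverts (the long-range ensemble then
keeps more super-threshold channels, since equal total power concentrates
its eigenvalues).  ×0.1 is the regime the adaptation prediction addresses:
the short-range profile is already low-pass while cutoffs remain beyond the
crossing.

## Numerical choices

* Eigendecomposition: `numpy.linalg.eigh`; eigenvalues sorted descending and
  clipped at 0 (tolerance 1e−10 relative, with a warning beyond it); row
  signs fixed so the first nonzero component is positive; numerically
  degenerate blocks ordered by eigenvector zero-crossing count so that
  smaller index ↔ fewer oscillations, keeping the index-to-modulation-
  frequency relation monotone.
* Minimum phase: taps below 1e−12·max are trimmed, roots come from the
  companion matrix (`numpy.roots`), roots with modulus > 1+1e−8 are
  reflected to their conjugate reciprocals, and roots within 1e−8 of the
  unit circle are left in place (they belong to both factorisations).  The
  polynomial is rebuilt from its roots in **Leja order** — each next root
  maximises its distance product to those already multiplied in — because
  band-limited gain profiles put dozens of clustered zeros on the unit
  circle and the naive sequential product loses ~3 digits per cluster;
  with Leja ordering the magnitude response is preserved to ~1e−14 at
  degree 63.  The rescaling factor `Π|r|` over reflected roots keeps the
  magnitude response exact.
* Acausal kernels are truncated where `|coeffs| < 1e−9·max` before
  causalization to keep the polynomial degree modest.
* Overall filter sign: largest-magnitude tap positive (the sign is pure
  unitary freedom).
* Cutoff conventions: for analytic gains the cutoff is the largest index
  with `g > 0` exactly (the closed form reaches 0 exactly); for measured
  MTFs a relative threshold (default 5% of max) is used, since assembled
  kernels never vanish exactly.  MTF argmax ties resolve to the lowest
  frequency, the conservative choice for band-pass claims.
* Band-pass vs low-pass: band-pass iff some nonzero frequency exceeds the
  zero-frequency magnitude by >10% (configurable margin).
* Lobe detection: maximal same-sign runs with peak ≥ 5% of the global max
  and ≥ 2 taps; main-lobe width is the FWHM of the strongest lobe.  These
  defaults are frozen in the tests.
* Degenerate inputs: all-zero gain profiles raise in filter construction
  and warn in `gain_profile`; the whitening diagnostic returns
  not-applicable when no channel has `S/N ≥ 100`.

## Design choices where the design was open

* Per-axis measures of the 2-D gain use the slice through the other axis's
  zero frequency.  The alternative (max over the other axis) plateaus at
  the global gain maximum across many rows, so its argmax is decided by
  discretization noise.
* The STRF's peak-latency adaptation is measured by the energy-centroid
  latency of the kernel (continuous, monotone across the SNR ladder) rather
  than the argmax bin, which jitters by one sample.
* STRF lobe comparisons use the kernel's frequency profile at peak latency
  and temporal profile at peak frequency; inhibition strength additionally
  uses the most-negative/most-positive value of the whole kernel.  A
  whole-kernel mass ratio is uninformative because the oscillating spectral
  structure makes positive and negative mass nearly equal at any SNR.
* The spectrogram front-end pools linear-frequency STFT power bins onto
  log-spaced (octave) channel centers by nearest-center assignment, which
  conserves total power; an ERB-style mapping is out of scope.
* WAV input is read with `scipy.io.wavfile` (PCM mono, averaged to mono and
  scaled to [−1, 1]).

## Limitations

Adaptation is computed, not mechanistic: the package solves each stimulus
condition's optimum independently and says nothing about the dynamics or
timescale of switching between optima.  Output nonlinearities, non-Gaussian
objectives (sparse coding / ICA), and neuron-to-neuron MTF diversity from
alternative multiplexing transforms are not modelled.  The phase of the
sound waveform is ignored throughout — the model operates on spectrogram
power — so phase-locking phenomena are outside its scope.  Quantitative
comparison against physiological MTF data requires the corresponding
recordings and is not part of the test suite; the tests check the model's
qualitative predictions (band-pass↔low-pass adaptation, cutoff and lobe
ordering) under the synthetic conditions above.
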