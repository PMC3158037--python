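"""Spectral receptive fields from an efficient code.

Generates the reference ensemble of 250 correlated Gaussian input spectra,
eigendecomposes its correlation matrix, assigns each principal component
(spectral 'ripple') its information/cost-optimal gain, and assembles the
spectral receptive fields K = U^T G U.  Printed: the eigenvalue range, the
gain peak and cutoff (in principal-component index k), and the
center-surround structure of one SRF.
"""

import numpy as np

import ecstrf as ec

noise = ec.NoiseSpec(input_noise_var=1.0, encoding_noise_var=1.0)
tradeoff = 4.0

ensemble = ec.make_spectral_ensemble(n_channels=250, n_samples=250, seed=0)
model = ec.estimate_correlation(ensemble)
print(f"eigenpairs: {len(model.eigenvalues)}")
print(f"signal power S_k: max {model.eigenvalues[0]:.1f}, "
      f"median {np.median(model.eigenvalues):.2e}")

gp = ec.gain_profile(model.eigenvalues, noise, tradeoff)
print(f"gain profile: {ec.classify_shape(gp.gains)}, "
      f"peak at k0={gp.peak_index}, cutoff at k_c={gp.cutoff_index}")
# band-pass: the gain is small where SNR is huge (whitening), rises as the
# signal power falls, and cuts off where noise dominates

srf = ec.build_srf(model, gp.gains)[125]
metrics = ec.lobe_metrics(srf)
print(f"SRF #125: {metrics.n_excitatory_lobes} excitatory / "
      f"{metrics.n_inhibitory_lobes} inhibitory lobes, "
      f"main lobe {metrics.main_lobe_width:.2f} octaves wide, "
      f"inhibition/excitation mass ratio {metrics.inhibitory_strength_ratio:.2f}")
# the excitatory center on the neuron's own channel with inhibitory flanks is
# the contrast-enhancing (decorrelating) shape expected at high SNR
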