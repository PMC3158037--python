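import numpy as np
import pytest

import ecstrf as ec


@pytest.fixture(scope="session")
def noise():
    return ec.NoiseSpec(input_noise_var=1.0, encoding_noise_var=1.0)


@pytest.fixture(scope="session")
def tradeoff():
    return 4.0


@pytest.fixture(scope="session")
def reference_model():
    """Analytic correlation model of the reference 250-channel ensemble."""
    R = ec.analytic_correlation_matrix(250)
    return ec.correlation_model_from_matrix(R)


@pytest.fixture(scope="session")
def reference_gains(reference_model, noise, tradeoff):
    return ec.gain_profile(reference_model.eigenvalues, noise, tradeoff)


@pytest.fixture(scope="session")
def strf_grid():
    """FFT-ordered modulation-frequency grids for 2-D kernels:
    64 rows at 0.02 oct spacing, 64 columns at 1 ms."""
    wf = np.fft.fftfreq(64, d=0.02)
    wt = np.fft.fftfreq(64, d=1e-3)
    return wf, wt
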