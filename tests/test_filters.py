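import itertools

import numpy as np
import pytest

import ecstrf as ec
from ecstrf.filters import LinearFilter1D


def filter_from_roots(roots, scale):
    return np.real(scale * np.poly(roots))


class TestBuildSRF:
    def test_unit_gains_give_identity(self, reference_model):
        K = ec.srf_matrix(reference_model, np.ones(reference_model.n))
        assert np.allclose(K, np.eye(reference_model.n), atol=1e-8)

    def test_center_surround_structure(self, reference_model, reference_gains):
        srfs = ec.build_srf(reference_model, reference_gains.gains)
        row = srfs[125].coeffs
        assert np.argmax(row) == 125          # excitatory center on own channel
        assert row.min() < -0.05 * row.max()  # inhibitory surround

    def test_high_frequency_srfs_wider_and_less_suppressed(
        self, reference_model, reference_gains
    ):
        srfs = ec.build_srf(reference_model, reference_gains.gains)

        def core_width(row):
            j = int(np.argmax(row))
            half = row[j] / 2
            left, right = j, j
            while left > 0 and row[left - 1] >= half:
                left -= 1
            while right < len(row) - 1 and row[right + 1] >= half:
                right += 1
            return right - left + 1

        lo, hi = srfs[40].coeffs, srfs[190].coeffs
        assert core_width(lo) <= core_width(hi)
        assert -lo.min() / lo.max() >= -hi.min() / hi.max()

    def test_output_covariance_identity(self, reference_model, reference_gains):
        m, g = reference_model, reference_gains.gains
        K = ec.srf_matrix(m, g)
        lhs = K @ m.R @ K.T
        rhs = (m.eigenvectors.T * (g**2 * m.eigenvalues)) @ m.eigenvectors
        assert np.abs(lhs - rhs).max() <= 1e-8 * np.abs(rhs).max()


class TestAcausalKernel:
    def test_flat_gains_give_delta(self):
        f = ec.acausal_kernel_from_gains(np.ones(16))
        expected = np.zeros(16)
        expected[8] = 1.0
        assert np.allclose(f.coeffs, expected, atol=1e-12)

    def test_even_symmetry_and_magnitude_roundtrip(self):
        g = np.abs(np.fft.fftfreq(32)) * -1 + 0.5  # symmetric triangular gains
        f = ec.acausal_kernel_from_gains(g)
        c = f.coeffs
        o = f.origin_index
        for k in range(1, o):
            assert np.isclose(c[o + k], c[o - k], atol=1e-10)
        mag = np.abs(np.fft.fft(np.fft.ifftshift(c)))
        assert np.allclose(mag, g, atol=1e-8)

    def test_asymmetric_gains_rejected(self):
        g = np.linspace(1, 0, 16)
        with pytest.raises(ValueError):
            ec.acausal_kernel_from_gains(g)


class TestMinimumPhase:
    def test_already_minimum_phase_unchanged(self):
        f = LinearFilter1D([1.0, 0.5], 1.0, False, 0)
        out = ec.minimum_phase(f)
        assert np.allclose(out.coeffs, [1.0, 0.5], atol=1e-9)

    def test_single_root_reflection(self):
        f = LinearFilter1D([0.5, 1.0], 1.0, False, 0)
        out = ec.minimum_phase(f)
        assert np.allclose(out.coeffs, [1.0, 0.5], atol=1e-9)
        a = np.abs(np.fft.fft([0.5, 1.0], 64))
        b = np.abs(np.fft.fft(out.coeffs, 64))
        assert np.allclose(a, b, atol=1e-9)

    def test_magnitude_preserved_random_taps(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            h = rng.standard_normal(rng.integers(2, 12))
            out = ec.minimum_phase(LinearFilter1D(h, 1.0, False, 0))
            a = np.abs(np.fft.fft(h, 128))
            b = np.abs(np.fft.fft(out.coeffs, 128))
            assert np.abs(a - b).max() <= 1e-6 * a.max()

    def test_energy_front_loading_beats_all_reflections(self):
        # among all 2^r magnitude-equivalent root-reflection assignments the
        # minimum-phase filter dominates every partial energy sum
        rng = np.random.default_rng(21)
        for _ in range(10):
            h = rng.standard_normal(8)
            out = ec.minimum_phase(LinearFilter1D(h, 1.0, False, 0))
            cum_min = np.cumsum(out.coeffs**2)
            roots = np.roots(h)
            off_circle = [r for r in roots if abs(abs(r) - 1.0) > 1e-8]
            for flips in itertools.product([False, True], repeat=len(off_circle)):
                alt_roots = [
                    1.0 / np.conj(r) if flip else r
                    for r, flip in zip(off_circle, flips)
                ]
                alt_roots += [r for r in roots if abs(abs(r) - 1.0) <= 1e-8]
                scale = h[0] * np.prod(
                    [abs(r) for r, flip in zip(off_circle, flips) if flip]
                )
                alt = filter_from_roots(alt_roots, scale)
                cum_alt = np.cumsum(alt**2)
                assert np.all(cum_min >= cum_alt - 1e-8 * cum_min[-1])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        h = rng.standard_normal(10)
        once = ec.minimum_phase(LinearFilter1D(h, 1.0, False, 0))
        twice = ec.minimum_phase(once)
        assert np.allclose(once.coeffs, twice.coeffs, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ec.minimum_phase(LinearFilter1D(np.zeros(4), 1.0, False, 0))


@pytest.fixture(scope="module")
def temporal_spectrum():
    R = ec.analytic_correlation_matrix(
        64, intensity_scale=10.0, smoothing_length=5.0, circular=True
    )
    return R[0]


class TestBuildTRF:
    def test_high_snr_bandpass_with_alternating_lobes(
        self, temporal_spectrum, noise, tradeoff
    ):
        S = ec.fourier_decorrelate(temporal_spectrum)
        trf = ec.build_trf(S, noise, tradeoff)
        assert trf.causal and trf.origin_index == 0
        mag = np.abs(np.fft.fft(trf.coeffs, 64))
        assert ec.classify_shape(mag[:33]) == "band-pass"
        lm = ec.lobe_metrics(trf)
        assert lm.n_excitatory_lobes + lm.n_inhibitory_lobes >= 3

    def test_low_snr_single_dominant_positive_bump(
        self, temporal_spectrum, noise, tradeoff
    ):
        S = ec.fourier_decorrelate(temporal_spectrum * 0.05**2)
        trf = ec.build_trf(S, noise, tradeoff)
        mag = np.abs(np.fft.fft(trf.coeffs, 64))
        assert ec.classify_shape(mag[:33]) == "low-pass"
        v = trf.coeffs
        assert v.max() == np.abs(v).max()  # dominant lobe is excitatory
        lm_low = ec.lobe_metrics(trf)
        S_hi = ec.fourier_decorrelate(temporal_spectrum)
        lm_hi = ec.lobe_metrics(ec.build_trf(S_hi, noise, tradeoff))
        assert lm_low.inhibitory_strength_ratio < lm_hi.inhibitory_strength_ratio

    def test_magnitude_equals_gain_profile(self, temporal_spectrum, noise, tradeoff):
        S = ec.fourier_decorrelate(temporal_spectrum)
        g = ec.optimal_gain(S, noise, tradeoff)
        trf = ec.build_trf(S, noise, tradeoff)
        mag = np.abs(np.fft.fft(trf.coeffs, 64))
        assert np.abs(mag - g).max() <= 1e-6 * g.max()


@pytest.fixture(scope="module")
def kernels(strf_grid, noise, tradeoff):
    wf, wt = strf_grid
    out = {}
    for label, scale in (("high", 40.0), ("low", 0.6)):
        mps = ec.modulation_power_2d(wf, wt, corr_params=(1.0, 0.03), scale=scale)
        out[label] = (mps, ec.build_strf(mps, noise, tradeoff, f0=2.0))
    return out


class TestBuildSTRF:
    def test_kernel_is_causal(self, kernels):
        for _, strf in kernels.values():
            assert strf.causal
            assert np.all(strf.latencies >= 0)

    def test_2d_dft_matches_gain_grid(self, kernels, noise, tradeoff):
        for mps, strf in kernels.values():
            g = ec.optimal_gain(mps.power, noise, tradeoff)
            mag = np.abs(np.fft.fft2(np.fft.ifftshift(strf.kernel, axes=0)))
            sup = g > 0
            assert np.abs(mag[sup] - g[sup]).max() <= 0.02 * g.max()
            assert np.abs(mag[~sup]).max() <= 0.02 * g.max()

    def test_low_snr_smoother_kernel(self, kernels):
        def slice_metrics(strf):
            k = strf.kernel
            i, j = np.unravel_index(int(np.argmax(np.abs(k))), k.shape)
            fs = ec.lobe_metrics(
                LinearFilter1D(k[:, j], strf.freq_step, False, k.shape[0] // 2)
            )
            ts = ec.lobe_metrics(LinearFilter1D(k[i, :], strf.time_step, True, 0))
            lobes = (
                fs.n_excitatory_lobes + fs.n_inhibitory_lobes
                + ts.n_excitatory_lobes + ts.n_inhibitory_lobes
            )
            inhibition = -k.min() / k.max()
            return lobes, fs.main_lobe_width, ts.main_lobe_width, inhibition

        hi = slice_metrics(kernels["high"][1])
        lo = slice_metrics(kernels["low"][1])
        assert lo[0] < hi[0]        # fewer lobes at low SNR
        assert lo[1] >= hi[1]       # wider spectral main lobe
        assert lo[2] >= hi[2]       # wider temporal main lobe
        assert lo[3] < hi[3]        # weaker inhibition

    def test_peak_latency_non_increasing_with_snr(self, strf_grid, noise, tradeoff):
        wf, wt = strf_grid
        centroids = []
        for scale in (0.6, 2.0, 6.0, 20.0, 40.0):
            mps = ec.modulation_power_2d(wf, wt, scale=scale)
            strf = ec.build_strf(mps, noise, tradeoff, f0=2.0)
            e = (strf.kernel**2).sum(axis=0)
            centroids.append(float((e * strf.latencies).sum() / e.sum()))
        assert np.all(np.diff(centroids) <= 1e-9)


@pytest.fixture(scope="module")
def strf(strf_grid, noise, tradeoff):
    wf, wt = strf_grid
    mps = ec.modulation_power_2d(wf, wt, scale=40.0)
    return ec.build_strf(mps, noise, tradeoff, f0=2.0)


class TestApplySTRF:
    def _spectrogram(self, strf, n_channels=100, n_frames=120):
        return ec.Spectrogram(
            power=np.zeros((n_channels, n_frames)),
            mean_power=np.zeros(n_channels),
            freq_axis=np.arange(n_channels) * strf.freq_step,
            time_axis=np.arange(n_frames) * strf.time_step,
        )

    def test_impulse_reproduces_kernel_row(self, strf):
        sg = self._spectrogram(strf)
        f0_idx = int(np.argmin(np.abs(sg.freq_axis - strf.f0)))
        row = 20
        channel = f0_idx + (row - strf.kernel.shape[0] // 2)
        t_star = 30
        sg.power[channel, t_star] = 1.0
        r = ec.apply_strf(sg, strf)
        expected = np.zeros(sg.power.shape[1])
        nt = strf.kernel.shape[1]
        expected[t_star : t_star + nt] = strf.kernel[row][: sg.power.shape[1] - t_star]
        assert np.allclose(r, expected, atol=1e-12)

    def test_matched_pattern_elicits_peak_response(self, strf):
        sg = self._spectrogram(strf, n_channels=200, n_frames=200)
        f0_idx = int(np.argmin(np.abs(sg.freq_axis - strf.f0)))
        nf, nt = strf.kernel.shape
        t0 = 80
        # present the time-reversed kernel so the convolution aligns at t0+nt-1
        for i in range(nf):
            c = f0_idx + (i - nf // 2)
            sg.power[c, t0 : t0 + nt] = strf.kernel[i][::-1]
        r = ec.apply_strf(sg, strf)
        assert int(np.argmax(r)) == t0 + nt - 1

    def test_zero_input_zero_response(self, strf):
        sg = self._spectrogram(strf)
        assert np.all(ec.apply_strf(sg, strf) == 0)

    def test_axis_step_mismatch_rejected(self, strf):
        sg = self._spectrogram(strf)
        sg.freq_axis = sg.freq_axis * 2.0
        with pytest.raises(ValueError):
            ec.apply_strf(sg, strf)
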