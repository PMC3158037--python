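"""HDF5 / CSV / JSON persistence for ensembles, kernels and metrics."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .coding import CodingSolution
from .ensembles import SpectralEnsemble
from .filters import LinearFilter1D, STRFKernel

__all__ = [
    "save_ensemble",
    "load_ensemble",
    "save_strf",
    "load_strf",
    "save_filter_csv",
    "save_solution",
]


def save_ensemble(path, ensemble: SpectralEnsemble) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=ensemble.samples)
        f.create_dataset("freq_axis", data=ensemble.freq_axis)
        f.attrs.update(
            intensity_scale=ensemble.intensity_scale,
            decay_rate=ensemble.decay_rate,
            smoothing_length=ensemble.smoothing_length,
            seed=ensemble.seed,
            circular=ensemble.circular,
        )


def load_ensemble(path) -> SpectralEnsemble:
    with h5py.File(path, "r") as f:
        return SpectralEnsemble(
            samples=f["samples"][()],
            freq_axis=f["freq_axis"][()],
            intensity_scale=float(f.attrs["intensity_scale"]),
            decay_rate=float(f.attrs["decay_rate"]),
            smoothing_length=float(f.attrs["smoothing_length"]),
            seed=int(f.attrs["seed"]),
            circular=bool(f.attrs["circular"]),
        )


def save_strf(path, kernel: STRFKernel, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kernel", data=kernel.kernel)
        f.create_dataset("freq_offsets", data=kernel.freq_offsets)
        f.create_dataset("latencies", data=kernel.latencies)
        f.attrs.update(
            f0=kernel.f0,
            freq_step=kernel.freq_step,
            time_step=kernel.time_step,
            causal=kernel.causal,
            config_hash=config_hash,
        )


def load_strf(path) -> STRFKernel:
    with h5py.File(path, "r") as f:
        return STRFKernel(
            kernel=f["kernel"][()],
            freq_step=float(f.attrs["freq_step"]),
            time_step=float(f.attrs["time_step"]),
            f0=float(f.attrs["f0"]),
            causal=bool(f.attrs["causal"]),
        )


def save_filter_csv(path, filt: LinearFilter1D) -> None:
    np.savetxt(
        path,
        np.column_stack([filt.lags, filt.coeffs]),
        delimiter=",",
        header="lag,coefficient",
        comments="",
    )


def save_solution(path, solution: CodingSolution) -> None:
    """Scalar summary of a CodingSolution as JSON (vectors go to HDF5)."""
    payload = {
        "cost": solution.cost,
        "total_information_bits": solution.total_information,
        "objective": solution.objective,
        "tradeoff": solution.tradeoff,
        "input_noise_var": solution.noise.input_noise_var,
        "encoding_noise_var": solution.noise.encoding_noise_var,
        "n_channels": int(len(np.ravel(solution.gains))),
        "n_active_channels": int(np.count_nonzero(np.ravel(solution.gains))),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
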