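"""Forward simulation of raw CSI k-space data from a phantom.

Phase-encode step n (acquired in the configured order at time
start_delay + n * TR) excites the slice with a small flip alpha and records
one FID.  The recorded signal is the spatial Fourier sum over voxels of the
per-voxel transverse magnetization:

    FID_n(t) = sum_v e^{2 pi i (k_x u_x + k_y u_y)}
               sum_m M_{v,m}(t_n) sin(alpha) e^{2 pi i f_m t - t / T2*_m}

with u the voxel position as a fraction of the field of view, f_m the
chemical-shift offset and T2*_m the apparent transverse decay of metabolite
m.  Longitudinal magnetization evolves between excitations under the
three-pool exchange model and is depleted by cos(alpha) at every TR.
Pyruvate hydrate is carried as a fixed fraction of the pyruvate
magnetization.  Receiver noise is complex circular Gaussian with equal
standard deviation in both channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

from .acquisition import METABOLITES, AcquisitionParams, encode_order
from .kinetics import Propagator
from .phantom import Phantom
from .rates import ExchangeParams

__all__ = [
    "CSIDataset",
    "simulate_csi",
    "noise_sd_for_snr",
    "save_csi",
    "load_csi",
]


@dataclass(frozen=True)
class CSIDataset:
    """Raw (or partially processed) CSI data.

    ``fids`` is complex, indexed (ky, kx, t) with DC at index matrix // 2
    along each spatial axis.
    """

    fids: np.ndarray
    acq: AcquisitionParams
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.acq.matrix
        if self.fids.shape != (ny, nx, self.acq.n_fid_points):
            raise ValueError(
                f"fids shape {self.fids.shape} does not match acquisition "
                f"({ny}, {nx}, {self.acq.n_fid_points})"
            )
        if not np.all(np.isfinite(self.fids.view(float))):
            raise ValueError("fids must be finite")

    def with_fids(self, fids: np.ndarray, **acq_updates) -> "CSIDataset":
        acq = replace(self.acq, **acq_updates) if acq_updates else self.acq
        return CSIDataset(fids=fids, acq=acq, noise_sd=self.noise_sd, seed=self.seed)


def _encode_magnetizations(
    params: ExchangeParams, acq: AcquisitionParams
) -> np.ndarray:
    """Per-encode longitudinal magnetization (n_encodes, 3), pre-flip."""
    prop = Propagator(params)
    m = np.asarray(params.m0, dtype=float).copy()
    m = prop.advance(m, 0.0, acq.start_delay)
    cos_a = np.cos(np.deg2rad(acq.flip_angle))
    out = np.empty((acq.n_encodes, 3))
    t0 = acq.start_delay
    for n in range(acq.n_encodes):
        out[n] = m
        m = m * cos_a
        m = prop.advance(m, t0 + n * acq.tr, t0 + (n + 1) * acq.tr)
    return out


def simulate_csi(
    phantom: Phantom,
    acq: AcquisitionParams,
    exchange_by_label: Mapping[str, ExchangeParams],
    noise_sd: float = 0.0,
    seed: int = 0,
    hydrate_fraction: float = 0.08,
) -> CSIDataset:
    """Simulate raw k-space CSI data for a phantom.

    Parameters
    ----------
    phantom
        Voxelised tissue model; its grid must match ``acq.matrix``.
    exchange_by_label
        Exchange parameters per phantom label name; every label present in
        the phantom must be covered.
    noise_sd
        Standard deviation of the complex Gaussian receiver noise per
        channel, in the same arbitrary units as the signal.
    seed
        Seeds the noise generator; output is bit-identical for equal seeds.
    hydrate_fraction
        Fraction of the pyruvate magnetization appearing at the pyruvate
        hydrate resonance (the remainder stays at the pyruvate resonance).
    """
    if phantom.grid != acq.matrix:
        raise ValueError(
            f"phantom grid {phantom.grid} does not match acquisition matrix {acq.matrix}"
        )
    missing = [n for n in phantom.label_names if n not in exchange_by_label]
    if missing:
        raise ValueError(f"exchange parameters missing for labels: {missing}")
    if not 0.0 <= hydrate_fraction < 1.0:
        raise ValueError("hydrate_fraction must lie in [0, 1)")
    if acq.n_fid_points / acq.spectral_width > acq.tr:
        raise ValueError("FID readout (n_fid_points / spectral_width) exceeds TR")

    ny, nx = acq.matrix
    order = encode_order(acq)  # (n_enc, 2) of (ky, kx)
    n_enc = order.shape[0]
    nt = acq.n_fid_points
    t = np.arange(nt) * acq.dwell
    sin_a = np.sin(np.deg2rad(acq.flip_angle))

    # per-metabolite time basis
    basis = np.empty((len(METABOLITES), nt), dtype=complex)
    for j, m in enumerate(METABOLITES):
        f = acq.resonance_freqs[m]
        t2s = acq.t2star[m]
        basis[j] = np.exp(2j * np.pi * f * t - t / t2s)

    # voxel positions as FOV fractions, centred
    uy = (np.arange(ny) - ny // 2) / ny
    ux = (np.arange(nx) - nx // 2) / nx

    # per-label phase-weighted perfusion sums S[label][n]
    amps = np.zeros((n_enc, len(METABOLITES)), dtype=complex)
    for name in phantom.label_names:
        vmask = phantom.mask(name)
        if not np.any(vmask):
            continue
        iy, ix = np.nonzero(vmask)
        perf = phantom.perfusion_map[iy, ix]
        phase = np.exp(
            2j
            * np.pi
            * (order[:, 0, None] * uy[iy][None, :] + order[:, 1, None] * ux[ix][None, :])
        )
        s = phase @ perf  # (n_enc,)
        mag = _encode_magnetizations(exchange_by_label[name], acq)  # (n_enc, 3)
        amps[:, 0] += s * mag[:, 0] * (1.0 - hydrate_fraction)  # pyruvate
        amps[:, 1] += s * mag[:, 1]  # lactate
        amps[:, 2] += s * mag[:, 2]  # alanine
        amps[:, 3] += s * mag[:, 0] * hydrate_fraction  # pyruvate hydrate

    fid_by_encode = sin_a * (amps @ basis)  # (n_enc, nt)

    fids = np.zeros((ny, nx, nt), dtype=complex)
    iy = order[:, 0] + ny // 2
    ix = order[:, 1] + nx // 2
    fids[iy, ix, :] = fid_by_encode

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fids = fids + noise_sd * (
            rng.standard_normal(fids.shape) + 1j * rng.standard_normal(fids.shape)
        )

    return CSIDataset(fids=fids, acq=acq, noise_sd=noise_sd, seed=seed)


def noise_sd_for_snr(dataset: CSIDataset, snr: float) -> float:
    """Noise sd giving a k-space peak signal-to-noise ratio ``snr``.

    SNR is defined against the largest FID magnitude in the dataset (the
    centre-out acquisition places it at the k-space centre).
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return float(np.max(np.abs(dataset.fids)) / snr)


# ---------------------------------------------------------------------------
# HDF5 container: /fids (complex, ky x kx x t), /acq attributes, /seed
# ---------------------------------------------------------------------------


def save_csi(path: str | Path, dataset: CSIDataset) -> None:
    """Write a CSIDataset to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("fids", data=dataset.fids)
        f.create_dataset("seed", data=dataset.seed)
        f.create_dataset("noise_sd", data=dataset.noise_sd)
        g = f.create_group("acq")
        acq = dataset.acq
        g.attrs["matrix"] = acq.matrix
        g.attrs["fov"] = acq.fov
        g.attrs["tr"] = acq.tr
        g.attrs["flip_angle"] = acq.flip_angle
        g.attrs["spectral_width"] = acq.spectral_width
        g.attrs["n_fid_points"] = acq.n_fid_points
        g.attrs["encoding_order"] = acq.encoding_order
        g.attrs["slice_thickness"] = acq.slice_thickness
        g.attrs["start_delay"] = acq.start_delay
        g.attrs["resonance_freqs"] = json.dumps(acq.resonance_freqs)
        g.attrs["t2star"] = json.dumps(acq.t2star)


def load_csi(path: str | Path) -> CSIDataset:
    """Read a CSIDataset from its HDF5 container."""
    with h5py.File(path, "r") as f:
        fids = f["fids"][()]
        seed = int(f["seed"][()])
        noise_sd = float(f["noise_sd"][()])
        a = f["acq"].attrs
        acq = AcquisitionParams(
            matrix=tuple(int(x) for x in a["matrix"]),
            fov=tuple(float(x) for x in a["fov"]),
            tr=float(a["tr"]),
            flip_angle=float(a["flip_angle"]),
            spectral_width=float(a["spectral_width"]),
            n_fid_points=int(a["n_fid_points"]),
            encoding_order=str(a["encoding_order"]),
            slice_thickness=float(a["slice_thickness"]),
            start_delay=float(a["start_delay"]),
            resonance_freqs=json.loads(a["resonance_freqs"]),
            t2star=json.loads(a["t2star"]),
        )
    return CSIDataset(fids=fids, acq=acq, noise_sd=noise_sd, seed=seed)
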