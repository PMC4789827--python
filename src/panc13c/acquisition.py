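"""CSI acquisition parameters and phase-encode ordering.

Defaults reproduce the in-vivo protocol: 32x32 data matrix over a 40x40 mm
field of view, TR 30 ms, 5 degree flip, 6 kHz spectral width, centre-out
phase-encode ordering, acquisition starting 20 s after the start of the
pyruvate injection.  Chemical-shift offsets place pyruvate at 0 Hz with
lactate, pyruvate hydrate and alanine at their 7 T carbonyl-carbon positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Metabolites carried through simulation and reconstruction.
METABOLITES = ("pyruvate", "lactate", "alanine", "pyruvate_hydrate")

_DEFAULT_FREQS = {
    "pyruvate": 0.0,
    "lactate": 950.0,
    "alanine": 440.0,
    "pyruvate_hydrate": 640.0,
}

_DEFAULT_T2STAR = {m: 0.015 for m in METABOLITES}


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-sequence and sampling parameters of the 13C CSI acquisition."""

    matrix: tuple[int, int] = (32, 32)
    fov: tuple[float, float] = (40.0, 40.0)  # mm
    tr: float = 0.030  # s
    flip_angle: float = 5.0  # degrees
    spectral_width: float = 6000.0  # Hz
    n_fid_points: int = 128
    encoding_order: str = "centre_out"
    slice_thickness: float = 6.0  # mm
    start_delay: float = 20.0  # s after start of injection
    resonance_freqs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FREQS)
    )
    t2star: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_T2STAR))

    def __post_init__(self) -> None:
        if not 0.0 < self.flip_angle <= 90.0:
            raise ValueError("flip_angle must lie in (0, 90]")
        if self.encoding_order not in ("centre_out", "row_major"):
            raise ValueError("encoding_order must be 'centre_out' or 'row_major'")

    @property
    def dwell(self) -> float:
        """Spectral dwell time, s."""
        return 1.0 / self.spectral_width

    @property
    def n_encodes(self) -> int:
        return self.matrix[0] * self.matrix[1]

    @property
    def total_time(self) -> float:
        """Total acquisition time, s (TR times matrix cells)."""
        return self.tr * self.n_encodes

    @property
    def voxel_size(self) -> tuple[float, float]:
        """Native voxel size, mm."""
        return (self.fov[0] / self.matrix[0], self.fov[1] / self.matrix[1])


def k_indices(n: int) -> np.ndarray:
    """Signed k indices for an n-point axis, DC at array index n // 2."""
    return np.arange(n) - n // 2


def encode_order(acq: AcquisitionParams) -> np.ndarray:
    """Phase-encode acquisition order as an (n_encodes, 2) array of (ky, kx).

    Centre-out ordering acquires the k-space centre first, preserving the
    decaying hyperpolarised magnetization for the contrast-bearing low
    spatial frequencies.  Ties at equal radius are broken by polar angle,
    then by ky.
    """
    ny, nx = acq.matrix
    ky, kx = np.meshgrid(k_indices(ny), k_indices(nx), indexing="ij")
    pairs = np.stack([ky.ravel(), kx.ravel()], axis=1)
    if acq.encoding_order == "row_major":
        return pairs
    radius = np.hypot(pairs[:, 0], pairs[:, 1])
    angle = np.mod(np.arctan2(pairs[:, 1], pairs[:, 0]), 2.0 * math.pi)
    order = np.lexsort((pairs[:, 0], angle, radius))
    return pairs[order]
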