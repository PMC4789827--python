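"""Digital phantoms standing in for the imaged mouse abdomen.

A phantom is a 2-D label map on the acquisition grid: a connected pancreas
region (mirroring the axial slice through the pancreas selected from the 1H
images), optionally a second organ, each carrying a disease-stage metabolic
profile, plus a per-voxel perfusion map scaling the local pyruvate delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stages import DiseaseStageProfile, Stage, stage_profile

BACKGROUND = 0


@dataclass(frozen=True)
class RegionSpec:
    """An elliptical tissue region in fractional grid coordinates."""

    name: str
    stage: Stage | str
    center: tuple[float, float] = (0.5, 0.5)  # (row, col), fraction of grid
    radii: tuple[float, float] = (0.2, 0.3)  # fraction of grid
    angle: float = 0.0  # degrees


@dataclass(frozen=True)
class PhantomSpec:
    """Description of a phantom: grid, regions and perfusion heterogeneity."""

    grid: tuple[int, int] = (32, 32)
    voxel_size: float = 1.25  # mm
    regions: tuple[RegionSpec, ...] = (
        RegionSpec(name="pancreas", stage=Stage.CONTROL),
    )
    perfusion_sigma: float = 0.0  # lognormal sd of per-voxel bolus scale


@dataclass(frozen=True)
class Phantom:
    """Voxelised tissue model: labels, stage profiles and perfusion."""

    grid: tuple[int, int]
    voxel_size: float
    label_map: np.ndarray  # int, 0 = background
    label_names: tuple[str, ...]  # index i+1 in label_map -> label_names[i]
    stage_by_label: dict[str, DiseaseStageProfile]
    perfusion_map: np.ndarray

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of the voxels carrying the named label."""
        idx = self.label_names.index(name) + 1
        return self.label_map == idx


def _ellipse_mask(
    grid: tuple[int, int], region: RegionSpec
) -> np.ndarray:
    ny, nx = grid
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cy, cx = region.center[0] * ny, region.center[1] * nx
    ry, rx = region.radii[0] * ny, region.radii[1] * nx
    th = np.deg2rad(region.angle)
    dy, dx = rows - cy, cols - cx
    u = dy * np.cos(th) + dx * np.sin(th)
    v = -dy * np.sin(th) + dx * np.cos(th)
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def build_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Rasterise a phantom spec onto its grid.

    Deterministic for a fixed seed (the seed only drives perfusion
    heterogeneity).  Later regions overwrite earlier ones where they overlap.

    Raises
    ------
    ValueError
        If the grid is smaller than 8x8, no region is named ``pancreas``, or
        the pancreas rasterises to zero voxels.
    """
    ny, nx = spec.grid
    if ny < 8 or nx < 8:
        raise ValueError("phantom grid must be at least 8x8")
    names = [r.name for r in spec.regions]
    if "pancreas" not in names:
        raise ValueError("phantom must contain a region named 'pancreas'")
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")

    label_map = np.zeros(spec.grid, dtype=np.int16)
    stage_by_label: dict[str, DiseaseStageProfile] = {}
    for i, region in enumerate(spec.regions, start=1):
        mask = _ellipse_mask(spec.grid, region)
        label_map[mask] = i
        stage_by_label[region.name] = stage_profile(region.stage)
    if not np.any(label_map == names.index("pancreas") + 1):
        raise ValueError("pancreas region rasterised to zero voxels")

    rng = np.random.default_rng(seed)
    if spec.perfusion_sigma > 0:
        perfusion = rng.lognormal(
            mean=-0.5 * spec.perfusion_sigma**2,
            sigma=spec.perfusion_sigma,
            size=spec.grid,
        )
    else:
        perfusion = np.ones(spec.grid)
    perfusion = np.where(label_map > 0, perfusion, 0.0)

    return Phantom(
        grid=spec.grid,
        voxel_size=spec.voxel_size,
        label_map=label_map,
        label_names=tuple(names),
        stage_by_label=stage_by_label,
        perfusion_map=perfusion,
    )
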