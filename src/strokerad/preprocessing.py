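"""Volume containers and the preprocessing chain.

A raw HU volume plus its volume-of-interest (VOI) mask is converted into the
representation all texture features are computed on:

1. isotropic resampling (trilinear image / nearest-neighbour mask),
2. intensity normalization: clip to a fixed brain window, map to [0, 1],
3. fixed-bin-count gray-level discretization to integer levels 1..n_bins.

Fixed bins over a fixed window are applied identically to every subject so
that discretized levels are comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class CTVolume:
    """3D grid of HU values with physical voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class VOIMask:
    """Binary mask aligned to a CTVolume grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels) > 0
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if not self.voxels.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DiscretizedVOI:
    """Integer gray levels 1..n_bins inside the mask, 0 outside."""

    levels: np.ndarray
    n_bins: int
    window: tuple[float, float]
    mask: VOIMask = field(repr=False)

    def __post_init__(self):
        self.levels = np.asarray(self.levels, dtype=np.int64)
        inside = self.levels[self.mask.voxels]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_bins):
            raise ValueError("in-mask levels outside [1, n_bins]")
        if np.any(self.levels[~self.mask.voxels] != 0):
            raise ValueError("out-of-mask levels must be 0")


def _check_aligned(volume: CTVolume, mask: VOIMask) -> None:
    if volume.shape != mask.shape or volume.spacing != mask.spacing:
        raise ValueError(
            f"volume and mask are misaligned: {volume.shape}@{volume.spacing} "
            f"vs {mask.shape}@{mask.spacing}"
        )


def resample_isotropic(
    volume: CTVolume, mask: VOIMask, target_spacing: float
) -> tuple[CTVolume, VOIMask]:
    """Resample to isotropic spacing: trilinear image, nearest mask.

    Output extent per axis = round(extent_mm / target_spacing); voxel k spans
    [k*s, (k+1)*s) with its center at (k+0.5)*s, so grids stay aligned at
    their physical midlines and an input already at the target spacing is
    returned unchanged.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    _check_aligned(volume, mask)
    if all(abs(s - target_spacing) < 1e-12 for s in volume.spacing):
        return (
            CTVolume(volume.voxels.copy(), volume.spacing),
            VOIMask(mask.voxels.copy(), mask.spacing),
        )

    in_shape = np.asarray(volume.shape)
    spacing = np.asarray(volume.spacing)
    out_shape = np.maximum(
        1, np.round(in_shape * spacing / target_spacing).astype(int)
    )
    # target voxel centers in source index coordinates
    grids = np.meshgrid(
        *[
            ((np.arange(n) + 0.5) * target_spacing) / s - 0.5
            for n, s in zip(out_shape, spacing)
        ],
        indexing="ij",
    )
    coords = np.stack(grids)
    new_vox = ndimage.map_coordinates(volume.voxels, coords, order=1, mode="nearest")
    new_mask = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), coords, order=0, mode="nearest"
    )
    if not new_mask.any():
        raise ValueError("resampling emptied the mask")
    t = (target_spacing,) * 3
    return CTVolume(new_vox, t), VOIMask(new_mask, t)


def normalize_intensity(
    volume: CTVolume, mask: VOIMask, window: tuple[float, float]
) -> CTVolume:
    """Clip in-mask HU to the window and map affinely to [0, 1].

    Out-of-mask voxels are left untouched.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"degenerate window {window}")
    _check_aligned(volume, mask)
    out = volume.voxels.copy()
    m = mask.voxels
    out[m] = (np.clip(out[m], lo, hi) - lo) / (hi - lo)
    return CTVolume(out, volume.spacing)


def discretize_gray_levels(
    volume: CTVolume, mask: VOIMask, n_bins: int, window: tuple[float, float] = (0.0, 1.0)
) -> DiscretizedVOI:
    """Uniform bins on [0, 1]: level = min(n_bins, floor(value*n_bins) + 1).

    Values exactly at an internal edge go to the higher bin; value 1.0 maps
    into the top bin.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    _check_aligned(volume, mask)
    m = mask.voxels
    vals = volume.voxels[m]
    if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
        raise ValueError("in-mask values must be normalized to [0, 1]")
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[m] = np.minimum(n_bins, np.floor(vals * n_bins).astype(np.int64) + 1)
    return DiscretizedVOI(levels, n_bins, window, mask)


def preprocess(volume: CTVolume, mask: VOIMask, config) -> tuple[CTVolume, VOIMask, DiscretizedVOI]:
    """Full chain: resample -> normalize -> discretize.

    Returns the resampled normalized volume, resampled mask, and levels.
    """
    config.validate()
    rvol, rmask = resample_isotropic(volume, mask, config.target_spacing_mm)
    nvol = normalize_intensity(rvol, rmask, config.window)
    disc = discretize_gray_levels(nvol, rmask, config.n_bins, config.window)
    return nvol, rmask, disc
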