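"""Texture matrices: gray-level co-occurrence, run-length, and size-zone.

Directions are the four in-plane angles (0, 45, 90, 135 degrees) applied
within each axial slice and accumulated over slices. In slice coordinates
(rows = axis 0, columns = axis 1) the displacement for offset d is:

    angle 0   -> (0,  d)     angle 45  -> (d,  d)
    angle 90  -> (d,  0)     angle 135 -> (d, -d)

For the run-length matrix, "offset" is the sampling step of the lattice ray:
rays advance ``step`` voxels per sample, and maximal same-level in-mask runs
are counted on the sampled sequence (step 1 is the classic run-length
matrix). Size zones are maximal 26-connected 3D components of equal level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..preprocessing import DiscretizedVOI

ANGLES = (0, 45, 90, 135)
_STEPS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


class UndefinedMatrixError(ValueError):
    """No valid voxel pairs / runs exist for the requested geometry."""


@dataclass
class CooccurrenceMatrix:
    """Symmetric normalized co-occurrence probabilities over levels 1..n."""

    p: np.ndarray  # (n_levels, n_levels); index i -> level i+1
    n_pairs: int  # ordered contributing pairs

    def __post_init__(self):
        if self.n_pairs <= 0:
            raise UndefinedMatrixError("co-occurrence matrix has no pairs")


@dataclass
class RunLengthMatrix:
    """R[g-1, r-1] = number of runs of level g and length r."""

    R: np.ndarray
    Nr: int

    def __post_init__(self):
        if self.Nr <= 0:
            raise UndefinedMatrixError("run-length matrix has no runs")


@dataclass
class SizeZoneMatrix:
    """Z[g-1, s-1] = number of 26-connected zones of level g and size s."""

    Z: np.ndarray
    Nz: int
    n_voxels: int

    def __post_init__(self):
        if self.Nz <= 0:
            raise UndefinedMatrixError("size-zone matrix has no zones")


def cooccurrence_matrix(disc: DiscretizedVOI, angle: int, offset: int) -> CooccurrenceMatrix:
    """In-plane GLCM at (angle, offset), symmetrized and normalized.

    Pairs require both voxels in-mask; counts accumulate over all axial
    slices (third array axis).
    """
    if offset < 1:
        raise ValueError("offset must be >= 1")
    di, dj = _STEPS[angle]
    di, dj = di * offset, dj * offset
    lv = disc.levels
    n = disc.n_bins
    nx, ny = lv.shape[0], lv.shape[1]

    # source region such that (i+di, j+dj) stays in the slice
    si = slice(max(0, -di), min(nx, nx - di))
    sj = slice(max(0, -dj), min(ny, ny - dj))
    a = lv[si, sj, :]
    b = lv[si.start + di : si.stop + di, sj.start + dj : sj.stop + dj, :]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise UndefinedMatrixError(f"no in-mask pairs at angle {angle}, offset {offset}")
    ai, bi = a[valid] - 1, b[valid] - 1
    counts = np.bincount(ai * n + bi, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T  # symmetrize: count each pair in both orders
    n_pairs = int(counts.sum())
    return CooccurrenceMatrix(counts / n_pairs, n_pairs)


def _ray_keys(shape, angle: int, step: int):
    """Ray id components and along-ray position for every voxel.

    Voxels sharing (z, invariant, phase) lie on one sampled ray; ``pos``
    increases by 1 between consecutive samples along it.
    """
    ii, jj, kk = np.indices(shape)
    if angle == 0:  # (0, 1)
        inv, phase, pos = ii, jj % step, jj // step
    elif angle == 90:  # (1, 0)
        inv, phase, pos = jj, ii % step, ii // step
    elif angle == 45:  # (1, 1): i - j constant along ray
        inv, phase, pos = ii - jj, jj % step, jj // step
    elif angle == 135:  # (1, -1): i + j constant along ray
        inv, phase, pos = ii + jj, jj % step, jj // step
    else:
        raise ValueError(f"unsupported angle {angle}")
    return kk.ravel(), inv.ravel(), phase.ravel(), pos.ravel()


def run_length_matrix(disc: DiscretizedVOI, angle: int, step: int) -> RunLengthMatrix:
    """Sampled-ray run-length matrix for one (angle, step)."""
    if step < 1:
        raise ValueError("step must be >= 1")
    lv = disc.levels
    z, inv, phase, pos = _ray_keys(lv.shape, angle, step)
    order = np.lexsort((pos, phase, inv, z))
    seq = lv.ravel()[order]
    same_ray = np.zeros(seq.size, dtype=bool)
    same_ray[1:] = (z[order][1:] == z[order][:-1]) & (inv[order][1:] == inv[order][:-1]) & (
        phase[order][1:] == phase[order][:-1]
    )
    # run break where ray changes or level changes
    brk = np.ones(seq.size, dtype=bool)
    brk[1:] = ~same_ray[1:] | (seq[1:] != seq[:-1])
    starts = np.flatnonzero(brk)
    lengths = np.diff(np.append(starts, seq.size))
    levels = seq[starts]
    keep = levels > 0
    levels, lengths = levels[keep], lengths[keep]
    if levels.size == 0:
        raise UndefinedMatrixError(f"no in-mask runs at angle {angle}, step {step}")
    max_r = int(lengths.max())
    R = np.zeros((disc.n_bins, max_r))
    np.add.at(R, (levels - 1, lengths - 1), 1.0)
    return RunLengthMatrix(R, int(levels.size))


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def size_zone_matrix(disc: DiscretizedVOI) -> SizeZoneMatrix:
    """26-connected same-level zone counts over the whole VOI."""
    lv = disc.levels
    n_vox = int((lv > 0).sum())
    if n_vox == 0:
        raise UndefinedMatrixError("empty mask")
    zones = []  # (level, size)
    for g in np.unique(lv[lv > 0]):
        lab, n_comp = ndimage.label(lv == g, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.append((int(g), sizes))
    max_s = max(int(s.max()) for _, s in zones)
    Z = np.zeros((disc.n_bins, max_s))
    for g, sizes in zones:
        cnt = np.bincount(sizes, minlength=max_s + 1)[1:]
        Z[g - 1, :] += cnt
    return SizeZoneMatrix(Z, int(Z.sum()), n_vox)
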