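"""Formfactor (shape) features of the VOI in physical units.

Surface area uses exposed-voxel-face counting: every mask-voxel face not
shared with another mask voxel contributes its physical face area.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import ConvexHull, QhullError

SHAPE_NAMES = (
    "Volume",
    "VoxelCount",
    "SurfaceArea",
    "SurfaceToVolumeRatio",
    "Compactness1",
    "Compactness2",
    "Sphericity",
    "SphericalDisproportion",
    "Maximum3DDiameter",
)


def _exposed_face_area(m: np.ndarray, spacing) -> float:
    sx, sy, sz = spacing
    face_area = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, fa in enumerate(face_area):
        pad = np.zeros((m.ndim, 2), dtype=int)
        pad[axis] = (1, 1)
        mp = np.pad(m, pad)
        inner = np.diff(mp.astype(np.int8), axis=axis)
        total += fa * float(np.abs(inner).sum())
    return total


def _max_diameter(points_mm: np.ndarray) -> float:
    """Largest pairwise distance between voxel centers (hull vertices)."""
    if len(points_mm) == 1:
        return 0.0
    pts = points_mm
    if len(pts) > 500:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except QhullError:  # degenerate (flat) mask: fall back below
            pass
    if len(pts) > 4000:  # block the quadratic pairwise product
        d2 = 0.0
        for i in range(0, len(pts), 1024):
            blk = pts[i : i + 1024]
            diff = blk[:, None, :] - pts[None, :, :]
            d2 = max(d2, float((diff**2).sum(axis=2).max()))
        return math.sqrt(d2)
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2).max()))


def shape_features(mask, spacing=None) -> dict[str, float]:
    """Nine formfactor features of a binary mask with mm spacing."""
    m = np.asarray(mask.voxels) > 0
    if spacing is None:
        spacing = mask.spacing
    if not m.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    n_vox = int(m.sum())
    volume = n_vox * float(spacing.prod())
    area = _exposed_face_area(m, spacing)
    pts = np.argwhere(m) * spacing
    diam = _max_diameter(pts)

    sphericity = (36.0 * math.pi * volume**2) ** (1.0 / 3.0) / area
    return {
        "Volume": volume,
        "VoxelCount": float(n_vox),
        "SurfaceArea": area,
        "SurfaceToVolumeRatio": area / volume,
        "Compactness1": volume / (math.sqrt(math.pi) * area**1.5),
        "Compactness2": 36.0 * math.pi * volume**2 / area**3,
        "Sphericity": sphericity,
        "SphericalDisproportion": 1.0 / sphericity,
        "Maximum3DDiameter": diam,
    }
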