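"""Lesion probability mapping.

Binary lesion masks (all on one grid) are each smoothed with a Gaussian
kernel of the given full-width-half-maximum and then averaged voxelwise,
giving each voxel a value in [0, 1]: the (smoothed) proportion of
patients with a lesion there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, ImageGrid, ScalarMap, _check_same_grid

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class ProbabilityMap:
    grid: ImageGrid
    values: np.ndarray
    n_subjects: int
    fwhm_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any() or (v > 1).any():
            raise ValueError("probability values must lie in [0, 1]")
        self.values = v

    def as_map(self) -> ScalarMap:
        return ScalarMap(self.grid, self.values)


def smooth_gaussian(volume: ScalarMap, fwhm_mm: float) -> ScalarMap:
    """Separable Gaussian smoothing; sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    The FWHM is in millimetres and converted to voxel units per axis;
    fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return ScalarMap(volume.grid, volume.values.copy(), mask=volume.mask)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in volume.grid.voxel_size]
    smoothed = ndimage.gaussian_filter(volume.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return ScalarMap(volume.grid, smoothed)


def build_probability_map(lesion_masks: list[BinaryMask], fwhm_mm: float = 3.0) -> ProbabilityMap:
    """Smooth each lesion mask, then average across patients (clipped to [0, 1])."""
    if not lesion_masks:
        raise ValueError("need at least one lesion mask")
    grid = lesion_masks[0].grid
    acc = np.zeros(grid.dims)
    for m in lesion_masks:
        _check_same_grid(grid, m.grid)
        sm = smooth_gaussian(ScalarMap(grid, m.membership.astype(float)), fwhm_mm)
        acc += sm.values
    mean = np.clip(acc / len(lesion_masks), 0.0, 1.0)
    return ProbabilityMap(grid=grid, values=mean, n_subjects=len(lesion_masks), fwhm_mm=fwhm_mm)
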