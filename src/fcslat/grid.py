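"""Shared volumetric data model.

All pipeline stages operate on a common voxel grid.  The convention is
fixed once, here: voxel indices are 0-based; when ``x_axis_is_left_right``
is set, the left hemisphere is the set of voxels with x index strictly
below the midline plane, which sits between columns (``nx/2 - 0.5``).
Mirror operations therefore require an even number of x columns — there is
no midline voxel to assign to either hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two volumes live on different grids (dims or voxel sizes differ)."""


class DimensionalityError(ValueError):
    """A volume has the wrong number of dimensions for the operation."""


class DataError(ValueError):
    """Voxel data violate a contract (non-finite values, zero variance...)."""


@dataclass(frozen=True)
class ImageGrid:
    """A regular 3D voxel grid with physical voxel sizes in millimetres."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    x_axis_is_left_right: bool = True

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def nx(self) -> int:
        return self.dims[0]

    @property
    def midline(self) -> float:
        """Half-integer x plane separating the hemispheres (nx/2 - 0.5)."""
        return self.nx / 2 - 0.5

    @property
    def n_voxels_total(self) -> int:
        return int(np.prod(self.dims))

    def require_mirrorable(self) -> None:
        """Reject grids on which left/right mirroring is ill-defined."""
        if not self.x_axis_is_left_right:
            raise ValueError("grid does not mark the x axis as left-right")
        if self.nx % 2 != 0:
            raise ValueError(
                f"mirror operations need an even nx (midline between columns); got nx={self.nx}"
            )

    def left_slice(self) -> slice:
        """x-index slice of the left hemisphere (x < midline)."""
        self.require_mirrorable()
        return slice(0, self.nx // 2)

    def right_slice(self) -> slice:
        self.require_mirrorable()
        return slice(self.nx // 2, self.nx)


def _check_same_grid(a: ImageGrid, b: ImageGrid) -> None:
    if a.dims != b.dims or a.voxel_size != b.voxel_size:
        raise GridMismatchError(
            f"grid mismatch: dims {a.dims} vs {b.dims}, voxel sizes {a.voxel_size} vs {b.voxel_size}"
        )


def flip_x(values: np.ndarray) -> np.ndarray:
    """Flip a volume (or 4D run) left-right along the x axis."""
    return values[::-1, ...]


@dataclass
class BinaryMask:
    """Boolean voxel membership on a grid."""

    grid: ImageGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.membership)
        if m.shape != self.grid.dims:
            raise DimensionalityError(
                f"mask shape {m.shape} does not match grid dims {self.grid.dims}"
            )
        self.membership = m.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.membership.sum())

    def usable_for_network(self) -> bool:
        """At least two member voxels are needed for any pairwise network."""
        return self.n_voxels >= 2

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership & other.membership)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership | other.membership)


@dataclass
class ScalarMap:
    """One real value per voxel, defined on a mask (zero outside it)."""

    grid: ImageGrid
    values: np.ndarray
    mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.dims:
            raise DimensionalityError(
                f"map shape {v.shape} does not match grid dims {self.grid.dims}"
            )
        if self.mask is not None:
            _check_same_grid(self.grid, self.mask.grid)
            v = np.where(self.mask.membership, v, 0.0)
        self.values = v

    def in_mask_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values.ravel()
        return self.values[self.mask.membership]


@dataclass
class Bold4D:
    """A 4D BOLD run: (x, y, z, frame) intensities plus repetition time."""

    grid: ImageGrid
    values: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 4:
            raise DimensionalityError(f"BOLD data must be 4D, got ndim={v.ndim}")
        if v.shape[:3] != self.grid.dims:
            raise DimensionalityError(
                f"BOLD spatial shape {v.shape[:3]} does not match grid dims {self.grid.dims}"
            )
        if v.shape[3] < 8:
            raise DimensionalityError(
                f"BOLD runs need at least 8 frames (frequency resolution); got {v.shape[3]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not np.isfinite(v).all():
            bad = np.argwhere(~np.isfinite(v))
            raise DataError(f"non-finite BOLD values at indices (first few): {bad[:5].tolist()}")
        self.values = v

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[3])

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)
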