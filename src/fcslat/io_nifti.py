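"""NIfTI-1 reading/writing and the plain-text sidecar formats.

Volumes are stored in a canonical orientation: the voxel-to-world affine is
a plain scaling by the voxel sizes.  Orientation metadata beyond the
left-right flag of :class:`~fcslat.grid.ImageGrid` is not interpreted —
all data in this pipeline are generated on, or assumed to be on, a common
grid, so registration/resampling never happens here.

Motion parameters are whitespace-delimited text with six columns (three
translations in mm, three rotations in radians), one row per frame.  The
subject table is a CSV with header ``id,group,visit,age,sex,fma,grip``.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import BinaryMask, Bold4D, DataError, DimensionalityError, ImageGrid, ScalarMap

SUBJECT_TABLE_COLUMNS = ["id", "group", "visit", "age", "sex", "fma", "grip"]


class FormatError(ValueError):
    """A file is not a readable NIfTI-1 volume or sidecar table."""


def _grid_from_header(img: nib.Nifti1Image) -> ImageGrid:
    zooms = img.header.get_zooms()[:3]
    return ImageGrid(dims=tuple(int(d) for d in img.shape[:3]),
                     voxel_size=tuple(float(z) for z in zooms))


def _canonical_affine(grid: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.voxel_size
    return aff


def _load(path: str | os.PathLike) -> nib.Nifti1Image:
    try:
        img = nib.load(os.fspath(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path!r} is not a NIfTI volume (got {type(img).__name__})")
    return img


def read_volume(path: str | os.PathLike) -> ScalarMap | BinaryMask:
    """Read a 3D volume; return a BinaryMask when all values are 0/1.

    Raises
    ------
    FormatError
        If the file is not a readable NIfTI-1 volume.
    DimensionalityError
        If the file is 4D (use :func:`read_bold`).
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path!r} has ndim={data.ndim}; expected a 3D volume")
    grid = _grid_from_header(img)
    data = np.asarray(data, dtype=float)
    if np.isin(data, (0.0, 1.0)).all():
        return BinaryMask(grid, data > 0.5)
    return ScalarMap(grid, data)


def read_bold(path: str | os.PathLike, tr_seconds: float | None = None) -> Bold4D:
    """Read a 4D BOLD run.  ``tr_seconds`` overrides the header TR."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"{path!r} has ndim={data.ndim}; expected a 4D BOLD run")
    grid = _grid_from_header(img)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
    if tr_seconds <= 0:
        raise DataError(f"no repetition time available for {path!r}; pass tr_seconds")
    data = np.asarray(data, dtype=float)
    if not np.isfinite(data).all():
        bad = np.argwhere(~np.isfinite(data))
        raise DataError(f"non-finite voxels in {path!r} at (first few): {bad[:5].tolist()}")
    return Bold4D(grid, data, tr_seconds=tr_seconds)


def write_volume(obj: ScalarMap | BinaryMask, path: str | os.PathLike) -> None:
    if isinstance(obj, BinaryMask):
        data = obj.membership.astype(np.uint8)
    else:
        data = obj.values.astype(np.float32)
    img = nib.Nifti1Image(data, _canonical_affine(obj.grid))
    img.header.set_zooms(obj.grid.voxel_size)
    nib.save(img, os.fspath(path))


def write_bold(bold: Bold4D, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(bold.values.astype(np.float32), _canonical_affine(bold.grid))
    img.header.set_zooms(bold.grid.voxel_size + (bold.tr_seconds,))
    nib.save(img, os.fspath(path))


def read_motion(path: str | os.PathLike) -> np.ndarray:
    """Read a 6-column motion-parameter table (one row per frame)."""
    arr = np.loadtxt(os.fspath(path), ndmin=2)
    if arr.shape[1] != 6:
        raise FormatError(f"motion table {path!r} has {arr.shape[1]} columns; expected 6")
    return arr


def write_motion(motion: np.ndarray, path: str | os.PathLike) -> None:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise FormatError(f"motion array has shape {motion.shape}; expected (n_frames, 6)")
    np.savetxt(os.fspath(path), motion, fmt="%.8f")


def read_subject_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUBJECT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"subject table {path!r} lacks columns {missing}")
    return df[SUBJECT_TABLE_COLUMNS + [c for c in df.columns if c not in SUBJECT_TABLE_COLUMNS]]


def write_subject_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)
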