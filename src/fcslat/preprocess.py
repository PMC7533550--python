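"""Temporal preprocessing of BOLD runs before network construction.

The chain is: drop the first volumes (magnetisation equilibrium), regress
out nuisance signals (Friston-24 motion expansion plus mean white-matter
and CSF signals), then band-pass to the low-frequency band of interest.
The order is fixed — regression and filtering do not commute — and is
recorded in the metadata of :func:`preprocess_run`.

The band-pass filter is an ideal (rectangular) frequency-domain filter:
Fourier coefficients with frequency inside [low, high] are kept, all
others zeroed.  This makes the filter a linear, idempotent projection,
which matches the behaviour of the preprocessing tools commonly used for
resting-state connectivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import BinaryMask, Bold4D, DataError, _check_same_grid
from .io_nifti import FormatError

logger = logging.getLogger(__name__)

PIPELINE_ORDER = ("drop_initial_volumes", "nuisance_regress", "bandpass")


@dataclass
class NuisanceMatrix:
    """A per-frame design matrix of confound regressors.

    ``data`` is (n_frames, n_columns); ``labels`` names each column.
    An intercept column is always present (added by the builders).
    """

    data: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise ValueError("design matrix must be 2D (frames x regressors)")
        if not self.labels:
            self.labels = [f"col{i}" for i in range(d.shape[1])]
        if len(self.labels) != d.shape[1]:
            raise ValueError("one label per design column required")
        self.data = d

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.data.shape[1])


def drop_initial_volumes(bold: Bold4D, n_drop: int) -> Bold4D:
    """Remove the first ``n_drop`` frames, preserving the rest in order."""
    if n_drop < 0:
        raise ValueError(f"n_drop must be >= 0, got {n_drop}")
    if n_drop >= bold.n_frames:
        raise ValueError(f"cannot drop {n_drop} of {bold.n_frames} frames")
    if n_drop == 0:
        return bold
    return Bold4D(bold.grid, bold.values[..., n_drop:], tr_seconds=bold.tr_seconds)


def build_friston24(motion6: np.ndarray) -> NuisanceMatrix:
    """Expand six rigid-body motion parameters to the Friston-24 set.

    Columns are, in blocks of six: the parameters m_t, their one-frame
    lags m_{t-1} (zero-filled at t = 0), their squares, and the squared
    lags — 24 regressors in total.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise FormatError(f"motion input has shape {m.shape}; expected (n_frames, 6)")
    if m.shape[0] < 2:
        raise FormatError("at least two frames are needed for the lagged terms")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    cols = np.hstack([m, lag, m**2, lag**2])
    labels = (
        [f"motion{i}" for i in range(6)]
        + [f"motion{i}_lag" for i in range(6)]
        + [f"motion{i}_sq" for i in range(6)]
        + [f"motion{i}_lag_sq" for i in range(6)]
    )
    return NuisanceMatrix(cols, labels)


def build_nuisance_matrix(
    motion6: np.ndarray,
    wm_signal: np.ndarray | None = None,
    csf_signal: np.ndarray | None = None,
) -> NuisanceMatrix:
    """Assemble intercept + Friston-24 + tissue mean signals."""
    friston = build_friston24(motion6)
    t = friston.n_frames
    cols = [np.ones((t, 1)), friston.data]
    labels = ["intercept"] + friston.labels
    for name, sig in (("wm_mean", wm_signal), ("csf_mean", csf_signal)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float).reshape(-1)
            if sig.shape[0] != t:
                raise ValueError(f"{name} has {sig.shape[0]} frames; design has {t}")
            cols.append(sig[:, None])
            labels.append(name)
    return NuisanceMatrix(np.hstack(cols), labels)


def nuisance_regress(
    bold: Bold4D, design: NuisanceMatrix, mask: BinaryMask | None = None
) -> Bold4D:
    """Per-voxel OLS residuals of the time series on the design matrix.

    An intercept is added if the design lacks one.  Rank-deficient designs
    are solved by pseudoinverse with a warning.  With ``mask`` given, only
    member voxels are regressed; the rest are passed through as zeros.
    """
    if design.n_frames != bold.n_frames:
        raise ValueError(
            f"design has {design.n_frames} rows but BOLD has {bold.n_frames} frames"
        )
    x = design.data
    if not any(np.allclose(c, c[0]) and c[0] != 0 for c in x.T):
        x = np.hstack([np.ones((x.shape[0], 1)), x])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            f"rank-deficient nuisance design (rank {rank} < {x.shape[1]} columns); "
            "using pseudoinverse solution",
            stacklevel=2,
        )
        logger.warning("rank-deficient design: rank %d of %d columns", rank, x.shape[1])
    t = bold.n_frames
    if mask is None:
        y = bold.values.reshape(-1, t).T  # (T, V)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        resid = y - x @ beta
        out = resid.T.reshape(bold.values.shape)
    else:
        _check_same_grid(bold.grid, mask.grid)
        y = bold.values[mask.membership].T  # (T, n_in)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        resid = y - x @ beta
        out = np.zeros_like(bold.values)
        out[mask.membership] = resid.T
    return Bold4D(bold.grid, out, tr_seconds=bold.tr_seconds)


def bandpass(bold: Bold4D, low_hz: float, high_hz: float) -> Bold4D:
    """Ideal rectangular band-pass filter along the time axis.

    Keeps Fourier coefficients with frequency in [low_hz, high_hz]
    (inclusive) and zeroes the rest; the DC component is removed whenever
    ``low_hz > 0``.
    """
    nyq = bold.nyquist_hz
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low < high, got low={low_hz}, high={high_hz}")
    if high_hz >= nyq:
        raise ValueError(f"high={high_hz} Hz is not below the Nyquist frequency {nyq} Hz")
    t = bold.n_frames
    freqs = np.fft.rfftfreq(t, d=bold.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(bold.values, axis=3)
    spectrum[..., ~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=t, axis=3)
    return Bold4D(bold.grid, filtered, tr_seconds=bold.tr_seconds)


def tissue_mean_signal(bold: Bold4D, tissue_mask: BinaryMask) -> np.ndarray:
    """Frame-wise arithmetic mean of the series over mask voxels."""
    _check_same_grid(bold.grid, tissue_mask.grid)
    if tissue_mask.n_voxels == 0:
        raise ValueError("tissue mask is empty")
    return bold.values[tissue_mask.membership].mean(axis=0)


def preprocess_run(
    bold: Bold4D,
    motion6: np.ndarray,
    gm_mask: BinaryMask,
    wm_mask: BinaryMask | None = None,
    csf_mask: BinaryMask | None = None,
    n_drop: int = 4,
    band: tuple[float, float] = (0.01, 0.1),
) -> tuple[Bold4D, dict]:
    """Run the fixed chain drop -> regress -> bandpass on one BOLD run.

    Returns the cleaned run (nonzero only inside the gray-matter mask) and
    a metadata dict recording the stage order and parameters.
    """
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.shape[0] == bold.n_frames and n_drop > 0:
        motion6 = motion6[n_drop:]
    cleaned = drop_initial_volumes(bold, n_drop)
    if motion6.shape[0] != cleaned.n_frames:
        raise ValueError(
            f"motion rows ({motion6.shape[0]}) match neither the raw nor the "
            f"dropped frame count ({cleaned.n_frames})"
        )
    wm_sig = tissue_mean_signal(cleaned, wm_mask) if wm_mask is not None else None
    csf_sig = tissue_mean_signal(cleaned, csf_mask) if csf_mask is not None else None
    design = build_nuisance_matrix(motion6, wm_sig, csf_sig)
    cleaned = nuisance_regress(cleaned, design, mask=gm_mask)
    cleaned = bandpass(cleaned, band[0], band[1])
    meta = {
        "pipeline_order": list(PIPELINE_ORDER),
        "n_drop": n_drop,
        "band_hz": list(band),
        "tr_seconds": bold.tr_seconds,
        "n_frames_in": bold.n_frames,
        "n_frames_out": cleaned.n_frames,
        "nuisance_columns": design.labels,
        "filter": "ideal_rectangular_fft",
    }
    return cleaned, meta
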