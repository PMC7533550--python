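"""Voxel-based functional connectivity strength (FCS).

FCS is a weighted degree-centrality map: every gray-matter voxel is a
node, the Pearson correlation r_ij between two voxels' time series is the
candidate edge weight, and the strength of voxel i is

    D_i = sum over j != i of w(r_ij) * [r_ij > r_threshold]

with only positive supra-threshold correlations contributing.  The edge
weight w is the Fisher r-to-z transform atanh(r) by default
(``edge_transform="fisher_z"``); ``"raw_r"`` sums the correlations
themselves.  Raw strengths are standardised across the mask to z-scores,

    z_i = (D_i - mean D) / sd D,

using the population (divisor-N) standard deviation.

Correlations are computed in voxel blocks, accumulating row sums without
ever materialising the full N x N matrix, so real-scale masks (tens of
thousands of voxels) stay within ordinary memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import BinaryMask, Bold4D, DataError, ScalarMap, _check_same_grid

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7  # keeps atanh finite for duplicated series
EDGE_TRANSFORMS = ("fisher_z", "raw_r")


@dataclass
class FcsMap:
    """Raw and standardised FCS with the provenance of their computation.

    ``standardized`` is None for the degenerate case of a constant raw
    map (zero spread cannot be z-scored).
    """

    raw: ScalarMap
    standardized: ScalarMap | None
    r_threshold: float
    edge_transform: str
    mask: BinaryMask
    mean_d: float
    sd_d: float

    def metadata(self) -> dict:
        return {
            "r_threshold": self.r_threshold,
            "edge_transform": self.edge_transform,
            "n_mask_voxels": self.mask.n_voxels,
            "mean_D": self.mean_d,
            "sd_D": self.sd_d,
            "sd_convention": "population (divisor N)",
        }


def _edge_weights(r: np.ndarray, r_threshold: float, edge_transform: str) -> np.ndarray:
    """Apply the positive-threshold edge rule to a block of correlations."""
    if edge_transform not in EDGE_TRANSFORMS:
        raise ValueError(f"edge_transform must be one of {EDGE_TRANSFORMS}, got {edge_transform!r}")
    keep = r > r_threshold  # strict: an edge exactly at threshold contributes nothing
    if edge_transform == "fisher_z":
        clipped = np.clip(r, -R_CLIP, R_CLIP)
        n_clipped = int((np.abs(r) > R_CLIP).sum())
        if n_clipped:
            logger.info("clipped %d correlation(s) to +/-%s before atanh", n_clipped, R_CLIP)
        w = np.arctanh(clipped)
    else:
        w = r
    return np.where(keep, w, 0.0)


def compute_fcs_from_corr(
    corr: np.ndarray, r_threshold: float = 0.2, edge_transform: str = "fisher_z"
) -> np.ndarray:
    """FCS strengths from an explicit correlation matrix (testing entry point)."""
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {c.shape}")
    if np.max(np.abs(c - c.T)) > 1e-10:
        raise ValueError("correlation matrix is not symmetric (beyond 1e-10)")
    if not np.allclose(np.diag(c), 1.0, atol=1e-10):
        raise ValueError("correlation matrix diagonal must be 1")
    if np.max(np.abs(c)) > 1.0 + 1e-10:
        raise ValueError("correlation values must lie in [-1, 1]")
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold must lie in (0, 1), got {r_threshold}")
    w = _edge_weights(c, r_threshold, edge_transform)
    np.fill_diagonal(w, 0.0)
    return w.sum(axis=1)


def _standardized_series(bold: Bold4D, mask: BinaryMask) -> np.ndarray:
    """In-mask series, demeaned and scaled to unit norm (rows: voxels)."""
    x = bold.values[mask.membership]  # (N, T)
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        idx = np.argwhere(mask.membership)[zero][:5]
        raise DataError(
            f"zero-variance time series inside the mask at voxel indices {idx.tolist()}"
        )
    return x / norms[:, None]


def compute_fcs(
    bold: Bold4D,
    mask: BinaryMask,
    r_threshold: float = 0.2,
    edge_transform: str = "fisher_z",
    block_size: int = 512,
) -> FcsMap:
    """Compute the FCS map of one preprocessed BOLD run.

    Parameters
    ----------
    bold
        Preprocessed run; every in-mask voxel must have nonzero variance.
    mask
        Gray-matter mask defining the network nodes (N >= 2).
    r_threshold
        Internodal correlation threshold; only r > r_threshold edges count.
    edge_transform
        ``"fisher_z"`` (default) sums atanh(r); ``"raw_r"`` sums r itself.
    block_size
        Number of voxel rows correlated per block.
    """
    _check_same_grid(bold.grid, mask.grid)
    if not mask.usable_for_network():
        raise ValueError(f"mask has {mask.n_voxels} voxels; at least 2 are required")
    if bold.n_frames < 8:
        raise ValueError(f"need at least 8 frames, got {bold.n_frames}")
    if not 0.0 < r_threshold < 1.0:
        raise ValueError(f"r_threshold must lie in (0, 1), got {r_threshold}")
    x = _standardized_series(bold, mask)
    n = x.shape[0]
    d = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r_block = x[start:stop] @ x.T  # (block, N)
        w = _edge_weights(r_block, r_threshold, edge_transform)
        # remove self-edges (diagonal of the full matrix)
        rows = np.arange(start, stop)
        w[np.arange(stop - start), rows] = 0.0
        d[start:stop] = w.sum(axis=1)
    raw_values = np.zeros(mask.grid.dims)
    raw_values[mask.membership] = d
    raw = ScalarMap(mask.grid, raw_values, mask=mask)
    try:
        standardized, mean_d, sd_d = standardize_fcs(raw, mask, return_moments=True)
    except DataError:
        logger.warning("constant raw FCS map; standardized map unavailable")
        standardized, mean_d, sd_d = None, float(d.mean()), 0.0
    return FcsMap(
        raw=raw,
        standardized=standardized,
        r_threshold=r_threshold,
        edge_transform=edge_transform,
        mask=mask,
        mean_d=mean_d,
        sd_d=sd_d,
    )


def standardize_fcs(
    raw: ScalarMap, mask: BinaryMask, return_moments: bool = False
):
    """Z-score a raw FCS map over the mask (population SD, divisor N)."""
    _check_same_grid(raw.grid, mask.grid)
    vals = raw.values[mask.membership]
    mean = float(vals.mean())
    sd = float(vals.std())  # population SD
    if sd == 0.0:
        raise DataError("all in-mask FCS values are equal; map cannot be standardised")
    z = np.zeros(raw.grid.dims)
    z[mask.membership] = (vals - mean) / sd
    out = ScalarMap(raw.grid, z, mask=mask)
    if return_moments:
        return out, mean, sd
    return out
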