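"""Hemispheric lateralization of FCS within a mirror-symmetric mask.

The mask is the union of the clusters showing group differences in FCS,
made left-right symmetric by mirror superposition (mask OR its x-flip).
The lateralization index of a raw FCS map over that mask is

    LI = (FCS_left - FCS_right) / (FCS_left + FCS_right),

where each term is the sum of raw FCS over the in-mask voxels of one
hemisphere.  LI runs from -1 (all strength on the right) to +1 (all on
the left); 0 means symmetric strength.  Raw (not z-standardised) FCS is
used by default: raw strengths are nonnegative, which is what keeps the
ratio inside [-1, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .fcs import FcsMap
from .grid import BinaryMask, ScalarMap, _check_same_grid, flip_x

logger = logging.getLogger(__name__)


@dataclass
class LiResult:
    li: float  # NaN when both hemisphere sums are zero (undefined)
    fcs_left: float
    fcs_right: float
    mask_id: str = ""
    subject: str = ""
    visit: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.li)


def build_change_mask(cluster_masks: list[BinaryMask]) -> BinaryMask:
    """Voxelwise union of the significant-cluster masks of all contrasts."""
    if not cluster_masks:
        raise ValueError("need at least one cluster mask")
    out = cluster_masks[0].membership.copy()
    for m in cluster_masks[1:]:
        _check_same_grid(cluster_masks[0].grid, m.grid)
        out |= m.membership
    return BinaryMask(cluster_masks[0].grid, out)


def mirror_symmetrize(mask: BinaryMask) -> BinaryMask:
    """Mirror superposition: mask OR its left-right flip.

    The result is exactly invariant under the flip.  Requires an even
    number of x columns (midline between columns) and a grid that marks
    the x axis as left-right.
    """
    mask.grid.require_mirrorable()
    return BinaryMask(mask.grid, mask.membership | flip_x(mask.membership))


def is_mirror_symmetric(mask: BinaryMask) -> bool:
    try:
        mask.grid.require_mirrorable()
    except ValueError:
        return False
    return bool((mask.membership == flip_x(mask.membership)).all())


def compute_li(
    fcs: FcsMap | ScalarMap,
    sym_mask: BinaryMask,
    subject: str = "",
    visit: str = "",
    mask_id: str = "",
) -> LiResult:
    """Lateralization index of a raw FCS map within a symmetric mask.

    When both hemisphere sums are zero the index is undefined and reported
    as NaN (never coerced to 0); callers exclude such results from group
    statistics.
    """
    fcs_map = fcs.raw if isinstance(fcs, FcsMap) else fcs
    _check_same_grid(fcs_map.grid, sym_mask.grid)
    if not is_mirror_symmetric(sym_mask):
        raise ValueError("LI requires a mirror-symmetric mask (see mirror_symmetrize)")
    grid = sym_mask.grid
    vals = np.where(sym_mask.membership, fcs_map.values, 0.0)
    left = float(vals[grid.left_slice()].sum())
    right = float(vals[grid.right_slice()].sum())
    denom = left + right
    if denom == 0.0:
        logger.warning(
            "LI undefined for subject=%r visit=%r: both hemisphere sums are zero",
            subject, visit,
        )
        li = float("nan")
    else:
        li = (left - right) / denom
    return LiResult(li=li, fcs_left=left, fcs_right=right,
                    mask_id=mask_id, subject=subject, visit=visit)
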