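"""Group inference for FCS maps and scalar clinical measures.

Voxelwise inference uses pooled-variance two-sample t maps enhanced by
threshold-free cluster enhancement (TFCE) and corrected for family-wise
error with the permutation distribution of the maximum TFCE statistic.
Scalar measures use the classical toolbox: within-subject one-way
repeated-measures ANOVA with Bonferroni-corrected paired post hocs,
paired and pooled two-sample t tests, the Pearson chi-square for 2x2
tables, and partial correlation with covariates regressed out.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .grid import BinaryMask, ScalarMap, _check_same_grid

logger = logging.getLogger(__name__)

TFCE_E = 0.5
TFCE_H = 2.0
TFCE_N_STEPS = 100
TFCE_CONNECTIVITY = 26

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class StatMap:
    values: ScalarMap
    df: float
    contrast: str = ""
    mask: BinaryMask | None = None


@dataclass
class TfceResult:
    """Enhanced statistic map and its permutation-FWE-corrected p map."""

    enhanced: ScalarMap
    p_fwe: ScalarMap
    n_permutations: int
    seed: int
    e_exponent: float = TFCE_E
    h_exponent: float = TFCE_H
    dh_steps: int = TFCE_N_STEPS
    connectivity: int = TFCE_CONNECTIVITY
    exhaustive: bool = False
    null_max: np.ndarray | None = field(default=None, repr=False)


def _stack_maps(maps: list[ScalarMap], mask: BinaryMask) -> np.ndarray:
    rows = []
    for m in maps:
        _check_same_grid(m.grid, mask.grid)
        rows.append(m.values[mask.membership])
    return np.asarray(rows)  # (n_subjects, n_voxels)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """Vectorised pooled-variance two-sample t over columns; sign A - B."""
    na, nb = a.shape[0], b.shape[0]
    df = na + nb - 2
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    ssa = ((a - a.mean(axis=0)) ** 2).sum(axis=0)
    ssb = ((b - b.mean(axis=0)) ** 2).sum(axis=0)
    pooled_var = (ssa + ssb) / df
    se = np.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    zero = se == 0
    if np.ndim(t) and zero.any():
        logger.info("%d voxel(s) with zero pooled variance; t set to 0", int(zero.sum()))
        t = np.where(zero, 0.0, t)
    elif np.ndim(t) == 0 and zero:
        t = np.float64(0.0)
    return t, df


def two_sample_t_map(
    group_a: list[ScalarMap], group_b: list[ScalarMap], mask: BinaryMask, contrast: str = ""
) -> StatMap:
    """Voxelwise pooled two-sample t (A - B) over the mask."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least two maps")
    a = _stack_maps(group_a, mask)
    b = _stack_maps(group_b, mask)
    t, df = _pooled_t(a, b)
    vol = np.zeros(mask.grid.dims)
    vol[mask.membership] = t
    return StatMap(ScalarMap(mask.grid, vol, mask=mask), df=df, contrast=contrast, mask=mask)


def two_sample_t_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, int]:
    """Pooled two-sample t from summary statistics; returns (t, df)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    if pooled_var == 0.0:
        if mean_a == mean_b:
            return 0.0, df
        return math.inf if mean_a > mean_b else -math.inf, df
    t = (mean_a - mean_b) / math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
    return t, df


def _tfce_array(
    values: np.ndarray,
    e_exponent: float,
    h_exponent: float,
    n_steps: int,
    structure: np.ndarray,
) -> np.ndarray:
    """TFCE of a nonnegative 3D array by a midpoint Riemann sum over heights."""
    out = np.zeros_like(values, dtype=float)
    vmax = float(values.max())
    if vmax <= 0:
        return out
    dh = vmax / n_steps
    for k in range(1, n_steps + 1):
        h = (k - 0.5) * dh  # midpoint heights halve the discretisation bias
        sup = values >= h
        labels, n_lab = ndimage.label(sup, structure=structure)
        if n_lab == 0:
            break
        sizes = np.bincount(labels.ravel())
        out[sup] += (sizes[labels[sup]] ** e_exponent) * h**h_exponent * dh
    return out


def tfce_transform(
    stat: StatMap | ScalarMap | np.ndarray,
    e_exponent: float = TFCE_E,
    h_exponent: float = TFCE_H,
    n_steps: int = TFCE_N_STEPS,
    connectivity: int = TFCE_CONNECTIVITY,
) -> np.ndarray | ScalarMap:
    """Threshold-free cluster enhancement of a one-tailed (>= 0) map.

    Each voxel's score integrates extent^E * height^H over all supra-
    threshold heights up to the map maximum, in ``n_steps`` Riemann steps;
    ``e(h)`` is the size of the connected supra-h component containing the
    voxel under the given neighbourhood (6, 18 or 26).
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    if n_steps < 10:
        raise ValueError(f"n_steps must be >= 10, got {n_steps}")
    if isinstance(stat, StatMap):
        arr, wrap = stat.values.values, stat.values
    elif isinstance(stat, ScalarMap):
        arr, wrap = stat.values, stat
    else:
        arr, wrap = np.asarray(stat, dtype=float), None
    if arr.ndim != 3:
        raise ValueError("TFCE expects a 3D map")
    if (arr < 0).any():
        raise ValueError("TFCE input must be nonnegative (split two-tailed maps first)")
    enhanced = _tfce_array(arr, e_exponent, h_exponent, n_steps, _STRUCTURES[connectivity])
    if wrap is None:
        return enhanced
    return ScalarMap(wrap.grid, enhanced, mask=wrap.mask)


def _label_iterator(n_a: int, n_b: int, n_permutations: int, rng: np.random.Generator):
    """Yield boolean group-A indicator vectors: the observed one first.

    Falls back to exhaustive enumeration when fewer distinct labelings
    exist than permutations requested.
    """
    n = n_a + n_b
    observed = np.zeros(n, dtype=bool)
    observed[:n_a] = True
    n_distinct = math.comb(n, n_a)
    if n_distinct <= n_permutations:
        logger.info(
            "only %d distinct labelings for %d permutations requested; enumerating exhaustively",
            n_distinct, n_permutations,
        )
        def gen():
            for combo in itertools.combinations(range(n), n_a):
                lab = np.zeros(n, dtype=bool)
                lab[list(combo)] = True
                yield lab
        return gen(), n_distinct, True

    def gen():
        yield observed
        for _ in range(n_permutations - 1):
            perm = rng.permutation(n)
            lab = np.zeros(n, dtype=bool)
            lab[perm[:n_a]] = True
            yield lab
    return gen(), n_permutations, False


def permutation_fwe(
    group_a: list[ScalarMap],
    group_b: list[ScalarMap],
    mask: BinaryMask,
    n_permutations: int = 5000,
    seed: int = 0,
    e_exponent: float = TFCE_E,
    h_exponent: float = TFCE_H,
    n_steps: int = TFCE_N_STEPS,
    connectivity: int = TFCE_CONNECTIVITY,
    tail: str = "positive",
) -> TfceResult:
    """TFCE + max-statistic permutation FWE for a two-sample contrast.

    Group labels are permuted; for each labeling the pooled t map is
    computed, its chosen tail rectified (``positive`` keeps max(t, 0),
    ``negative`` keeps max(-t, 0)), TFCE-enhanced, and the maximum over
    the mask recorded.  The observed labeling is part of the null, so no
    corrected p can fall below 1/n_permutations.
    """
    if len(group_a) + len(group_b) < 4:
        raise ValueError("need at least 4 subjects in total")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if tail not in ("positive", "negative"):
        raise ValueError(f"tail must be 'positive' or 'negative', got {tail!r}")
    struct = _STRUCTURES[connectivity]
    a = _stack_maps(group_a, mask)
    b = _stack_maps(group_b, mask)
    data = np.vstack([a, b])
    n_a = a.shape[0]
    rng = np.random.default_rng(seed)
    sign = 1.0 if tail == "positive" else -1.0
    member = mask.membership

    labelings, n_used, exhaustive = _label_iterator(n_a, b.shape[0], n_permutations, rng)
    enhanced_obs = None
    null_max = np.empty(n_used)
    vol = np.zeros(mask.grid.dims)
    for i, lab in enumerate(labelings):
        t, _ = _pooled_t(data[lab], data[~lab])
        vol[member] = np.maximum(sign * t, 0.0)
        enh = _tfce_array(vol, e_exponent, h_exponent, n_steps, struct)
        null_max[i] = enh[member].max() if member.any() else 0.0
        if i == 0 and not exhaustive:
            enhanced_obs = enh.copy()
    if exhaustive:
        # observed labeling = first n_a subjects in group A
        t, _ = _pooled_t(data[:n_a], data[n_a:])
        vol[member] = np.maximum(sign * t, 0.0)
        enhanced_obs = _tfce_array(vol, e_exponent, h_exponent, n_steps, struct)

    p = np.ones(mask.grid.dims)
    obs_in = enhanced_obs[member]
    # corrected p at voxel v: fraction of null maxima >= observed enhancement
    p_in = (null_max[None, :] >= obs_in[:, None]).mean(axis=1)
    p[member] = p_in
    return TfceResult(
        enhanced=ScalarMap(mask.grid, enhanced_obs, mask=mask),
        p_fwe=ScalarMap(mask.grid, np.where(member, p, 1.0)),
        n_permutations=n_used,
        seed=seed,
        e_exponent=e_exponent,
        h_exponent=h_exponent,
        dh_steps=n_steps,
        connectivity=connectivity,
        exhaustive=exhaustive,
        null_max=null_max,
    )


def two_tailed_contrast(
    group_a: list[ScalarMap],
    group_b: list[ScalarMap],
    mask: BinaryMask,
    alpha: float = 0.05,
    **kwargs,
) -> dict:
    """Two-tailed voxelwise inference as two one-tailed TFCE runs.

    Each tail is tested at alpha/2; the significance mask is the union of
    the two tails' suprathreshold voxels.
    """
    pos = permutation_fwe(group_a, group_b, mask, tail="positive", **kwargs)
    neg = permutation_fwe(group_a, group_b, mask, tail="negative", **kwargs)
    sig = (pos.p_fwe.values < alpha / 2) | (neg.p_fwe.values < alpha / 2)
    sig &= mask.membership
    return {
        "positive": pos,
        "negative": neg,
        "significant": BinaryMask(mask.grid, sig),
        "alpha": alpha,
    }


def _complete_table(values: pd.DataFrame | np.ndarray) -> np.ndarray:
    x = values.to_numpy(dtype=float) if isinstance(values, pd.DataFrame) else np.asarray(values, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2D subjects-by-visits table")
    if np.isnan(x).any():
        rows = sorted(set(np.argwhere(np.isnan(x))[:, 0].tolist()))
        raise ValueError(f"missing cells in rows {rows}; listwise-complete table required")
    return x


def rm_anova_oneway(values: pd.DataFrame | np.ndarray) -> dict:
    """One-way within-subject (repeated-measures) ANOVA.

    ``values`` is subjects x visits, complete.  F = MS_visits over the
    visit-by-subject interaction mean square, df = (k-1), (k-1)(n-1).  No
    sphericity correction is applied.  A zero interaction mean square with
    a nonzero visit effect is flagged as an infinite F.
    """
    x = _complete_table(values)
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError(f"need >= 2 visits and >= 3 subjects, got {k} visits, {n} subjects")
    grand = x.mean()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_visit = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_visit
    df_visit = k - 1
    df_err = (k - 1) * (n - 1)
    ms_visit = ss_visit / df_visit
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f = 0.0 if ms_visit == 0 else math.inf
        p = 1.0 if ms_visit == 0 else 0.0
    else:
        f = ms_visit / ms_err
        p = float(sps.f.sf(f, df_visit, df_err))
    return {"F": float(f), "df": (df_visit, df_err), "p": p,
            "ms_visit": float(ms_visit), "ms_error": float(ms_err)}


def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Paired t test: one-sample t on the differences, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1D arrays with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return {"t": 0.0, "df": n - 1, "p": 1.0, "infinite": False}
        return {"t": math.copysign(math.inf, d.mean()), "df": n - 1, "p": 0.0, "infinite": True}
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return {"t": float(t), "df": n - 1, "p": p, "infinite": False}


def bonferroni_posthoc(values: pd.DataFrame | np.ndarray,
                       labels: list[str] | None = None) -> pd.DataFrame:
    """All pairwise paired t tests with Bonferroni-adjusted p values.

    The adjustment factor is the number of pairs, k(k-1)/2 (10 for five
    visits); adjusted p = min(1, raw p x n_pairs).
    """
    x = _complete_table(values)
    k = x.shape[1]
    if labels is None:
        labels = (list(values.columns) if isinstance(values, pd.DataFrame)
                  else [f"v{i}" for i in range(k)])
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        res = paired_t(x[:, i], x[:, j])
        rows.append({
            "a": labels[i], "b": labels[j],
            "t": res["t"], "df": res["df"],
            "p_raw": res["p"],
            "p_bonferroni": min(1.0, res["p"] * len(pairs)),
        })
    return pd.DataFrame(rows)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Pearson chi-square for a 2x2 table, df = 1, no continuity correction."""
    counts = (a, b, c, d)
    if any(v < 0 for v in counts):
        raise ValueError("counts must be nonnegative")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        raise ValueError("every row and column margin must be nonzero")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return {"chi2": float(chi2), "df": 1, "p": float(sps.chi2.sf(chi2, 1))}


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None = None
) -> dict:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on the covariates (with intercept) and
    the residuals correlated; df = n - 2 - n_covariates.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = (covariates.to_numpy(dtype=float) if isinstance(covariates, pd.DataFrame)
             else np.asarray(covariates, dtype=float))
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2; got n={n}, covariates={k}")
    design = np.hstack([np.ones((n, 1)), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates (rank-deficient design)")
    proj = design @ np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)[0]
    rx = x - proj[:, 0]
    ry = y - proj[:, 1]
    df = n - 2 - k
    # a variable fully explained by the covariates leaves a residual of pure
    # rounding noise; its partial correlation is 0 by construction
    tol_x = 1e-10 * max(np.linalg.norm(x), 1.0)
    tol_y = 1e-10 * max(np.linalg.norm(y), 1.0)
    if np.linalg.norm(rx) <= tol_x or np.linalg.norm(ry) <= tol_y:
        return {"r": 0.0, "df": df, "p": 1.0}
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r_clamped = max(-1.0, min(1.0, r))
    if abs(r_clamped) >= 1.0:
        p = 0.0
    else:
        t = r_clamped * math.sqrt(df / (1.0 - r_clamped**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return {"r": r, "df": df, "p": p}


def extract_clusters(
    p_fwe: ScalarMap,
    stat: StatMap,
    alpha: float = 0.05,
    connectivity: int = TFCE_CONNECTIVITY,
) -> pd.DataFrame:
    """Cluster table of suprathreshold voxels (p_fwe < alpha).

    Each connected component yields one row: voxel count, the peak |t|
    voxel's grid indices, its millimetre offset from the grid centre, and
    the peak t value.
    """
    _check_same_grid(p_fwe.grid, stat.values.grid)
    sig = p_fwe.values < alpha
    if stat.mask is not None:
        sig &= stat.mask.membership
    labels, n_lab = ndimage.label(sig, structure=_STRUCTURES[connectivity])
    grid = p_fwe.grid
    centre = (np.asarray(grid.dims) - 1) / 2.0
    voxmm = np.asarray(grid.voxel_size)
    rows = []
    tvals = stat.values.values
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        cluster_t = tvals[tuple(idx.T)]
        peak_pos = idx[np.argmax(np.abs(cluster_t))]
        peak_t = tvals[tuple(peak_pos)]
        mm = (peak_pos - centre) * voxmm
        rows.append({
            "cluster": lab,
            "voxel_number": int(idx.shape[0]),
            "peak_x": int(peak_pos[0]), "peak_y": int(peak_pos[1]), "peak_z": int(peak_pos[2]),
            "peak_x_mm": float(mm[0]), "peak_y_mm": float(mm[1]), "peak_z_mm": float(mm[2]),
            "peak_t": float(peak_t),
        })
    return pd.DataFrame(rows, columns=[
        "cluster", "voxel_number", "peak_x", "peak_y", "peak_z",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t",
    ])
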