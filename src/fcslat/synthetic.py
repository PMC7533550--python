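"""Synthetic longitudinal stroke cohort generator.

Emulates the statistical structure the downstream analysis assumes,
without any real data: a cohort of stroke patients scanned at five visits
plus once-scanned healthy controls, each run a 4D BOLD volume on a small
common grid.

The signal model per run is

    y_v(t) = baseline + a_v * latent_k(t) + sqrt(1 - a_v^2) * n_v(t)
             + nuisance_v(t)

where voxels of the same "hub community" share a latent signal (so their
expected pairwise correlation is a^2, planting FCS hubs), n_v is AR(1)
noise, and the nuisance term bundles low-frequency drift, motion-coupled
artifact and tissue (WM/CSF) signals — exactly the components the
preprocessing chain is built to remove.  Hemispheric asymmetry is planted
by giving patients' left-hemisphere communities a per-visit loading
offset whose extremum sits at the 30-day visit, so the group LI
trajectory has a known shape.  Patients additionally carry ellipsoidal
lesion masks confined to a left "basal-ganglia" block of the grid, kept
disjoint from the hub communities so lesion and hub effects stay
separable.

Everything is a pure function of (config, seed): the same configuration
regenerates bit-identical data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .grid import BinaryMask, Bold4D, ImageGrid, flip_x

DEFAULT_SEED = 20200918

# Per-visit motor summaries (mean, SD): FMA (0-100) and right-hand grip (kgf)
DEFAULT_FMA = ((82.85, 22.46), (89.27, 15.47), (94.25, 9.93), (97.25, 4.67), (99.09, 1.91))
DEFAULT_GRIP = ((60.69, 6.02), (64.31, 5.48), (68.40, 5.63), (69.23, 5.17), (73.23, 5.42))


class ConfigError(ValueError):
    """A cohort configuration violates its constraints."""


@dataclass(frozen=True)
class HubCommunity:
    """A cubic block of voxels sharing one latent signal, in the LEFT hemisphere.

    A mirrored right-hemisphere copy is generated automatically (with its
    own latent), so the planted structure is symmetric unless an
    asymmetry offset is applied.
    """

    name: str
    center: tuple[int, int, int]
    half_size: int = 1
    loading: float = 0.6

    def voxels(self, dims: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        cx, cy, cz = self.center
        h = self.half_size
        return [
            (x, y, z)
            for x in range(max(0, cx - h), min(dims[0], cx + h + 1))
            for y in range(max(0, cy - h), min(dims[1], cy + h + 1))
            for z in range(max(0, cz - h), min(dims[2], cz + h + 1))
        ]

    def mirrored_voxels(self, dims: tuple[int, int, int]) -> list[tuple[int, int, int]]:
        return [(dims[0] - 1 - x, y, z) for (x, y, z) in self.voxels(dims)]


def _default_hubs() -> tuple[HubCommunity, ...]:
    return (
        HubCommunity("frontal", center=(5, 6, 8), loading=0.7),
        HubCommunity("occipital", center=(6, 17, 8), loading=0.7),
        HubCommunity("parietal", center=(9, 11, 13), loading=0.7),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Everything that determines the synthetic cohort."""

    n_patients: int = 25
    n_controls: int = 26
    visits: tuple[str, ...] = ("d007", "d014", "d030", "d090", "d180")
    control_visit: str = "d000"
    dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 3.0
    n_frames: int = 124
    hubs: tuple[HubCommunity, ...] = field(default_factory=_default_hubs)
    # Left-minus-right loading offset per visit; extremum at the third visit.
    # With loading 0.7 the left community correlation is 0.41 / 0.31 / 0.16 /
    # 0.31 / 0.41 across visits — at the third visit it falls below the
    # r = 0.2 network threshold, so left hub edges vanish there.
    asymmetry_trajectory: tuple[float, ...] = (-0.06, -0.14, -0.30, -0.14, -0.06)
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 0.5
    motion_amplitude: float = 0.3
    tissue_coupling: float = 0.8
    gm_tissue_bleed: float = 0.15
    fma_spec: tuple[tuple[float, float], ...] = DEFAULT_FMA
    grip_spec: tuple[tuple[float, float], ...] = DEFAULT_GRIP
    motor_subject_rho: float = 0.5
    age_patients: tuple[float, float, float, float] = (52.73, 10.51, 39.0, 73.0)
    age_controls: tuple[float, float, float, float] = (51.84, 8.06, 30.0, 70.0)
    n_male_patients: int = 18
    n_male_controls: int = 15
    # Left "basal-ganglia" block (inclusive index ranges) hosting all lesions
    lesion_block: tuple[tuple[int, int], ...] = ((4, 8), (8, 14), (5, 9))
    baseline_intensity: float = 100.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if len(set(self.visits)) != len(self.visits) or not self.visits:
            raise ConfigError("visits must be nonempty and unique")
        if len(self.asymmetry_trajectory) != len(self.visits):
            raise ConfigError("asymmetry_trajectory needs one offset per visit")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ConfigError("ar1_coefficient must lie in [0, 1)")
        for hub in self.hubs:
            if not 0.0 <= hub.loading <= 1.0:
                raise ConfigError(f"hub {hub.name!r} loading {hub.loading} outside [0, 1]")
            if any(x >= self.dims[0] / 2 for (x, _, _) in hub.voxels(self.dims)):
                raise ConfigError(f"hub {hub.name!r} crosses the midline; centers must be left")
        block = set(itertools.product(
            range(self.lesion_block[0][0], self.lesion_block[0][1] + 1),
            range(self.lesion_block[1][0], self.lesion_block[1][1] + 1),
            range(self.lesion_block[2][0], self.lesion_block[2][1] + 1),
        ))
        for hub in self.hubs:
            overlap = block.intersection(hub.voxels(self.dims))
            if overlap:
                raise ConfigError(
                    f"hub {hub.name!r} overlaps the lesion block at {sorted(overlap)[:3]}; "
                    "hub and lesion effects must stay separable"
                )

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.dims, self.voxel_size, x_axis_is_left_right=True)


def _radial_distance(dims: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = dims
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rx, ry, rz = nx / 2.0 - 1.5, ny / 2.0 - 1.5, nz / 2.0 - 0.5
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    return np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2)


def tissue_masks(config: CohortConfig) -> dict[str, BinaryMask]:
    """Nested-ellipsoid head model: CSF core, WM shell, GM rind (all symmetric)."""
    rho = _radial_distance(config.dims)
    grid = config.grid
    brain = rho <= 1.0
    csf = rho < 0.30
    wm = (rho >= 0.30) & (rho < 0.62)
    gm = (rho >= 0.62) & brain
    return {
        "brain": BinaryMask(grid, brain),
        "csf": BinaryMask(grid, csf),
        "wm": BinaryMask(grid, wm),
        "gm": BinaryMask(grid, gm),
    }


def _ar1(rng: np.random.Generator, phi: float, shape: tuple[int, ...]) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis."""
    e = rng.standard_normal(shape)
    if phi == 0.0:
        return e
    scale = np.sqrt(1.0 - phi**2)
    e[..., 1:] *= scale  # first innovation keeps unit variance (stationary start)
    return lfilter([1.0], [1.0, -phi], e, axis=-1)


def _generate_motion(rng: np.random.Generator, n_frames: int) -> np.ndarray:
    """Slow random-walk head motion: 3 translations (mm), 3 rotations (rad)."""
    steps = rng.standard_normal((n_frames, 6)) * np.array([0.02] * 3 + [0.005] * 3)
    return np.cumsum(steps, axis=0)


@dataclass
class RunData:
    bold: Bold4D
    motion: np.ndarray


@dataclass
class Cohort:
    """Lazy cohort: BOLD runs are regenerated on demand, deterministically."""

    config: CohortConfig
    subjects: pd.DataFrame
    masks: dict[str, BinaryMask]
    lesions: dict[str, BinaryMask]

    def subject_visits(self) -> list[tuple[str, str]]:
        return list(self.subjects[["id", "visit"]].itertuples(index=False, name=None))

    def generate_run(self, subject_id: str, visit: str) -> RunData:
        row = self.subjects[(self.subjects.id == subject_id) & (self.subjects.visit == visit)]
        if row.empty:
            raise KeyError(f"no run for subject {subject_id!r} at visit {visit!r}")
        group = row.iloc[0]["group"]
        return _generate_run(self.config, self.masks, subject_id, visit, group)

    def bold(self, subject_id: str, visit: str) -> Bold4D:
        return self.generate_run(subject_id, visit).bold

    def motion(self, subject_id: str, visit: str) -> np.ndarray:
        return self.generate_run(subject_id, visit).motion


def _run_seed(config: CohortConfig, subject_id: str, visit: str) -> np.random.Generator:
    subj_kind = 0 if subject_id.startswith("P") else 1
    subj_num = int(subject_id[1:])
    visit_num = (config.visits.index(visit) if visit in config.visits else 99)
    ss = np.random.SeedSequence([config.seed, 7, subj_kind, subj_num, visit_num])
    return np.random.default_rng(ss)


def _generate_run(
    config: CohortConfig,
    masks: dict[str, BinaryMask],
    subject_id: str,
    visit: str,
    group: str,
) -> RunData:
    rng = _run_seed(config, subject_id, visit)
    t = config.n_frames
    phi = config.ar1_coefficient
    dims = config.dims
    brain = masks["brain"].membership
    n_brain = int(brain.sum())

    series = _ar1(rng, phi, (n_brain, t))  # independent voxel noise

    # index of each voxel within the brain-flat ordering
    flat_index = np.full(dims, -1, dtype=int)
    flat_index[brain] = np.arange(n_brain)

    # hub communities: shared latent per community per hemisphere
    offset_idx = config.visits.index(visit) if visit in config.visits else None
    offset = (config.asymmetry_trajectory[offset_idx]
              if (group == "patient" and offset_idx is not None) else 0.0)
    for hub in config.hubs:
        for side, voxels in (("left", hub.voxels(dims)), ("right", hub.mirrored_voxels(dims))):
            latent = _ar1(rng, phi, (t,))
            a = hub.loading + (offset if side == "left" else 0.0)
            a = float(np.clip(a, 0.0, 1.0))
            idx = np.array([flat_index[v] for v in voxels if brain[v]])
            if idx.size == 0:
                continue
            series[idx] = a * latent + np.sqrt(1.0 - a**2) * series[idx]

    # tissue latents: strong within WM/CSF, small bleed into GM
    wm_latent = _ar1(rng, phi, (t,))
    csf_latent = _ar1(rng, phi, (t,))
    c = config.tissue_coupling
    for mask_name, latent in (("wm", wm_latent), ("csf", csf_latent)):
        idx = flat_index[masks[mask_name].membership]
        if c > 0 and idx.size:
            series[idx] = c * latent + np.sqrt(1.0 - c**2) * series[idx]
    gm_idx = flat_index[masks["gm"].membership]
    if config.gm_tissue_bleed > 0:
        series[gm_idx] += config.gm_tissue_bleed * wm_latent

    # drift: per-voxel linear ramp plus a slow scanner-period sine
    if config.drift_amplitude > 0:
        ramp = np.linspace(-0.5, 0.5, t)
        slow = np.sin(2 * np.pi * np.arange(t) * config.tr_seconds / (t * config.tr_seconds))
        amp = rng.uniform(0.0, 1.0, n_brain)
        series += config.drift_amplitude * amp[:, None] * (ramp + 0.5 * slow)[None, :]

    # motion-coupled artifact: standardized motion summary times a spatial map
    motion = _generate_motion(rng, t)
    if config.motion_amplitude > 0:
        m_std = motion.std(axis=0)
        m_std[m_std == 0] = 1.0
        m_norm = (motion - motion.mean(axis=0)) / m_std
        summary = m_norm.mean(axis=1)
        weights = rng.uniform(0.0, 1.0, n_brain)
        series += config.motion_amplitude * weights[:, None] * summary[None, :]

    values = np.zeros(dims + (t,))
    values[brain] = config.baseline_intensity + series
    bold = Bold4D(config.grid, values, tr_seconds=config.tr_seconds)
    return RunData(bold=bold, motion=motion)


def _generate_lesion(config: CohortConfig, rng: np.random.Generator) -> BinaryMask:
    (x0, x1), (y0, y1), (z0, z1) = config.lesion_block
    cx = rng.uniform(x0, x1)
    cy = rng.uniform(y0, y1)
    cz = rng.uniform(z0, z1)
    radii = rng.uniform(1.0, 2.2, size=3)
    x, y, z = np.meshgrid(*[np.arange(d) for d in config.dims], indexing="ij")
    ellipsoid = (((x - cx) / radii[0]) ** 2 + ((y - cy) / radii[1]) ** 2
                 + ((z - cz) / radii[2]) ** 2) <= 1.0
    block = np.zeros(config.dims, dtype=bool)
    block[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1] = True
    lesion = ellipsoid & block
    if not lesion.any():  # degenerate draw; keep at least the centre voxel
        lesion[int(round(cx)), int(round(cy)), int(round(cz))] = True
    assert not lesion[config.dims[0] // 2:, :, :].any(), "lesion crossed the midline"
    return BinaryMask(config.grid, lesion)


def _truncated_normal(rng, mean, sd, low, high, size=None):
    out = rng.normal(mean, sd, size=size)
    return np.clip(out, low, high)


def _scaled_male_count(n_male: int, n_reference: int, n_actual: int) -> int:
    """Male count for a cohort of n_actual, keeping the reference proportion.

    Clamped so both sexes are represented whenever n_actual >= 2 (keeps the
    sex chi-square margins nonzero in reduced cohorts).
    """
    if n_actual == n_reference or n_reference == 0:
        count = min(n_male, n_actual)
    else:
        count = round(n_actual * n_male / n_reference)
    if n_actual >= 2:
        count = min(max(count, 1), n_actual - 1)
    return count


def _subject_table(config: CohortConfig) -> pd.DataFrame:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    rows = []
    mean, sd, lo, hi = config.age_patients
    ages_p = _truncated_normal(rng, mean, sd, lo, hi, config.n_patients)
    n_male_p = _scaled_male_count(config.n_male_patients, 25, config.n_patients)
    sex_p = np.array(["male"] * n_male_p + ["female"] * (config.n_patients - n_male_p))
    rng.shuffle(sex_p)
    subj_effect = rng.standard_normal(config.n_patients)
    rho = config.motor_subject_rho
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        for v, visit in enumerate(config.visits):
            fm_mean, fm_sd = config.fma_spec[v]
            gr_mean, gr_sd = config.grip_spec[v]
            eps_f, eps_g = rng.standard_normal(2)
            fma = np.clip(fm_mean + fm_sd * (rho * subj_effect[i]
                                             + np.sqrt(1 - rho**2) * eps_f), 0.0, 100.0)
            grip = max(0.0, gr_mean + gr_sd * (rho * subj_effect[i]
                                               + np.sqrt(1 - rho**2) * eps_g))
            rows.append({"id": pid, "group": "patient", "visit": visit,
                         "age": round(float(ages_p[i]), 1), "sex": sex_p[i],
                         "fma": round(float(fma), 2), "grip": round(float(grip), 2)})
    mean, sd, lo, hi = config.age_controls
    ages_c = _truncated_normal(rng, mean, sd, lo, hi, config.n_controls)
    n_male_c = _scaled_male_count(config.n_male_controls, 26, config.n_controls)
    sex_c = np.array(["male"] * n_male_c + ["female"] * (config.n_controls - n_male_c))
    rng.shuffle(sex_c)
    for i in range(config.n_controls):
        cid = f"C{i + 1:02d}"
        fma = np.clip(rng.normal(98.0, 2.5), 0.0, 100.0)
        grip = max(0.0, rng.normal(70.0, 6.0))
        rows.append({"id": cid, "group": "control", "visit": config.control_visit,
                     "age": round(float(ages_c[i]), 1), "sex": sex_c[i],
                     "fma": round(float(fma), 2), "grip": round(float(grip), 2)})
    return pd.DataFrame(rows, columns=["id", "group", "visit", "age", "sex", "fma", "grip"])


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Build the cohort bundle (tables, masks, lesions; BOLD is lazy)."""
    config = config or CohortConfig()
    masks = tissue_masks(config)
    subjects = _subject_table(config)
    lesions = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13, i]))
        lesions[pid] = _generate_lesion(config, rng)
    return Cohort(config=config, subjects=subjects, masks=masks, lesions=lesions)


def planted_li_trajectory(
    config: CohortConfig, r_threshold: float = 0.2, edge_transform: str = "fisher_z"
) -> dict[str, float]:
    """Analytically expected patient LI per visit, from the planted loadings.

    Considers community edges only (background correlations are zero in
    expectation): two same-community voxels with loading a correlate at
    a^2, so each community contributes (m - 1) * w(a^2) per voxel when
    a^2 exceeds the threshold, with w the edge transform.
    """
    def weight(rho: float) -> float:
        if rho <= r_threshold:
            return 0.0
        return float(np.arctanh(rho)) if edge_transform == "fisher_z" else rho

    out = {}
    for v, visit in enumerate(config.visits):
        left_sum = right_sum = 0.0
        for hub in config.hubs:
            m = len(hub.voxels(config.dims))
            a_left = float(np.clip(hub.loading + config.asymmetry_trajectory[v], 0.0, 1.0))
            a_right = hub.loading
            left_sum += m * (m - 1) * weight(a_left**2)
            right_sum += m * (m - 1) * weight(a_right**2)
        denom = left_sum + right_sum
        out[visit] = 0.0 if denom == 0.0 else (left_sum - right_sum) / denom
    return out


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write the cohort to disk in the formats the readers expect.

    Layout: ``masks/{gm,wm,csf}.nii.gz``, ``lesions/<id>_lesion.nii.gz``,
    ``bold/<id>_<visit>_bold.nii.gz`` with matching
    ``motion/<id>_<visit>_motion.txt``, ``subjects.csv``, and a
    ``cohort_meta.json`` recording the full configuration and seed.
    """
    import json
    import os
    from dataclasses import asdict

    from .io_nifti import write_bold, write_motion, write_subject_table, write_volume

    out = os.fspath(out_dir)
    for sub in ("masks", "lesions", "bold", "motion"):
        os.makedirs(os.path.join(out, sub), exist_ok=True)
    for name in ("gm", "wm", "csf", "brain"):
        write_volume(cohort.masks[name], os.path.join(out, "masks", f"{name}.nii.gz"))
    for pid, lesion in cohort.lesions.items():
        write_volume(lesion, os.path.join(out, "lesions", f"{pid}_lesion.nii.gz"))
    for subject_id, visit in cohort.subject_visits():
        run = cohort.generate_run(subject_id, visit)
        write_bold(run.bold, os.path.join(out, "bold", f"{subject_id}_{visit}_bold.nii.gz"))
        write_motion(run.motion, os.path.join(out, "motion", f"{subject_id}_{visit}_motion.txt"))
    write_subject_table(cohort.subjects, os.path.join(out, "subjects.csv"))
    meta = asdict(cohort.config)
    meta["hubs"] = [asdict(h) for h in cohort.config.hubs]
    with open(os.path.join(out, "cohort_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2, default=list)


def symmetric_config(**overrides) -> CohortConfig:
    """A config with no planted asymmetry (all offsets zero)."""
    base = CohortConfig(**overrides) if overrides else CohortConfig()
    return replace(base, asymmetry_trajectory=(0.0,) * len(base.visits))
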