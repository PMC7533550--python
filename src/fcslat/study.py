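"""End-to-end study replica: model object, fit, and results.

`StrokeConnectivityStudy` wraps a cohort (synthetic or read from disk)
together with a :class:`RunConfig` of analysis parameters, and its
``fit()`` executes the four study steps:

1. per-run preprocessing and FCS map computation;
2. per-visit patient-vs-control voxelwise contrasts with TFCE
   permutation FWE correction (two one-tailed runs at alpha/2);
3. union of the significant clusters across visits, mirror
   superposition, and per-run lateralization indices;
4. scalar statistics — repeated-measures ANOVA with Bonferroni post
   hocs on LI, patient-vs-control LI t tests, motor-score tests, and
   partial correlations of baseline-to-visit changes in FCS/LI with
   changes in FMA/grip, controlling age and sex.

The returned :class:`StudyResults` carries every table plus a manifest
that fully determines the run (parameters, seeds, stage order).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .fcs import FcsMap, compute_fcs
from .grid import BinaryMask, ScalarMap
from .io_nifti import write_volume
from .lateralization import build_change_mask, compute_li, mirror_symmetrize
from .preprocess import preprocess_run
from .stats import (
    StatMap,
    bonferroni_posthoc,
    extract_clusters,
    partial_correlation,
    rm_anova_oneway,
    two_sample_t_map,
    two_sample_t_summary,
    chi_square_2x2,
    two_tailed_contrast,
    paired_t,
)
from .synthetic import Cohort

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stage-isolated child seed: hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """All analysis parameters of one study run (no silent defaults:
    every field lands in the manifest)."""

    n_drop: int = 4
    band_hz: tuple[float, float] = (0.01, 0.1)
    r_threshold: float = 0.2
    edge_transform: str = "fisher_z"
    n_permutations: int = 5000
    alpha: float = 0.05
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_steps: int = 100
    connectivity: int = 26
    li_source: str = "raw"  # "raw" or "standardized" FCS enters the LI sums
    contrast_maps: str = "standardized"  # which FCS maps the group contrasts use
    delta_fcs: str = "mask_mean"  # scalarisation of per-subject FCS change
    seed: int = 7


@dataclass
class StudyResults:
    """Fitted study: maps, tables and the manifest that reproduces them."""

    config: RunConfig
    manifest: dict
    li_table: pd.DataFrame
    cluster_tables: dict[str, pd.DataFrame]
    contrasts: dict[str, dict]
    change_mask: BinaryMask | None
    sym_mask: BinaryMask | None
    li_anova: dict | None
    li_posthoc: pd.DataFrame | None
    li_vs_hc: pd.DataFrame | None
    motor_tests: pd.DataFrame
    demographics: pd.DataFrame
    correlations: pd.DataFrame
    fcs_maps: dict[tuple[str, str], FcsMap] = field(default_factory=dict, repr=False)

    def li_trajectory(self) -> pd.Series:
        """Patient group-mean LI per visit (undefined LIs excluded)."""
        pat = self.li_table[self.li_table.group == "patient"]
        return pat.groupby("visit", sort=False)["li"].mean()

    def summary(self) -> str:
        lines = ["Stroke FCS/LI study results", "=" * 60]
        lines.append(f"runs analysed: {len(self.li_table)}  "
                     f"(r threshold {self.config.r_threshold}, "
                     f"edge {self.config.edge_transform})")
        for name, tab in self.cluster_tables.items():
            lines.append(f"contrast {name}: {len(tab)} significant cluster(s), "
                         f"{int(tab.voxel_number.sum()) if len(tab) else 0} voxel(s)")
        if self.sym_mask is not None:
            lines.append(f"symmetric change mask: {self.sym_mask.n_voxels} voxels")
        traj = self.li_trajectory()
        if len(traj):
            lines.append("patient mean LI by visit:")
            for visit, val in traj.items():
                lines.append(f"  {visit}: {val:+.4f}")
            lines.append(f"LI extremum at visit {traj.idxmin()}")
        if self.li_anova is not None:
            f, (d1, d2), p = self.li_anova["F"], self.li_anova["df"], self.li_anova["p"]
            lines.append(f"LI repeated-measures ANOVA: F({d1},{d2}) = {f:.2f}, p = {p:.4g}")
        if len(self.correlations):
            n_sig = int((self.correlations.p < 0.05).sum())
            lines.append(f"brain-behaviour partial correlations: "
                         f"{n_sig}/{len(self.correlations)} at p < 0.05")
        return "\n".join(lines)

    def save(self, out_dir: str | os.PathLike) -> None:
        out = os.fspath(out_dir)
        os.makedirs(os.path.join(out, "tables"), exist_ok=True)
        os.makedirs(os.path.join(out, "maps"), exist_ok=True)
        self.li_table.to_csv(os.path.join(out, "tables", "li.csv"), index=False)
        self.motor_tests.to_csv(os.path.join(out, "tables", "motor_tests.csv"), index=False)
        self.demographics.to_csv(os.path.join(out, "tables", "demographics.csv"), index=False)
        self.correlations.to_csv(os.path.join(out, "tables", "correlations.csv"), index=False)
        if self.li_posthoc is not None:
            self.li_posthoc.to_csv(os.path.join(out, "tables", "li_posthoc.csv"), index=False)
        if self.li_vs_hc is not None:
            self.li_vs_hc.to_csv(os.path.join(out, "tables", "li_vs_hc.csv"), index=False)
        for name, tab in self.cluster_tables.items():
            tab.to_csv(os.path.join(out, "tables", f"clusters_{name}.csv"), index=False)
        if self.sym_mask is not None:
            write_volume(self.sym_mask, os.path.join(out, "maps", "sym_change_mask.nii.gz"))
        for name, contrast in self.contrasts.items():
            write_volume(contrast["positive"].p_fwe,
                         os.path.join(out, "maps", f"{name}_p_fwe_pos.nii.gz"))
            write_volume(contrast["negative"].p_fwe,
                         os.path.join(out, "maps", f"{name}_p_fwe_neg.nii.gz"))
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


class StrokeConnectivityStudy:
    """The study model: a cohort plus the analysis configuration.

    Parameters
    ----------
    cohort
        A :class:`~fcslat.synthetic.Cohort` (or any object with the same
        interface: ``subjects`` table, ``masks`` dict, ``generate_run``).
    config
        Analysis parameters; defaults are the study's stated settings.
    """

    def __init__(self, cohort: Cohort, config: RunConfig | None = None):
        self.cohort = cohort
        self.config = config or RunConfig()

    @classmethod
    def from_cohort(cls, cohort: Cohort, **config_kwargs) -> "StrokeConnectivityStudy":
        return cls(cohort, RunConfig(**config_kwargs))

    # -- step 1 ---------------------------------------------------------
    def _compute_fcs_maps(self) -> dict[tuple[str, str], FcsMap]:
        cfg = self.config
        masks = self.cohort.masks
        out: dict[tuple[str, str], FcsMap] = {}
        for subject_id, visit in self.cohort.subject_visits():
            run = self.cohort.generate_run(subject_id, visit)
            cleaned, _ = preprocess_run(
                run.bold, run.motion, gm_mask=masks["gm"],
                wm_mask=masks.get("wm"), csf_mask=masks.get("csf"),
                n_drop=cfg.n_drop, band=cfg.band_hz,
            )
            out[(subject_id, visit)] = compute_fcs(
                cleaned, masks["gm"], r_threshold=cfg.r_threshold,
                edge_transform=cfg.edge_transform,
            )
            logger.debug("FCS computed for %s %s", subject_id, visit)
        return out

    # -- step 2 ---------------------------------------------------------
    def _group_contrasts(self, fcs_maps) -> tuple[dict, dict, list[BinaryMask]]:
        cfg = self.config
        gm = self.cohort.masks["gm"]
        subjects = self.cohort.subjects
        which = "standardized" if cfg.contrast_maps == "standardized" else "raw"
        controls = subjects[subjects.group == "control"]
        hc_maps = [getattr(fcs_maps[(r.id, r.visit)], which)
                   for r in controls.itertuples()]
        patients = subjects[subjects.group == "patient"]
        visits = list(dict.fromkeys(patients.visit))
        contrasts, cluster_tables, sig_masks = {}, {}, []
        for i, visit in enumerate(visits):
            rows = patients[patients.visit == visit]
            pat_maps = [getattr(fcs_maps[(r.id, r.visit)], which) for r in rows.itertuples()]
            name = f"{visit}_vs_hc"
            contrast = two_tailed_contrast(
                pat_maps, hc_maps, gm, alpha=cfg.alpha,
                n_permutations=cfg.n_permutations,
                seed=stage_seed(cfg.seed, f"contrast_{visit}"),
                e_exponent=cfg.tfce_e, h_exponent=cfg.tfce_h,
                n_steps=cfg.tfce_steps, connectivity=cfg.connectivity,
            )
            contrasts[name] = contrast
            t_map = two_sample_t_map(pat_maps, hc_maps, gm, contrast=name)
            sig = contrast["significant"]
            sig_masks.append(sig)
            p_combined = ScalarMap(
                gm.grid,
                np.minimum(contrast["positive"].p_fwe.values * 2,
                           contrast["negative"].p_fwe.values * 2),
            )
            cluster_tables[name] = extract_clusters(
                p_combined, t_map, alpha=cfg.alpha, connectivity=cfg.connectivity
            )
            logger.info("contrast %s: %d significant voxels", name, sig.n_voxels)
        return contrasts, cluster_tables, sig_masks

    # -- step 3 ---------------------------------------------------------
    def _lateralization(self, fcs_maps, sig_masks):
        cfg = self.config
        union = build_change_mask(sig_masks)
        if union.n_voxels == 0:
            logger.warning("no significant voxels in any contrast; LI undefined")
            return None, None, pd.DataFrame(
                columns=["id", "group", "visit", "li", "fcs_left", "fcs_right", "mask_id"])
        sym = mirror_symmetrize(union)
        mask_id = f"union5_mirror_{sym.n_voxels}vox"
        rows = []
        for (subject_id, visit), fmap in fcs_maps.items():
            source = fmap.raw if cfg.li_source == "raw" else fmap.standardized
            res = compute_li(source, sym, subject=subject_id, visit=visit, mask_id=mask_id)
            group = self.cohort.subjects.loc[
                self.cohort.subjects.id == subject_id, "group"].iloc[0]
            rows.append({"id": subject_id, "group": group, "visit": visit,
                         "li": res.li, "fcs_left": res.fcs_left,
                         "fcs_right": res.fcs_right, "mask_id": mask_id})
        return union, sym, pd.DataFrame(rows)

    # -- step 4 ---------------------------------------------------------
    def _scalar_stats(self, li_table, fcs_maps, sym_mask):
        cfg = self.config
        subjects = self.cohort.subjects
        patients = subjects[subjects.group == "patient"]
        controls = subjects[subjects.group == "control"]
        visits = list(dict.fromkeys(patients.visit))
        baseline = visits[0]

        # demographics (summary two-sample t on age; chi-square on sex)
        age_p = patients.drop_duplicates("id").age
        age_c = controls.age
        t_age, df_age = two_sample_t_summary(
            age_p.mean(), age_p.std(ddof=1), len(age_p),
            age_c.mean(), age_c.std(ddof=1), len(age_c))
        males_p = int((patients.drop_duplicates("id").sex == "male").sum())
        males_c = int((controls.sex == "male").sum())
        chi = chi_square_2x2(males_p, len(age_p) - males_p, males_c, len(age_c) - males_c)
        demographics = pd.DataFrame([
            {"measure": "age", "statistic": t_age, "df": df_age, "test": "two_sample_t"},
            {"measure": "sex", "statistic": chi["chi2"], "df": chi["df"],
             "test": "chi_square", "p": chi["p"]},
        ])

        # motor scores: RM-ANOVA across visits + paired t vs baseline
        motor_rows = []
        for score in ("fma", "grip"):
            wide = patients.pivot(index="id", columns="visit", values=score)[visits]
            anova = rm_anova_oneway(wide)
            motor_rows.append({"measure": score, "test": "rm_anova",
                               "statistic": anova["F"], "df1": anova["df"][0],
                               "df2": anova["df"][1], "p": anova["p"]})
            for visit in visits[1:]:
                res = paired_t(wide[visit].to_numpy(), wide[baseline].to_numpy())
                motor_rows.append({"measure": score, "test": f"paired_t_{visit}_vs_{baseline}",
                                   "statistic": res["t"], "df1": res["df"], "p": res["p"]})
        motor_tests = pd.DataFrame(motor_rows)

        li_anova = li_posthoc = li_vs_hc = None
        correlations = pd.DataFrame(columns=["metric", "motor", "visit", "r", "df", "p"])
        if len(li_table):
            pat_li = li_table[li_table.group == "patient"].dropna(subset=["li"])
            wide_li = pat_li.pivot(index="id", columns="visit", values="li")
            complete = wide_li.dropna()
            n_excluded = len(wide_li) - len(complete)
            if n_excluded:
                logger.warning("excluding %d patient(s) with undefined LI", n_excluded)
            if len(complete) >= 3:
                li_anova = rm_anova_oneway(complete[visits])
                li_posthoc = bonferroni_posthoc(complete[visits])
            hc_li = li_table[(li_table.group == "control")].li.dropna().to_numpy()
            rows = []
            for visit in visits:
                vis_li = pat_li[pat_li.visit == visit].li.to_numpy()
                if len(vis_li) >= 2 and len(hc_li) >= 2:
                    t, df = two_sample_t_summary(
                        vis_li.mean(), vis_li.std(ddof=1), len(vis_li),
                        hc_li.mean(), hc_li.std(ddof=1), len(hc_li))
                    rows.append({"visit": visit, "t": t, "df": df,
                                 "mean_patient": vis_li.mean(), "mean_hc": hc_li.mean()})
            li_vs_hc = pd.DataFrame(rows)

            # brain-behaviour: Δ metric vs Δ motor, controlling age and sex
            correlations = self._delta_correlations(li_table, fcs_maps, sym_mask,
                                                    patients, visits, baseline)
        return demographics, motor_tests, li_anova, li_posthoc, li_vs_hc, correlations

    def _delta_correlations(self, li_table, fcs_maps, sym_mask, patients, visits, baseline):
        cfg = self.config
        pat_ids = list(dict.fromkeys(patients.id))
        demo = patients.drop_duplicates("id").set_index("id")
        covars = pd.DataFrame({
            "age": demo.age,
            "sex": (demo.sex == "male").astype(float),
        }).loc[pat_ids]

        def mask_mean_fcs(subject_id, visit):
            fmap = fcs_maps[(subject_id, visit)]
            source = fmap.raw if cfg.li_source == "raw" else fmap.standardized
            return float(source.values[sym_mask.membership].mean())

        li_lookup = li_table.set_index(["id", "visit"]).li
        motor = patients.set_index(["id", "visit"])
        rows = []
        for visit in visits[1:]:
            deltas = {"fcs": [], "li": [], "fma": [], "grip": []}
            for pid in pat_ids:
                deltas["fcs"].append(mask_mean_fcs(pid, visit) - mask_mean_fcs(pid, baseline))
                deltas["li"].append(li_lookup.get((pid, visit), np.nan)
                                    - li_lookup.get((pid, baseline), np.nan))
                deltas["fma"].append(motor.loc[(pid, visit), "fma"]
                                     - motor.loc[(pid, baseline), "fma"])
                deltas["grip"].append(motor.loc[(pid, visit), "grip"]
                                      - motor.loc[(pid, baseline), "grip"])
            frame = pd.DataFrame(deltas, index=pat_ids).dropna()
            if len(frame) <= covars.shape[1] + 2:
                logger.warning(
                    "visit %s: only %d complete patients; too few for partial "
                    "correlation with %d covariates", visit, len(frame), covars.shape[1])
                continue
            for metric in ("fcs", "li"):
                for score in ("fma", "grip"):
                    res = partial_correlation(frame[metric], frame[score],
                                              covars.loc[frame.index])
                    rows.append({"metric": f"delta_{metric}", "motor": f"delta_{score}",
                                 "visit": visit, "r": res["r"], "df": res["df"],
                                 "p": res["p"]})
        return pd.DataFrame(rows)

    def fit(self, keep_fcs_maps: bool = False) -> StudyResults:
        """Run the full pipeline and return the results object."""
        cfg = self.config
        fcs_maps = self._compute_fcs_maps()
        contrasts, cluster_tables, sig_masks = self._group_contrasts(fcs_maps)
        union, sym, li_table = self._lateralization(fcs_maps, sig_masks)
        demographics, motor_tests, li_anova, li_posthoc, li_vs_hc, correlations = (
            self._scalar_stats(li_table, fcs_maps, sym))

        manifest = {
            "package_version": __version__,
            "run_config": asdict(cfg),
            "pipeline_order": ["preprocess", "fcs", "contrasts", "lateralization", "stats"],
            "stage_seeds": {f"contrast_{v}": stage_seed(cfg.seed, f"contrast_{v}")
                            for v in dict.fromkeys(
                                self.cohort.subjects[self.cohort.subjects.group == "patient"].visit)},
            "cohort": {
                "n_patients": int((self.cohort.subjects.group == "patient").sum()
                                  / max(1, len(set(self.cohort.subjects[
                                      self.cohort.subjects.group == "patient"].visit)))),
                "n_controls": int((self.cohort.subjects.group == "control").sum()),
                "n_runs": len(self.cohort.subjects),
                "grid_dims": list(self.cohort.masks["gm"].grid.dims),
                "gm_voxels": self.cohort.masks["gm"].n_voxels,
            },
            "n_contrasts": len(contrasts),
            "n_li_posthoc_pairs": 0 if li_posthoc is None else len(li_posthoc),
            "n_correlation_sets": len(correlations),
        }
        return StudyResults(
            config=cfg,
            manifest=manifest,
            li_table=li_table,
            cluster_tables=cluster_tables,
            contrasts=contrasts,
            change_mask=union,
            sym_mask=sym,
            li_anova=li_anova,
            li_posthoc=li_posthoc,
            li_vs_hc=li_vs_hc,
            motor_tests=motor_tests,
            demographics=demographics,
            correlations=correlations,
            fcs_maps=fcs_maps if keep_fcs_maps else {},
        )
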