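# Methods

## Problem and scope

`fcslat` implements a voxel-based functional connectivity strength (FCS)
and lateralization analysis for longitudinal resting-state fMRI, of the
kind used to track network reorganisation after a focal left basal-ganglia
stroke across five follow-up visits. The package covers the full analysis
chain — temporal preprocessing, FCS (weighted degree-centrality) mapping,
TFCE permutation inference on group contrasts, mirror-mask lateralization
indices, lesion probability mapping, and the scalar clinical statistics —
plus a synthetic-cohort generator that provides data with the statistical
structure the analysis assumes. Spatial preprocessing (slice timing,
realignment estimation, template normalisation, registration) is out of
scope: all volumes are assumed to live on one common grid, which the
generator guarantees by construction.

## Data model and conventions

Volumes are NIfTI-1 on an `ImageGrid` (dims, voxel sizes, a left-right
flag for the x axis). Voxel indices are 0-based; the left hemisphere is
x < nx/2 − 0.5. Mirror operations require an even nx so the midline falls
between columns and no voxel needs a hemisphere tie-break; odd-nx grids
are rejected. Orientation metadata beyond this flag is not interpreted.

## Preprocessing

The chain is fixed: drop initial volumes (default 4, for magnetisation
equilibrium) → nuisance regression → band-pass. Nuisance regressors are an
intercept, the Friston-24 motion expansion (6 parameters, their one-frame
lags — zero-filled at t = 0, a common convention — and both sets squared)
and mean white-matter and CSF signals. Regression is per-voxel OLS;
rank-deficient designs fall back to the pseudoinverse with a warning. The
band-pass (default 0.01–0.1 Hz) is an ideal rectangular filter in the
Fourier domain: deterministic, linear, and an idempotent projection, so
"filter twice = filter once" is testable exactly. Both regression and
filtering are applied inside the gray-matter mask only; outside voxels
pass through as zeros.

## FCS

Every gray-matter voxel is a network node; the Pearson correlation r_ij
between time series is the candidate edge. Only positive correlations
strictly above the threshold (default r = 0.2; r = 0.4 as a robustness
variant, a pure configuration change) contribute. The default edge weight
is Fisher's z = atanh(r) (with r clipped to ±(1 − 1e−7) so duplicated
series stay finite); `edge_transform="raw_r"` sums the correlations
themselves. Strengths D_i are computed in voxel blocks (default 512 rows)
that accumulate row sums of the thresholded correlation block without
materialising the N×N matrix; at real-mask scale (tens of thousands of
voxels) this is the difference between ~hundreds of MB and ~16 GB. A
brute-force full-matrix oracle is kept in the tests and must agree to
1e−12 on 300-voxel instances. Standardised maps use z_i = (D_i − mean)/SD
with the population (divisor-N) SD over the mask.

Because the threshold is applied to r and atanh is monotone, thresholding
r or z selects the same edge set; the strict inequality at the threshold
is an explicit convention (an edge at exactly r = 0.2 contributes
nothing).

## Lateralization index

The change mask is the union of significant clusters from the five
patient-vs-control contrasts, made symmetric by mirror superposition
(mask OR its x-flip). Within it, LI = (FCS_left − FCS_right) /
(FCS_left + FCS_right), computed by default on the **raw** FCS map:
raw strengths are nonnegative, which is what guarantees LI ∈ [−1, 1]
(+1 all-left, −1 all-right, 0 symmetric). Standardised maps contain
negatives and would break both the denominator's sign and the range, so
`li_source="standardized"` exists only as a sensitivity switch. A 0/0
index is propagated as NaN (undefined), never coerced to 0, and excluded
from group statistics with a logged count.

## Group inference

Voxelwise contrasts are pooled-variance two-sample t maps. TFCE integrates
extent^E × height^H over supra-threshold heights (defaults E = 0.5, H = 2,
26-connectivity, 100 integration steps — the method's recommended
defaults); the integral uses midpoint heights, which halves the
discretisation bias of an endpoint rule. Note the per-voxel integral ends
at the voxel's own height, so doubling the step count still moves small
voxel values by O(dh) (~2%); convergence holds at the 1% level relative to
the map scale, and the tests assert that form.

Family-wise error correction uses the permutation distribution of the
maximum TFCE statistic over the mask: group labels are permuted (the
observed labeling always counts in the null, so no corrected p can fall
below 1/n_permutations); when fewer distinct labelings exist than
permutations requested, the labelings are enumerated exhaustively.
Two-tailed contrasts run as two one-tailed TFCE passes (positive and
negative) each at alpha/2. The default of 5,000 permutations is the
full-scale setting; desk-scale runs and the calibration tests use
100–500.

Scalar tests are classical closed forms, implemented directly and checked
against hand fixtures to 1e−10: pooled two-sample t (from data or summary
statistics), paired t, the Pearson 2×2 chi-square without continuity
correction, one-way within-subject (repeated-measures) ANOVA
(F = MS_visits / MS_visit×subject, no sphericity correction), Bonferroni
post hocs (factor = number of pairs, 10 for five visits), and partial
correlation (residualise both variables on the covariates with intercept;
df = n − 2 − k; sex coded 0/1). A variable numerically fully explained by
its covariates yields partial r = 0 rather than noise.

## Lesion probability map

Each binary lesion mask is smoothed with a Gaussian kernel
(sigma = FWHM/(2√(2 ln 2)) per axis, in voxel units; default FWHM 3 mm)
and the smoothed masks are averaged voxelwise — smoothing before
averaging, in that order — giving each voxel the (smoothed) proportion of
patients lesioned there, clipped to [0, 1]. Registration steps are
replaced by the common-grid assumption.

## Synthetic cohort

The generator is a pure function of its configuration (including the
seed); identical configs regenerate bit-identical data. Defaults encode
the study design: 25 patients × 5 visits (labels d007…d180) plus 26
once-scanned controls, TR 3 s, 124 frames per run, 3 mm isotropic voxels.
The grid is 24×24×16 with a nested-ellipsoid head (CSF core, WM shell,
GM rind of ~2,600 voxels) instead of a real-scale 45k-voxel mask — every
code path is identical, at desk-scale runtime.

Signals: each voxel carries stationary unit-variance AR(1) noise
(coefficient 0.3 — BOLD noise is autocorrelated, and the band-pass needs
realistic input). Three "hub" communities (3×3×3 blocks, with mirrored
right-hemisphere twins) share per-community latent AR(1) signals with
loading a = 0.7, so same-community voxels correlate at a² = 0.49 in
expectation and become degree hubs. Nuisance terms layer on top:
per-voxel linear drift plus a slow scanner-period sine, a motion-coupled
artifact built from random-walk motion parameters (which are also emitted
as the motion table), a strong shared tissue signal inside WM and CSF,
and a small WM bleed into gray matter. Patients' left-hemisphere
communities get a per-visit loading offset of (−0.06, −0.14, −0.30,
−0.14, −0.06): the left community correlation runs 0.41 / 0.31 / 0.16 /
0.31 / 0.41 across visits, dipping **below** the r = 0.2 network threshold
exactly at the third visit, so left hub edges vanish there and the
group-mean LI has a strict planted minimum at d030. The magnitudes were
chosen so the recovered group LI values (≈ −0.01 to −0.08) are of the
order typical of patient LI trajectories in this literature while giving
comfortable power at n = 10/visit; no empirical effect sizes for
connectivity change exist to copy, so these are the package's own
choices. Lesions are random ellipsoids confined to a designated left
"basal-ganglia" block that is validated to be disjoint from every hub
community (lesion and hub effects stay separable) and can never cross the
midline. Motor scores are truncated normals with per-visit FMA/grip means and SDs
showing the steady improvement characteristic of recovering stroke
cohorts, a within-subject random effect (correlation 0.5 across visits),
FMA clipped to [0, 100].

What the generator does **not** emulate: hemodynamic response shapes,
cardiac/respiratory physiology, realistic anatomy, spatial autocorrelation
of noise, and lesion effects on the BOLD signal itself. Passing recovery
tests therefore show that the pipeline's inferential machinery is correct
and calibrated under its stated assumptions — not that the published
cohort results would reproduce on real data.

## Study orchestration

`StrokeConnectivityStudy` (model) + `StudyResults` (fitted results with
`summary()`) run the four steps end to end: per-run FCS maps; five
two-tailed contrasts of patients at each visit vs the single control
session; union + mirror mask + per-run LI; repeated-measures ANOVA and
Bonferroni post hocs on LI, per-visit LI-vs-control t tests, motor-score
ANOVA and baseline-vs-visit paired t tests, and partial correlations of
baseline-to-visit changes (ΔFCS, ΔLI vs ΔFMA, Δgrip) controlling age and
sex. ΔFCS is scalarised as the mean raw FCS within the union change mask
(the same mask LI uses) — the least arbitrary single number available; a
per-cluster alternative would be a config extension. Group contrasts use
the standardised (z) maps, matching how such maps are normally compared
across subjects; LI uses raw maps as above. Per-stage randomness is
isolated by SHA-256-derived child seeds of the master seed, so the
manifest (which records every parameter) fully determines the outputs;
refitting the same configuration reproduces the result tables
byte-for-byte.

Degenerate cohorts are handled explicitly: if no contrast yields any
significant voxel the change mask is empty, LI is reported as undefined
(not fabricated), and downstream LI statistics are skipped with warnings;
partial correlations are skipped when fewer complete patients remain than
covariates + 3.

## Problem sizes used in the tests

The test suite exercises the statistical guarantees at sizes chosen for a
desk machine: FCS oracle equivalence on 300-voxel instances; TFCE
permutation calibration on 100 null datasets of 200 voxels with 200
permutations each (the familywise false-positive count must fall in the
central 95% region of Binomial(100, 0.05)); and trajectory recovery on 20
replicate cohorts of 10 patients + 10 controls with 100 permutations and
50 TFCE steps per contrast, requiring the planted d030 minimum and a
significant LI ANOVA in ≥ 19/20 replicates.

## Known limitations

- No spatial preprocessing or registration; data must share a grid.
- No slice-timing, scrubbing, or global-signal regression (the analysed
  design does not use them).
- RM-ANOVA applies no sphericity correction; with k = 5 visits this is
  anticonservative under strong non-sphericity.
- Cluster tables report grid/mm coordinates but no anatomical labels.
- The generator's noise is temporally but not spatially correlated, which
  makes TFCE's spatial enhancement conservative relative to real data.
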