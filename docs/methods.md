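# Methods

## The analysis model

`seedpls` implements single-group behavioural/seed PLS for event-related
fMRI. The object being decomposed is a stacked matrix of condition-wise
Pearson correlations between a small variable block (seed activity, tract
FA, reaction time) and every (lag, voxel) column of the trial-window datamat.
The SVD of that matrix is the estimator; everything else is construction of
its inputs (datamat, variable block) and resampling inference on its outputs
(permutation p-values, bootstrap SEs, cluster-thresholded maps).

Assumptions worth making explicit:

- **Between-subject correlation structure.** All correlations are computed
  across subjects within a condition; subjects are the exchangeable unit for
  both the permutation test and the bootstrap.
- **Linear trial averaging.** Each subject x condition cell is the mean of
  its trial windows in percent signal change relative to the onset scan.
  The percent-signal-change reference makes the datamat invariant to global
  BOLD scaling, at the cost of an identically-zero lag-0 column (set to
  r = 0 silently) and of injecting the onset-scan noise into every lag.
- **No re-scaling before SVD.** Beyond correlation-building, voxel-lag
  columns are not standardised again.
- **Seed exclusion.** The seed region's voxels are removed from the brain
  block before correlation: the seed is related to *all other* regions, and
  keeping its own voxels would both inflate LV1 and bias the permutation
  null (the seed variable is a deterministic function of those columns).

## Pipeline stages and parameters

| parameter | default | units | notes |
|---|---|---|---|
| `lag_count` | 6 | TRs (3 s each) | 18-s window covering the hemodynamic response |
| seed extent | centre voxel + 26-neighbourhood | voxels | point coordinates are noise-dominated; radius configurable |
| `z_outlier` | 3.0 | sample z | subjects with any variable cell \|z\| > 3 removed listwise |
| `n_perm` | 500 | — | add-one estimator, p >= 1/(n_perm+1) |
| `n_boot` | 100 | — | >= 1000 recommended when percentile CIs are the quantity of interest |
| `bsr_threshold` | 3.0 | — | salience/SE, approximately p < .001 under normality |
| `min_cluster` | 100 | voxels per lag | cluster-extent filter; 27 used on the 12^3 demo grid |
| `connectivity` | 26 | — | 6 and 18 selectable |

Stage order: datamat extraction -> seed signal -> accurate-RT means ->
variable block assembly (inner join; listwise deletion for missing FA or
empty accurate-RT cells, all reported) -> outlier exclusion -> seed-voxel
drop -> stacked correlation matrix -> SVD -> permutation -> bootstrap ->
BSR thresholding -> per-LV report.

## Numerical choices

- **SVD sign convention.** Each LV's sign is pinned so its maximum-absolute
  task-salience entry is positive; resampling and reporting inherit this.
  Ties are broken by the first such entry.
- **Permutation scheme.** The variable rows are permuted against the brain
  rows independently within each condition; the null statistic is the
  per-index singular value without re-sorting. Fewer than 4 subjects is an
  error (too few distinct permutations); fewer than 20 permutations warns.
- **Bootstrap alignment.** Resampled decompositions are aligned to the
  original by an orthogonal Procrustes transform estimated on the
  singular-value-weighted task saliences and applied to both sides.
  Estimating the rotation from the voxel saliences themselves overfits the
  reference's voxel noise and biases voxel SEs downward; the singular-value
  weighting keeps near-null LVs (whose axes are arbitrary) from leaking
  into stable ones, and degenerates gracefully to per-LV sign alignment
  when the cross-product is rank deficient (e.g. exact rank-1 data).
- **Degenerate inputs.** Zero-variance variables are an error (named by
  condition and variable); zero-variance voxel columns correlate as r = 0
  (silently when identically zero — the structural lag-0 column — with a
  warning otherwise); an all-zero stacked matrix is an error; SE = 0 cells
  yield infinite bootstrap ratios that are flagged unstable and excluded
  from thresholding. Bootstrap draws that kill a variable's variance are
  redrawn; more than 20% redraws is an error.
- **Cluster peaks.** Components are labelled per lag and per salience pole;
  the peak is the max-|BSR| voxel of its cluster; peaks are sorted posterior
  to anterior (ascending MNI y) within sign, ties broken by |BSR|. The
  threshold is strict (`> 3.0`). Both poles are reported: the positive and
  negative ends of an LV are alternative patterns of correlated activity.
- **Tolerances.** SVD identities (reconstruction, orthonormality, energy
  conservation) hold to 1e-8 relative; affine round trips to 1e-9; the
  disk round trip of a simulated dataset reproduces the in-memory datamat
  to 1e-6 (volumes are stored as float32).

## The synthetic generator

The generator emulates a cued emotion-perception task: four expectancy
conditions (AC, AI, HC, HI), a 1-s cue, jittered ~1-s ISI, 3-s videos, TR
3 s, responses within 3 s. Defaults: a 12^3 grid with a spherical 672-voxel
mask, 40 subjects, 20 trials per condition, and a planted support of 120
voxels (two contiguous 60-voxel blobs, one per salience sign, ~18% of the
mask) — sized to emulate the widespread distributed networks this method
reports rather than a focal activation.

Generative model: subject-level latent `z_s ~ N(0,1)` and condition scores
`z_{s,c} = (z_s + e_{s,c})/sqrt(2)`. The trial-evoked response at active
voxel j, lag l is `A * z_{s,c} * m_j * h_l` with spatial map `m_j = ±1`,
canonical double-gamma HRF profile `h` (boxcar-convolved, peak-normalised,
exactly 0 at lag 0) and peak amplitude `A = 1` percent signal; white noise
sd 2 gives per-trial voxelwise SNR 0.5 at the peak lag. Seed amplitude,
condition-mean RT (1,500 ± 300 ms, conventional speeded-task values; trial
sd 100 ms, clipped to (200, 3000] ms) and FA (0.55 ± 0.10, clipped to
[0.02, 0.98]) are linear in the latents through the planted task-salience
pattern times the coupling strength, plus latent-scale noise (sd 0.5,
giving planted brain-score correlations in the 0.5–0.8 range). Accuracy is
Bernoulli(0.9) with at least one accurate trial forced per cell; inaccurate
trials carry no RT. FA couples through the subject-level latent only, so
its effective task salience is condition-invariant — a structural property
of a per-subject scalar. Coupling 0 is the null regime; `noise_sd = 0`
switches off every stochastic perturbation except the latents, which makes
the stacked correlation matrix exactly rank one (to float32 storage
precision) and is the basis of several exact tests.

What the generator does **not** emulate: physiological and scanner noise
spectra (noise is white), motion, multi-run drift, spatial smoothness of
noise (voxels are independent), hemodynamic variability across subjects or
regions, unequal trial counts across conditions, and soft-edged activation
(blobs have hard ±1 edges). Passing tests therefore certify the estimator
and its inference machinery, not robustness to realistic artefact
structure.

## Study sizes used by the test suite and acceptance script

Chosen to keep full studies at desk scale: permutation calibration on 200
null datasets (20 subjects, 100 permutations each); planted recovery and
detection on 50 datasets (40 subjects, 100 permutations, 100 bootstrap
iterations, cluster extent 27 on the 12^3 grid); CI coverage on 50 datasets
(20 subjects, 200 bootstrap iterations). The acceptance script runs scaled
versions (20/100/25 replicates) of the same studies.

## Known limitations

- **Voxel-level error near true clusters.** Cluster-extent inclusion admits
  above-threshold null voxels adjacent to genuine clusters. In the planted
  studies the suite runs, sensitivity is 1.0 but the voxelwise
  false-positive rate pooled over the six lag maps measures ~0.011 — all
  false positives sit within 1–2 voxels of the planted blobs. Per
  (lag, voxel) cell the rate is ~0.002–0.003. Cluster-extent thresholds
  control cluster-level, not voxel-level, error.
- **BSR is approximate.** The bootstrap SE of Procrustes-aligned saliences
  is anchored on the in-sample direction and under-covers at null cells
  (measured true-SD/bootstrap-SE ≈ 1.3 at n = 40), so the null BSR tail is
  heavier than the nominal normal tail; `BSR > 3 ≈ p < .001` is a
  convention, not a guarantee.
- **Percentile CIs at n_boot = 100** are coarse; use >= 1000 for CI-centred
  conclusions.
- **Single-group, correlation-based PLS only.** Mean-centred task PLS,
  non-rotated PLS and multi-group designs are out of scope, as are
  anatomical labelling of peaks and fMRI/diffusion preprocessing (the
  pipeline consumes preprocessed volumes and per-tract FA scalars).
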