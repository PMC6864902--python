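"""Synthetic event-related fMRI datasets with planted latent brain-behaviour structure.

The generator emulates a dynamic emotion-perception task: four expectancy
conditions (angry/happy videos preceded by congruent or incongruent emotion
cues: AC, AI, HC, HI), multiple trials per condition, a 3-s repetition time,
and per-subject structural (tract FA) and behavioural (reaction time)
measures. A single latent network is planted: each subject receives a latent
score per condition, the score drives both a spatially contiguous voxel
pattern (via a canonical hemodynamic response) and the seed/FA/RT variables,
so the full analysis pipeline has a known ground-truth acceptance surface.

Coupling strength 0 defines the null regime (no brain-variable association);
``noise_sd = 0`` defines the fully deterministic noise-free regime in which
the downstream stacked correlation matrix is exactly rank one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma

# -- task design constants -------------------------------------------------
CONDITIONS: tuple[str, ...] = ("AC", "AI", "HC", "HI")
DEFAULT_VARIABLES: tuple[str, ...] = ("seed", "fa", "rt")
TR_S = 3.0                  # repetition time, seconds
VIDEO_DURATION_S = 3.0      # emotion video length; responses fall inside it
CUE_DURATION_S = 1.0        # emotion cue preceding the video
DEFAULT_GRID = (12, 12, 12)
DEFAULT_LAGS = 6            # post-onset TRs retained per trial
TRIAL_SPACING_SCANS = 7     # scans between consecutive trial starts
LEAD_IN_SCANS = 2
BASELINE = 100.0            # raw BOLD baseline, so 1 signal unit ~ 1 % change

# behavioural/structural scales (the source study reports none; these are
# conventional values for a speeded two-choice emotion task)
RT_MEAN_MS = 1500.0
RT_SD_MS = 300.0
RT_TRIAL_SD_MS = 100.0
RT_MIN_MS, RT_MAX_MS = 200.0, 3000.0
ACCURACY_RATE = 0.9
FA_MEAN, FA_SD = 0.55, 0.10
LATENT_NOISE_SD = 0.5       # variable-level noise on the latent scale

# per-condition coupling template, condition order (AC, AI, HC, HI);
# mixed signs mimic congruency-dependent structure/behaviour correlations.
_SEED_PATTERN = np.array([0.9, 0.7, 0.8, 0.6])
_FA_PATTERN = np.array([0.5, 0.5, 0.5, 0.5])   # FA is subject-level, so its
                                               # effective coupling cannot
                                               # differ across conditions
_RT_PATTERN = np.array([-0.8, 0.6, -0.6, 0.5])
_FA_EXTRA_SCALES = (1.0, -0.7, 0.5)            # successive FA tracts


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s)."""
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, 6.0) - _gamma.pdf(t, 16.0) / 6.0
    return h


def lag_response_profile(n_lags: int = DEFAULT_LAGS, tr_s: float = TR_S,
                         duration_s: float = VIDEO_DURATION_S) -> np.ndarray:
    """Trial response sampled at post-onset TRs.

    Convolves a ``duration_s`` boxcar with the double-gamma HRF and samples at
    0, tr, 2*tr, ... The value at lag 0 is exactly zero (the HRF is causal and
    delayed), which makes percent-signal-change referencing at the onset scan
    exactly linear in the planted amplitudes.
    """
    dt = 0.05
    t = np.arange(0.0, n_lags * tr_s + duration_s + dt, dt)
    box = (t < duration_s).astype(float)
    resp = np.convolve(double_gamma_hrf(t), box)[: t.size] * dt
    lags = np.round(np.arange(n_lags) * tr_s / dt).astype(int)
    prof = resp[lags]
    prof[0] = 0.0
    peak = prof.max()
    if peak <= 0:
        raise ValueError("degenerate hemodynamic profile")
    return prof / peak


@dataclasses.dataclass
class GroundTruth:
    """Planted latent network: what the pipeline should recover."""

    grid_shape: tuple[int, int, int]
    mask: np.ndarray                   # 3D bool
    n_lags: int
    conditions: tuple[str, ...]
    variables: tuple[str, ...]
    voxel_salience_true: np.ndarray    # (n_lags * n_mask_voxels,), unit norm
    spatial_map: np.ndarray            # (n_mask_voxels,), +-1 on the blobs
    active_voxel_set: np.ndarray       # flat indices into mask voxel order
    variable_salience_true: np.ndarray  # (n_conditions, n_variables)
    coupling_strength: float
    noise_sd: float
    signal_amplitude: float
    lag_profile: np.ndarray
    seed_center_ijk: tuple[int, int, int]
    affine: np.ndarray
    seed_rng: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_null(self) -> bool:
        """Coupling 0 is the null regime: no brain-variable association."""
        return self.coupling_strength == 0

    @property
    def seed_center_mni(self) -> tuple[float, float, float]:
        ijk = np.array([*self.seed_center_ijk, 1.0])
        return tuple((self.affine @ ijk)[:3])

    def to_json_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "n_lags": self.n_lags,
            "conditions": list(self.conditions),
            "variables": list(self.variables),
            "coupling_strength": self.coupling_strength,
            "noise_sd": self.noise_sd,
            "signal_amplitude": self.signal_amplitude,
            "seed_center_ijk": list(self.seed_center_ijk),
            "seed_rng": self.seed_rng,
            "active_voxel_set": [int(i) for i in self.active_voxel_set],
            "spatial_map": [float(v) for v in self.spatial_map],
            "variable_salience_true": [list(map(float, r))
                                       for r in self.variable_salience_true],
            "lag_profile": [float(v) for v in self.lag_profile],
            "voxel_salience_true": [float(v) for v in self.voxel_salience_true],
            "affine": [list(map(float, r)) for r in self.affine],
        }


def _default_affine(grid_shape: Sequence[int], voxel_mm: float = 2.5) -> np.ndarray:
    """Scaled affine centring the grid on the origin (MNI-like mm axes)."""
    aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    centre = (np.asarray(grid_shape) - 1) / 2.0
    aff[:3, 3] = -voxel_mm * centre
    return aff


def _brain_mask(grid_shape: Sequence[int]) -> np.ndarray:
    """Spherical mask inscribed in the grid (a crude 'brain')."""
    centre = (np.asarray(grid_shape) - 1) / 2.0
    radius = min(grid_shape) / 2.0 - 0.5
    ii, jj, kk = np.indices(grid_shape)
    dist2 = ((ii - centre[0]) ** 2 + (jj - centre[1]) ** 2
             + (kk - centre[2]) ** 2)
    return dist2 <= radius ** 2


def _grow_blob(mask: np.ndarray, centre: np.ndarray, n: int) -> np.ndarray:
    """Flat mask-order indices of the n in-mask voxels nearest to centre.

    For a convex mask region this yields a single 26-connected blob.
    """
    coords = np.argwhere(mask)
    d2 = ((coords - centre) ** 2).sum(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    return np.sort(order[:n])


def _region_centres(grid_shape: Sequence[int], rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centre = (np.asarray(grid_shape) - 1) / 2.0
    half = min(grid_shape) / 2.0
    pos = centre + half * np.array([-0.45, -0.27, -0.27])
    neg = centre + half * np.array([0.45, 0.27, 0.27])
    seed = centre + half * np.array([0.09, -0.45, 0.45])
    jitter = rng.integers(-1, 2, size=(3, 3)).astype(float)
    return pos + jitter[0], neg + jitter[1], seed + jitter[2]


def _variable_pattern(name: str, n_conditions: int, fa_rank: int) -> np.ndarray:
    if name == "seed":
        base = _SEED_PATTERN
    elif name == "rt":
        base = _RT_PATTERN
    elif name.startswith("fa"):
        scale = _FA_EXTRA_SCALES[fa_rank % len(_FA_EXTRA_SCALES)]
        base = _FA_PATTERN * scale
    else:
        raise ValueError(
            f"unknown variable {name!r}: expected 'seed', 'rt' or 'fa*'")
    return np.resize(base, n_conditions).astype(float)


def make_ground_truth(grid_shape: Sequence[int] = DEFAULT_GRID,
                      n_active_voxels: int = 120,
                      n_lags: int = DEFAULT_LAGS,
                      conditions: Sequence[str] = CONDITIONS,
                      variables: Sequence[str] = DEFAULT_VARIABLES,
                      coupling_strength: float = 0.8,
                      seed: int = 0,
                      noise_sd: float = 2.0,
                      signal_amplitude: float = 1.0) -> GroundTruth:
    """Plant a latent network on a spherical brain mask.

    The spatial support is two contiguous blobs, one per salience sign, so
    cluster-extent thresholding can detect it. The full (lag, voxel) salience
    is the outer product of the hemodynamic lag profile with the +-1 spatial
    map, normalised to unit Euclidean norm. With the defaults
    (``signal_amplitude=1``, ``noise_sd=2``) the per-trial voxelwise SNR is
    0.5 at the peak lag.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if coupling_strength < 0:
        raise ValueError("coupling_strength must be >= 0")
    mask = _brain_mask(grid_shape)
    n_vox = int(mask.sum())
    if not 1 <= n_active_voxels <= n_vox:
        raise ValueError(
            f"n_active_voxels={n_active_voxels} exceeds the "
            f"{n_vox} in-mask voxels of grid {grid_shape}")
    rng = np.random.default_rng(seed)
    pos_c, neg_c, seed_c = _region_centres(grid_shape, rng)

    n_pos = (n_active_voxels + 1) // 2
    n_neg = n_active_voxels - n_pos
    pos_idx = _grow_blob(mask, pos_c, n_pos)
    neg_idx = _grow_blob(mask, neg_c, n_neg) if n_neg else np.empty(0, int)
    seed_ijk = tuple(int(round(c)) for c in seed_c)
    seed_region = _seed_cube_indices(mask, seed_ijk, radius=1)
    regions = [set(pos_idx), set(neg_idx), set(seed_region)]
    if (regions[0] & regions[1]) or (regions[0] & regions[2]) \
            or (regions[1] & regions[2]):
        # jittered placement collided; fall back to the deterministic layout
        pos_c, neg_c, seed_c = _region_centres(grid_shape, _NoJitter())
        pos_idx = _grow_blob(mask, pos_c, n_pos)
        neg_idx = _grow_blob(mask, neg_c, n_neg) if n_neg else np.empty(0, int)
        seed_ijk = tuple(int(round(c)) for c in seed_c)
        seed_region = _seed_cube_indices(mask, seed_ijk, radius=1)
        if (set(pos_idx) | set(neg_idx)) & set(seed_region):
            raise ValueError("planted blobs overlap the seed region; "
                             "reduce n_active_voxels or enlarge the grid")

    spatial = np.zeros(n_vox)
    spatial[pos_idx] = 1.0
    spatial[neg_idx] = -1.0
    profile = lag_response_profile(n_lags)
    salience = np.outer(profile, spatial).ravel()
    norm = np.linalg.norm(salience)
    salience = salience / norm

    n_cond, n_var = len(conditions), len(variables)
    w = np.zeros((n_cond, n_var))
    fa_rank = 0
    for j, name in enumerate(variables):
        w[:, j] = _variable_pattern(name, n_cond, fa_rank)
        if name.startswith("fa"):
            fa_rank += 1
    w = w / np.abs(w).max()

    active = np.sort(np.concatenate([pos_idx, neg_idx]).astype(int))
    return GroundTruth(
        grid_shape=grid_shape, mask=mask, n_lags=n_lags,
        conditions=tuple(conditions), variables=tuple(variables),
        voxel_salience_true=salience, spatial_map=spatial,
        active_voxel_set=active, variable_salience_true=w,
        coupling_strength=float(coupling_strength), noise_sd=float(noise_sd),
        signal_amplitude=float(signal_amplitude), lag_profile=profile,
        seed_center_ijk=seed_ijk, affine=_default_affine(grid_shape),
        seed_rng=int(seed))


class _NoJitter:
    """Deterministic zero-jitter stand-in for a Generator (fallback layout)."""

    def integers(self, low, high, size):
        return np.zeros(size, dtype=int)


def _seed_cube_indices(mask: np.ndarray, centre_ijk: Sequence[int],
                       radius: int = 1) -> np.ndarray:
    """Flat mask-order indices of the (2r+1)^3 cube around centre, in-mask."""
    flat_of_grid = -np.ones(mask.shape, dtype=int)
    flat_of_grid[mask] = np.arange(int(mask.sum()))
    out = []
    ci, cj, ck = centre_ijk
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            for dk in range(-radius, radius + 1):
                i, j, k = ci + di, cj + dj, ck + dk
                if all(0 <= v < s for v, s in zip((i, j, k), mask.shape)) \
                        and mask[i, j, k]:
                    out.append(flat_of_grid[i, j, k])
    return np.sort(np.array(out, dtype=int))


@dataclasses.dataclass
class SimulatedDataset:
    """Multi-subject simulated study with saved generative latents."""

    truth: GroundTruth
    subjects: list[str]
    bold: dict[str, np.ndarray]        # subject -> (x, y, z, t) float32
    events: dict[str, pd.DataFrame]    # onset/duration/condition/accuracy/rt
    fa: pd.DataFrame                   # long: subject_id, tract, fa
    mask: np.ndarray
    affine: np.ndarray
    tr_s: float
    latent_scores: np.ndarray          # (n_subjects, n_conditions)
    subject_latent: np.ndarray         # (n_subjects,)
    seed_amplitude: np.ndarray         # (n_subjects, n_conditions)
    rng_seed: int

    @property
    def n_scans(self) -> int:
        return next(iter(self.bold.values())).shape[-1]


def simulate_dataset(truth: GroundTruth,
                     n_subjects: int = 40,
                     n_trials_per_condition: int = 20,
                     seed: int = 0,
                     accuracy_rate: float = ACCURACY_RATE) -> SimulatedDataset:
    """Simulate a full study from a planted ground truth.

    Per subject s and condition c a latent score z[s, c] (correlated across
    conditions through a subject-level component) multiplies the planted voxel
    salience to give the trial-evoked BOLD amplitude, and enters the seed
    amplitude and condition-mean RT through ``variable_salience_true``; FA is
    a per-subject scalar driven by the subject-level latent. ``noise_sd = 0``
    turns off every stochastic perturbation except the latents themselves.
    """
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    if n_trials_per_condition < 1:
        raise ValueError("n_trials_per_condition must be >= 1")
    if truth.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    conditions = truth.conditions
    n_cond = len(conditions)
    n_trials_total = n_cond * n_trials_per_condition
    n_scans = LEAD_IN_SCANS + n_trials_total * TRIAL_SPACING_SCANS + truth.n_lags
    n_vox = truth.n_voxels
    mask = truth.mask
    noise_free = truth.noise_sd == 0
    eta_sd = 0.0 if noise_free else LATENT_NOISE_SD
    trial_rt_sd = 0.0 if noise_free else RT_TRIAL_SD_MS
    acc_rate = 1.0 if noise_free else accuracy_rate

    cpl = truth.coupling_strength
    w = truth.variable_salience_true  # (C, V)
    var_idx = {name: j for j, name in enumerate(truth.variables)}
    if "seed" not in var_idx:
        raise ValueError("truth.variables must contain 'seed'")

    z_subj = rng.standard_normal(n_subjects)
    z = (z_subj[:, None] + rng.standard_normal((n_subjects, n_cond))) / np.sqrt(2)

    seed_amp = (cpl * w[None, :, var_idx["seed"]] * z
                + eta_sd * rng.standard_normal((n_subjects, n_cond)))

    rt_cond_mean = None
    if "rt" in var_idx:
        rt_cond_mean = RT_MEAN_MS + RT_SD_MS * (
            cpl * w[None, :, var_idx["rt"]] * z
            + eta_sd * rng.standard_normal((n_subjects, n_cond)))

    fa_rows = []
    fa_tracts = [v for v in truth.variables if v.startswith("fa")]
    fa_values: dict[str, np.ndarray] = {}
    for tract in fa_tracts:
        w_eff = w[:, var_idx[tract]].mean()
        vals = FA_MEAN + FA_SD * (cpl * w_eff * z_subj
                                  + eta_sd * rng.standard_normal(n_subjects))
        fa_values[tract] = np.clip(vals, 0.02, 0.98)

    seed_region = _seed_cube_indices(mask, truth.seed_center_ijk, radius=1)
    profile = truth.lag_profile
    amp_map = truth.signal_amplitude * truth.spatial_map  # (V,)

    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    bold: dict[str, np.ndarray] = {}
    events: dict[str, pd.DataFrame] = {}
    for s, sub in enumerate(subjects):
        cond_seq = rng.permutation(np.repeat(np.arange(n_cond),
                                             n_trials_per_condition))
        start_scan = LEAD_IN_SCANS + np.arange(n_trials_total) * TRIAL_SPACING_SCANS
        isi = rng.uniform(0.5, 1.5, n_trials_total)
        onset = start_scan * TR_S + CUE_DURATION_S + isi
        if np.any(np.floor(onset / TR_S).astype(int) + truth.n_lags > n_scans):
            raise ValueError("trial window overruns the scan")

        acc = rng.random(n_trials_total) < acc_rate
        for c in range(n_cond):  # guarantee >= 1 accurate trial per condition
            sel = np.flatnonzero(cond_seq == c)
            if not acc[sel].any():
                acc[sel[0]] = True
        rt = np.full(n_trials_total, np.nan)
        if rt_cond_mean is not None:
            means = rt_cond_mean[s, cond_seq]
            rt_all = means + trial_rt_sd * rng.standard_normal(n_trials_total)
            rt = np.where(acc, np.clip(rt_all, RT_MIN_MS, RT_MAX_MS), np.nan)

        flat = np.zeros((n_vox, n_scans))
        for t in range(n_trials_total):
            c = cond_seq[t]
            s0 = start_scan[t]
            flat[:, s0:s0 + truth.n_lags] += np.outer(z[s, c] * amp_map, profile)
            flat[seed_region, s0:s0 + truth.n_lags] += np.outer(
                truth.signal_amplitude * seed_amp[s, c]
                * np.ones(seed_region.size), profile)
        flat += BASELINE
        if not noise_free:
            flat += truth.noise_sd * rng.standard_normal((n_vox, n_scans))
        vol = np.zeros((*truth.grid_shape, n_scans), dtype=np.float32)
        vol[mask] = flat.astype(np.float32)
        bold[sub] = vol

        events[sub] = pd.DataFrame({
            "onset": onset,
            "duration": VIDEO_DURATION_S,
            "condition": [conditions[c] for c in cond_seq],
            "accuracy": acc.astype(int),
            "rt": rt,
        })

    for sub_i, sub in enumerate(subjects):
        for tract in fa_tracts:
            fa_rows.append({"subject_id": sub, "tract": tract,
                            "fa": float(fa_values[tract][sub_i])})
    fa_df = pd.DataFrame(fa_rows, columns=["subject_id", "tract", "fa"])

    return SimulatedDataset(
        truth=truth, subjects=subjects, bold=bold, events=events, fa=fa_df,
        mask=mask, affine=truth.affine, tr_s=TR_S, latent_scores=z,
        subject_latent=z_subj, seed_amplitude=seed_amp, rng_seed=int(seed))


def evaluate_recovery(voxel_salience_est: np.ndarray, truth: GroundTruth,
                      detected_voxels: Sequence[int] | None = None) -> dict:
    """Compare an estimated voxel salience with the planted one.

    Returns the absolute cosine similarity (sign-invariant: an LV and its
    reflection are the same pattern) and, when a thresholded spatial voxel set
    is supplied, the sensitivity and specificity against the planted support.
    """
    est = np.asarray(voxel_salience_est, dtype=float).ravel()
    true = truth.voxel_salience_true
    if est.size != true.size:
        raise ValueError(
            f"salience length mismatch: estimated {est.size}, true {true.size}")
    denom = np.linalg.norm(est) * np.linalg.norm(true)
    cosine = float(abs(est @ true) / denom) if denom > 0 else 0.0
    report = {"cosine": cosine}
    if detected_voxels is not None:
        detected = set(int(i) for i in detected_voxels)
        support = set(int(i) for i in truth.active_voxel_set)
        n_vox = truth.n_voxels
        tp = len(detected & support)
        fp = len(detected - support)
        fn = len(support - detected)
        tn = n_vox - tp - fp - fn
        report["sensitivity"] = tp / max(len(support), 1)
        report["specificity"] = tn / max(tn + fp, 1)
        report["false_positive_rate"] = fp / max(n_vox - len(support), 1)
    return report


# -- on-disk round trip ----------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict:
    """Write NIfTI volumes, TSV events, CSV FA, truth JSON and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def _save_nifti(arr, name):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64),
                              dataset.affine)
        img.header.set_zooms((*np.abs(np.diag(dataset.affine)[:3]),)
                             + ((dataset.tr_s,) if arr.ndim == 4 else ()))
        path = outdir / name
        nib.save(img, path)
        files[name] = _sha256(path)

    _save_nifti(dataset.mask.astype(np.float64), "mask.nii")
    for sub in dataset.subjects:
        _save_nifti(dataset.bold[sub], f"{sub}_bold.nii")
        ev = dataset.events[sub]
        path = outdir / f"{sub}_events.tsv"
        ev.to_csv(path, sep="\t", index=False, float_format="%.6f")
        files[path.name] = _sha256(path)
    fa_path = outdir / "fa.csv"
    dataset.fa.to_csv(fa_path, index=False, float_format="%.8f")
    files["fa.csv"] = _sha256(fa_path)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(dataset.truth.to_json_dict(),
                                     sort_keys=True, indent=1))
    files["truth.json"] = _sha256(truth_path)

    manifest = {
        "subjects": dataset.subjects,
        "conditions": list(dataset.truth.conditions),
        "variables": list(dataset.truth.variables),
        "tr_s": dataset.tr_s,
        "n_scans": dataset.n_scans,
        "rng_seed": dataset.rng_seed,
        "truth_seed": dataset.truth.seed_rng,
        "files": files,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def read_truth(path: str | Path) -> GroundTruth:
    """Rebuild a GroundTruth from its JSON sidecar."""
    d = json.loads(Path(path).read_text())
    grid = tuple(d["grid_shape"])
    mask = _brain_mask(grid)
    return GroundTruth(
        grid_shape=grid, mask=mask, n_lags=d["n_lags"],
        conditions=tuple(d["conditions"]), variables=tuple(d["variables"]),
        voxel_salience_true=np.array(d["voxel_salience_true"]),
        spatial_map=np.array(d["spatial_map"]),
        active_voxel_set=np.array(d["active_voxel_set"], dtype=int),
        variable_salience_true=np.array(d["variable_salience_true"]),
        coupling_strength=d["coupling_strength"], noise_sd=d["noise_sd"],
        signal_amplitude=d["signal_amplitude"],
        lag_profile=np.array(d["lag_profile"]),
        seed_center_ijk=tuple(d["seed_center_ijk"]),
        affine=np.array(d["affine"]), seed_rng=d["seed_rng"])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
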