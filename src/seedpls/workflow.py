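"""End-to-end reproducible runs: simulate -> analyse -> report.

A single declarative YAML configuration drives the whole pipeline. Every
output directory carries a manifest with the config hash and the seed triple
(simulation, permutation, bootstrap), so deleting the outputs and re-running
reproduces them byte-for-byte.

The analysis stage order: datamat extraction -> seed signal -> accurate-RT
means -> variable block assembly -> outlier exclusion (|z| > 3) -> seed
voxels dropped from the brain block -> stacked correlation matrix -> SVD ->
permutation test -> bootstrap -> BSR thresholding -> per-LV report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import datamat as dm
from . import inference as inf
from . import pls
from . import reporting as rep
from . import synthetic as syn

log = logging.getLogger("seedpls")


class ConfigError(ValueError):
    """Invalid configuration (validation failure, exit code 1 in the CLI)."""


@dataclasses.dataclass
class AnalysisConfig:
    """Declarative description of one simulate + analyse run."""

    # paths
    data_dir: str = "data"
    out_dir: str = "results"
    # simulation
    grid_shape: tuple[int, int, int] = syn.DEFAULT_GRID
    n_active_voxels: int = 120
    n_subjects: int = 40
    n_trials_per_condition: int = 20
    coupling_strength: float = 0.8
    noise_sd: float = 2.0
    conditions: tuple[str, ...] = syn.CONDITIONS
    variables: tuple[str, ...] = syn.DEFAULT_VARIABLES
    # seeds
    seed_simulate: int = 1
    seed_permutation: int = 2
    seed_bootstrap: int = 3
    truth_seed: int = 0
    # analysis
    lag_count: int = 6
    seed_mni: tuple[float, float, float] | None = None  # None: from truth
    seed_radius: int = 1
    exclude_seed_voxels: bool = True
    z_outlier: float = 3.0
    n_perm: int = 500
    n_boot: int = 100
    bsr_threshold: float = 3.0
    min_cluster: int = 100
    connectivity: int = 26
    n_report_lvs: int = 2

    def validate(self) -> None:
        if len(self.conditions) < 2 or len(set(self.conditions)) != len(
                self.conditions):
            raise ConfigError("conditions must be >= 2 distinct labels")
        if "seed" not in self.variables:
            raise ConfigError("variables must include 'seed'")
        for name, lo in (("n_subjects", 3), ("n_trials_per_condition", 1),
                         ("lag_count", 1), ("n_perm", 1), ("n_boot", 2),
                         ("min_cluster", 1), ("n_report_lvs", 1)):
            if getattr(self, name) < lo:
                raise ConfigError(f"{name} must be >= {lo}")
        if self.noise_sd < 0 or self.coupling_strength < 0:
            raise ConfigError("noise_sd and coupling_strength must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.bsr_threshold <= 0 or self.z_outlier <= 0:
            raise ConfigError("bsr_threshold and z_outlier must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("grid_shape", "conditions", "variables", "seed_mni"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "conditions", "variables", "seed_mni"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclasses.dataclass
class AnalysisResult:
    """In-memory result bundle of one full analysis."""

    lvs: list[pls.LatentVariable]
    permutation: inf.PermutationResult
    bootstrap: inf.BootstrapResult
    correlations: dict[int, pd.DataFrame]     # lv index -> point estimates
    peaks: list[rep.ClusterPeak]
    reports: list[dict]
    excluded_outliers: list[dict]
    dropped_subjects: list[dict]
    subjects: list[str]
    datamat: dm.TrialWindowMatrix
    block: dm.VariableBlock
    manifest: dict


def prepare_from_dataset(dataset: syn.SimulatedDataset,
                         lag_count: int = 6, seed_radius: int = 1,
                         z_outlier: float = 3.0,
                         exclude_seed_voxels: bool = True
                         ) -> tuple[dm.TrialWindowMatrix, dm.VariableBlock,
                                    dict]:
    """Datamat + variable block straight from a simulated dataset."""
    windows = dm.datamat_from_dataset(dataset, lag_count)
    seed_mean, seed_voxels = dm.extract_seed_signal(
        windows, seed_ijk=dataset.truth.seed_center_ijk, radius=seed_radius)
    rt, rt_flags = dm.compute_condition_rt(dataset.events,
                                           dataset.truth.conditions)
    fa_wide = dm.fa_long_to_wide(dataset.fa)
    block = dm.assemble_variable_block(seed_mean, fa_wide, rt,
                                       dataset.truth.variables)
    block, removed = dm.exclude_outliers(block, z_outlier)
    windows = windows.select_subjects(block.subjects)
    if exclude_seed_voxels:
        windows = windows.drop_voxels(seed_voxels)
    info = {"seed_voxels": seed_voxels, "rt_flags": rt_flags,
            "outliers": removed, "dropped": block.dropped_subjects}
    return windows, block, info


def analyze(windows: dm.TrialWindowMatrix, block: dm.VariableBlock,
            n_perm: int = 500, n_boot: int = 100,
            seed_permutation: int | None = None,
            seed_bootstrap: int | None = None,
            bsr_threshold: float = 3.0, min_cluster: int = 100,
            connectivity: int = 26, n_report_lvs: int = 2,
            manifest: dict | None = None,
            excluded_outliers: Sequence[dict] = (),
            dropped_subjects: Sequence[dict] = ()) -> AnalysisResult:
    """Run the full PLS analysis on a prepared datamat + variable block."""
    manifest = dict(manifest or {})
    manifest.setdefault("hash", "unhashed")
    log.info("analysis: %d subjects, %d conditions, %d variables, "
             "%d voxel columns", len(block.subjects), len(block.conditions),
             len(block.variable_order), windows.n_columns)
    scm = pls.build_stacked_correlation_matrix(windows, block)
    lvs = pls.svd_decompose(scm)
    for lv in lvs:
        lv.brain_scores = pls.compute_brain_scores(windows, lv)
    log.info("SVD: %d LVs, LV1 %.2f%% covariance", len(lvs),
             lvs[0].pct_covariance)
    perm = inf.permutation_test(windows, block, n_perm, seed_permutation)
    n_sig = int((perm.p_values < 0.05).sum())
    log.info("permutation: %d LVs with p < .05 (n_perm=%d)", n_sig, n_perm)
    n_report = min(n_report_lvs, len(lvs))
    boot = inf.bootstrap_saliences(windows, block, n_boot, seed_bootstrap,
                                   n_ci_lvs=n_report)
    peaks: list[rep.ClusterPeak] = []
    correlations: dict[int, pd.DataFrame] = {}
    reports = []
    n_vox = windows.values.shape[-1]
    for lv in lvs[:n_report]:
        k = lv.index - 1
        bsr_lag = boot.bsr[k].reshape(windows.lag_count, n_vox)
        unst = boot.unstable[k].reshape(windows.lag_count, n_vox)
        lv_peaks = rep.threshold_bsr(
            bsr_lag, windows.mask, windows.voxel_ids, windows.affine,
            bsr_threshold, min_cluster, connectivity, unstable=unst,
            lv=lv.index)
        peaks.extend(lv_peaks)
        corr = pls.correlate_brain_scores(lv.brain_scores, block)
        correlations[lv.index] = corr
        reports.append(rep.lv_report(lv, perm, boot, lv_peaks, corr,
                                     manifest))
    return AnalysisResult(
        lvs=lvs, permutation=perm, bootstrap=boot, correlations=correlations,
        peaks=peaks, reports=reports,
        excluded_outliers=list(excluded_outliers),
        dropped_subjects=list(dropped_subjects),
        subjects=list(block.subjects), datamat=windows, block=block,
        manifest=manifest)


# -- disk-facing runs ------------------------------------------------------

def _check_outdir(outdir: Path, force: bool) -> None:
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ConfigError(
            f"output directory {outdir} is not empty (use force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)


def run_simulate(config: AnalysisConfig, force: bool = False) -> dict:
    """Generate a dataset to ``config.data_dir`` and write its manifest."""
    config.validate()
    outdir = Path(config.data_dir)
    _check_outdir(outdir, force)
    truth = syn.make_ground_truth(
        grid_shape=config.grid_shape, n_active_voxels=config.n_active_voxels,
        n_lags=config.lag_count, conditions=config.conditions,
        variables=config.variables,
        coupling_strength=config.coupling_strength, seed=config.truth_seed,
        noise_sd=config.noise_sd)
    dataset = syn.simulate_dataset(truth, config.n_subjects,
                                   config.n_trials_per_condition,
                                   seed=config.seed_simulate)
    manifest = syn.write_dataset(dataset, outdir)
    manifest["config_hash"] = config.hash
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    log.info("simulate: wrote %d subjects to %s", config.n_subjects, outdir)
    return manifest


def load_dataset_dir(data_dir: str | Path
                     ) -> tuple[dict, dict, pd.DataFrame, np.ndarray,
                                np.ndarray, syn.GroundTruth | None]:
    """Read a written dataset back: bold, events, FA, mask, affine, truth."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json in {data_dir}")
    manifest = json.loads(manifest_path.read_text())
    mask, affine = dm.load_mask(data_dir / "mask.nii")
    tr = manifest.get("tr_s", syn.TR_S)
    bold = {sub: dm.load_volume(data_dir / f"{sub}_bold.nii", tr_s=tr)
            for sub in manifest["subjects"]}
    events = {sub: dm.load_events(data_dir / f"{sub}_events.tsv")
              for sub in manifest["subjects"]}
    fa = pd.read_csv(data_dir / "fa.csv")
    truth_path = data_dir / "truth.json"
    truth = syn.read_truth(truth_path) if truth_path.exists() else None
    return bold, events, fa, mask, affine, truth


def run_analysis(config: AnalysisConfig, force: bool = False) -> dict:
    """Full analysis of a dataset directory; writes results to out_dir."""
    config.validate()
    outdir = Path(config.out_dir)
    _check_outdir(outdir, force)
    bold, events, fa, mask, affine, truth = load_dataset_dir(config.data_dir)
    conditions = config.conditions
    windows = dm.extract_trial_windows(bold, events, mask, affine,
                                       config.lag_count, conditions)
    if config.seed_mni is not None:
        seed_mean, seed_voxels = dm.extract_seed_signal(
            windows, seed_mni=config.seed_mni, radius=config.seed_radius)
    elif truth is not None:
        seed_mean, seed_voxels = dm.extract_seed_signal(
            windows, seed_ijk=truth.seed_center_ijk,
            radius=config.seed_radius)
    else:
        raise ConfigError("seed_mni not set and no truth sidecar to "
                          "take the seed location from")
    rt, rt_flags = dm.compute_condition_rt(events, conditions)
    block = dm.assemble_variable_block(seed_mean, dm.fa_long_to_wide(fa),
                                       rt, config.variables)
    block, removed = dm.exclude_outliers(block, config.z_outlier)
    windows = windows.select_subjects(block.subjects)
    if config.exclude_seed_voxels:
        windows = windows.drop_voxels(seed_voxels)
    manifest = {
        "hash": config.hash,
        "config": config.to_dict(),
        "subjects_analysed": block.subjects,
        "outliers_removed": removed,
        "subjects_dropped": block.dropped_subjects,
        "rt_flags": rt_flags,
        "n_voxel_columns": windows.n_columns,
    }
    result = analyze(windows, block, config.n_perm, config.n_boot,
                     config.seed_permutation, config.seed_bootstrap,
                     config.bsr_threshold, config.min_cluster,
                     config.connectivity, config.n_report_lvs,
                     manifest=manifest, excluded_outliers=removed,
                     dropped_subjects=block.dropped_subjects)
    if truth is not None and windows.lag_count == truth.n_lags:
        est = _embed_salience(result.lvs[0].voxel_salience, windows, truth)
        detected = rep.detected_voxels(
            result.bootstrap.bsr[0].reshape(windows.lag_count, -1),
            windows.mask, windows.voxel_ids, config.bsr_threshold,
            config.min_cluster, config.connectivity,
            unstable=result.bootstrap.unstable[0].reshape(
                windows.lag_count, -1))
        manifest["recovery"] = syn.evaluate_recovery(est, truth, detected)
    _write_results(result, outdir)
    log.info("analysis complete: results in %s", outdir)
    return manifest


def _embed_salience(salience: np.ndarray, windows: dm.TrialWindowMatrix,
                    truth: syn.GroundTruth) -> np.ndarray:
    """Re-embed a (lag x kept-voxel) salience into the full mask order so it
    is commensurable with the planted truth (dropped columns read 0)."""
    n_vox = windows.values.shape[-1]
    per_lag = salience.reshape(windows.lag_count, n_vox)
    full = np.zeros((windows.lag_count, truth.n_voxels))
    full[:, windows.voxel_ids] = per_lag
    return full.ravel()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_results(result: AnalysisResult, outdir: Path) -> None:
    doc = {
        "manifest": result.manifest,
        "singular_values": [lv.singular_value for lv in result.lvs],
        "pct_covariance": [lv.pct_covariance for lv in result.lvs],
        "p_values": result.permutation.p_values.tolist(),
        "n_perm": result.permutation.n_perm,
        "n_boot": result.bootstrap.n_boot,
        "lv_reports": result.reports,
    }
    (outdir / "results.json").write_text(
        json.dumps(doc, sort_keys=True, indent=1, default=_json_default))
    rep.peaks_to_frame(result.peaks).to_csv(outdir / "peaks.csv", index=False)
    windows = result.datamat
    n_vox = windows.values.shape[-1]
    for lv in result.lvs[:len(result.reports)]:
        k = lv.index - 1
        sal = _embed_4d(lv.voxel_salience, windows)
        bsr = _embed_4d(np.where(result.bootstrap.unstable[k], 0.0,
                                 result.bootstrap.bsr[k]), windows)
        nib.save(nib.Nifti1Image(sal, windows.affine),
                 outdir / f"lv{lv.index}_salience.nii")
        nib.save(nib.Nifti1Image(bsr, windows.affine),
                 outdir / f"lv{lv.index}_bsr.nii")
    scores = {f"lv{lv.index}": lv.brain_scores.tolist()
              for lv in result.lvs[:len(result.reports)]
              if lv.brain_scores is not None}
    (outdir / "brain_scores.json").write_text(
        json.dumps({"subjects": result.subjects,
                    "conditions": result.block.conditions,
                    "scores": scores}, sort_keys=True, indent=1))


def _embed_4d(salience: np.ndarray, windows: dm.TrialWindowMatrix
              ) -> np.ndarray:
    n_vox = windows.values.shape[-1]
    per_lag = np.asarray(salience, dtype=float).reshape(windows.lag_count,
                                                        n_vox)
    out = np.zeros((*windows.mask.shape, windows.lag_count))
    flat_full = np.zeros(int(windows.mask.sum()))
    for lag in range(windows.lag_count):
        flat_full[:] = 0.0
        flat_full[windows.voxel_ids] = per_lag[lag]
        out[windows.mask, lag] = flat_full
    return out


def run_report(results_dir: str | Path) -> str:
    """Render the stored analysis results; no recomputation."""
    results_dir = Path(results_dir)
    path = results_dir / "results.json"
    if not path.exists():
        raise ConfigError(f"missing results file {path}")
    doc = json.loads(path.read_text())
    lines = []
    man = doc["manifest"]
    lines.append(f"analysis {man.get('hash', '?')}: "
                 f"{len(man.get('subjects_analysed', []))} subjects analysed")
    if man.get("outliers_removed"):
        lines.append(f"  outliers removed: "
                     f"{[o['subject'] for o in man['outliers_removed']]}")
    if man.get("subjects_dropped"):
        lines.append(f"  dropped (missing data): "
                     f"{[o['subject'] for o in man['subjects_dropped']]}")
    for repdoc in doc["lv_reports"]:
        lines.append(
            f"LV{repdoc['lv']}: p = {repdoc['p_value']:.4g}, "
            f"{repdoc['pct_covariance']:.2f}% covariance")
        sig = [c for c in repdoc["correlations"] if c.get("significant")]
        for c in sig:
            lines.append(
                f"  {c['condition']}/{c['variable']}: r = {c['r']:+.3f} "
                f"[{c['lower']:+.3f}, {c['upper']:+.3f}]")
        npos = len(repdoc["peaks"]["positive"])
        nneg = len(repdoc["peaks"]["negative"])
        lines.append(f"  clusters: {npos} positive, {nneg} negative")
    if "recovery" in man:
        rec = man["recovery"]
        lines.append(f"recovery vs planted truth: cosine "
                     f"{rec['cosine']:.3f}"
                     + (f", sensitivity {rec['sensitivity']:.3f}"
                        if "sensitivity" in rec else ""))
    return "\n".join(lines)
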