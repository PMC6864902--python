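"""Event-locked trial-window extraction and the per-subject variable block.

Turns per-subject 4D BOLD series plus event tables into the
subjects x conditions x (lags x voxels) datamat, and assembles the
seed / tract-FA / reaction-time variable block that the condition-wise
correlation step consumes. Each trial contributes a 6-TR window starting at
the scan at-or-before the video onset, expressed as percent signal change
relative to that onset scan, and windows are averaged within
subject x condition.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

log = logging.getLogger("seedpls")

DEFAULT_LAG_COUNT = 6
EVENT_COLUMNS = ("onset", "duration", "condition", "accuracy", "rt")


@dataclasses.dataclass
class VolumeSeries:
    """One subject's 4D BOLD series with its affine and repetition time."""

    data: np.ndarray      # (x, y, z, t)
    affine: np.ndarray    # 4x4 voxel -> mm
    tr_s: float

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be > 0")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")


@dataclasses.dataclass
class TrialWindowMatrix:
    """Subjects x conditions x lags x in-mask voxels event-locked datamat."""

    values: np.ndarray            # (S, C, L, V) percent signal change
    subjects: list[str]
    conditions: list[str]
    lag_count: int
    mask: np.ndarray              # 3D bool, the original mask
    affine: np.ndarray
    voxel_ids: np.ndarray         # (V,) indices into mask-flat voxel order

    @property
    def n_columns(self) -> int:
        return self.lag_count * self.values.shape[-1]

    @property
    def ijk(self) -> np.ndarray:
        """(V, 3) voxel indices for the retained columns."""
        return np.argwhere(self.mask)[self.voxel_ids]

    def as_2d(self) -> np.ndarray:
        """(S, C, L*V) lag-major flattening of the voxel dimensions."""
        s, c, l, v = self.values.shape
        return self.values.reshape(s, c, l * v)

    def drop_voxels(self, flat_ids: Sequence[int]) -> "TrialWindowMatrix":
        """Remove voxel columns (e.g. the seed region) by mask-flat index."""
        drop = set(int(i) for i in flat_ids)
        keep = np.array([i for i, fid in enumerate(self.voxel_ids)
                         if int(fid) not in drop])
        return dataclasses.replace(
            self, values=self.values[:, :, :, keep],
            voxel_ids=self.voxel_ids[keep])

    def select_subjects(self, subjects: Sequence[str]) -> "TrialWindowMatrix":
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = [pos[s] for s in subjects]
        return dataclasses.replace(self, values=self.values[idx],
                                   subjects=list(subjects))


@dataclasses.dataclass
class VariableBlock:
    """Per subject x condition values of the correlated variables.

    Subject-level variables (tract FA) are replicated across conditions, as
    one structural value enters every condition's correlation row.
    """

    values: np.ndarray            # (S, C, n_variables)
    subjects: list[str]
    conditions: list[str]
    variable_order: tuple[str, ...]
    dropped_subjects: list[dict] = dataclasses.field(default_factory=list)

    def select_subjects(self, subjects: Sequence[str]) -> "VariableBlock":
        pos = {s: i for i, s in enumerate(self.subjects)}
        idx = [pos[s] for s in subjects]
        return dataclasses.replace(self, values=self.values[idx],
                                   subjects=list(subjects))


def load_volume(path: str | Path, tr_s: float | None = None) -> VolumeSeries:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    tr = tr_s if tr_s is not None else (float(zooms[3]) if len(zooms) > 3 else 0.0)
    return VolumeSeries(data=np.asarray(img.dataobj, dtype=np.float64),
                        affine=np.asarray(img.affine), tr_s=tr)


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0.5, np.asarray(img.affine)


def load_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(ev.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns {sorted(missing)}")
    return ev


def _extract_subject_windows(series: VolumeSeries, events: pd.DataFrame,
                             mask: np.ndarray, conditions: Sequence[str],
                             lag_count: int, subject: str) -> np.ndarray:
    flat = series.data[mask]                      # (V, T)
    n_scans = flat.shape[1]
    out = np.zeros((len(conditions), lag_count, flat.shape[0]))
    for ci, cond in enumerate(conditions):
        trials = events[events["condition"] == cond]
        if trials.empty:
            raise ValueError(
                f"condition {cond!r} absent for subject {subject}")
        acc = np.zeros((lag_count, flat.shape[0]))
        for ti, onset in enumerate(trials["onset"].to_numpy(dtype=float)):
            # nearest scan at or before onset: onsets are jittered off the grid
            s0 = int(np.floor(onset / series.tr_s + 1e-9))
            if s0 < 0 or s0 + lag_count > n_scans:
                raise ValueError(
                    f"trial {ti} of condition {cond!r} (subject {subject}, "
                    f"onset {onset:.2f}s) needs scans [{s0}, {s0 + lag_count})"
                    f" but the series has {n_scans}")
            ref = flat[:, s0]
            if np.any(ref <= 0):
                raise ValueError(
                    f"non-positive reference value at onset scan {s0} "
                    f"(subject {subject}, condition {cond!r})")
            win = flat[:, s0:s0 + lag_count]
            acc += ((win / ref[:, None]) - 1.0).T * 100.0
        out[ci] = acc / len(trials)
    return out


def extract_trial_windows(bold: Mapping[str, VolumeSeries],
                          events: Mapping[str, pd.DataFrame],
                          mask: np.ndarray,
                          affine: np.ndarray,
                          lag_count: int = DEFAULT_LAG_COUNT,
                          conditions: Sequence[str] | None = None
                          ) -> TrialWindowMatrix:
    """Build the datamat from per-subject volume series and event tables.

    Each trial's window is percent signal change relative to the onset scan
    (``x_lag / x_onset - 1``, in percent), averaged over trials within each
    subject x condition cell. Every subject must supply every condition.
    """
    subjects = list(bold)
    if conditions is None:
        conditions = sorted({c for ev in events.values()
                             for c in ev["condition"].unique()})
    conditions = list(conditions)
    n_vox = int(mask.sum())
    values = np.zeros((len(subjects), len(conditions), lag_count, n_vox))
    for si, sub in enumerate(subjects):
        values[si] = _extract_subject_windows(
            bold[sub], events[sub], mask, conditions, lag_count, sub)
    return TrialWindowMatrix(values=values, subjects=subjects,
                             conditions=conditions, lag_count=lag_count,
                             mask=mask, affine=np.asarray(affine),
                             voxel_ids=np.arange(n_vox))


def datamat_from_dataset(dataset, lag_count: int = DEFAULT_LAG_COUNT
                         ) -> TrialWindowMatrix:
    """In-memory datamat straight from a SimulatedDataset."""
    bold = {s: VolumeSeries(dataset.bold[s].astype(np.float64),
                            dataset.affine, dataset.tr_s)
            for s in dataset.subjects}
    return extract_trial_windows(bold, dataset.events, dataset.mask,
                                 dataset.affine, lag_count,
                                 dataset.truth.conditions)


# -- seed signal -----------------------------------------------------------

def resolve_seed_voxels(mask: np.ndarray, affine: np.ndarray,
                        seed_mni: Sequence[float] | None = None,
                        seed_ijk: Sequence[int] | None = None,
                        radius: int = 1) -> np.ndarray:
    """Mask-flat indices of the seed region: centre voxel + Chebyshev-radius
    neighbourhood (27-voxel cube for radius 1) intersected with the mask."""
    if (seed_mni is None) == (seed_ijk is None):
        raise ValueError("give exactly one of seed_mni or seed_ijk")
    if seed_ijk is None:
        inv = np.linalg.inv(affine)
        hom = inv @ np.array([*seed_mni, 1.0])
        seed_ijk = tuple(int(round(v)) for v in hom[:3])
    seed_ijk = tuple(int(v) for v in seed_ijk)
    inside = all(0 <= v < s for v, s in zip(seed_ijk, mask.shape)) \
        and bool(mask[seed_ijk])
    if not inside:
        mni = (affine @ np.array([*seed_ijk, 1.0]))[:3]
        raise ValueError(
            f"seed voxel {seed_ijk} (MNI {tuple(np.round(mni, 1))} mm) "
            "falls outside the brain mask")
    flat_of_grid = -np.ones(mask.shape, dtype=int)
    flat_of_grid[mask] = np.arange(int(mask.sum()))
    out = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            for dk in range(-radius, radius + 1):
                i, j, k = (seed_ijk[0] + di, seed_ijk[1] + dj, seed_ijk[2] + dk)
                if all(0 <= v < s for v, s in zip((i, j, k), mask.shape)) \
                        and mask[i, j, k]:
                    out.append(flat_of_grid[i, j, k])
    return np.sort(np.array(out, dtype=int))


def extract_seed_signal(windows: TrialWindowMatrix,
                        seed_mni: Sequence[float] | None = None,
                        seed_ijk: Sequence[int] | None = None,
                        radius: int = 1
                        ) -> tuple[pd.DataFrame, np.ndarray]:
    """Window-averaged seed activity per subject x condition.

    Averages the datamat over the seed voxel set and all lags. Returns the
    (subjects x conditions) table and the seed's mask-flat voxel indices so
    the caller can drop them from the brain block.
    """
    seed_voxels = resolve_seed_voxels(windows.mask, windows.affine,
                                      seed_mni, seed_ijk, radius)
    pos = {int(fid): i for i, fid in enumerate(windows.voxel_ids)}
    cols = [pos[int(v)] for v in seed_voxels if int(v) in pos]
    if not cols:
        raise ValueError("seed region has no voxels in the datamat")
    seed_mean = windows.values[:, :, :, cols].mean(axis=(2, 3))
    df = pd.DataFrame(seed_mean, index=windows.subjects,
                      columns=windows.conditions)
    return df, seed_voxels


# -- behavioural / structural tables ---------------------------------------

def compute_condition_rt(events: Mapping[str, pd.DataFrame],
                         conditions: Sequence[str]
                         ) -> tuple[pd.DataFrame, list[dict]]:
    """Mean accurate reaction time per subject x condition (ms).

    Only trials with accuracy == 1 and a recorded RT contribute. A cell with
    no accurate trials is returned as NaN and flagged for exclusion rather
    than silently imputed.
    """
    rows, flags = {}, []
    for sub, ev in events.items():
        vals = []
        for cond in conditions:
            trials = ev[(ev["condition"] == cond) & (ev["accuracy"] == 1)]
            rt = trials["rt"].dropna()
            if rt.empty:
                flags.append({"subject": sub, "condition": cond,
                              "reason": "no accurate trials"})
                vals.append(np.nan)
            else:
                vals.append(float(rt.mean()))
        rows[sub] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(conditions))
    return df, flags


def fa_long_to_wide(fa: pd.DataFrame) -> pd.DataFrame:
    """Pivot a (subject_id, tract, fa) long table to subjects x tracts."""
    for col in ("subject_id", "tract", "fa"):
        if col not in fa.columns:
            raise ValueError(f"FA table lacks column {col!r}")
    return fa.pivot(index="subject_id", columns="tract", values="fa")


def assemble_variable_block(seed_mean: pd.DataFrame,
                            fa_wide: pd.DataFrame,
                            rt: pd.DataFrame,
                            variable_order: Sequence[str]
                            ) -> VariableBlock:
    """Inner-join seed/FA/RT tables into the (S, C, V) variable block.

    Subjects missing any required FA tract (e.g. an indeterminable tract) or
    any condition's accurate-RT mean are dropped listwise and reported in
    ``dropped_subjects``.
    """
    conditions = list(seed_mean.columns)
    subjects = [s for s in seed_mean.index
                if s in fa_wide.index and s in rt.index]
    if not subjects:
        raise ValueError(
            "empty join: no common subjects across seed "
            f"({list(seed_mean.index)[:5]}...), FA "
            f"({list(fa_wide.index)[:5]}...) and RT tables")
    dropped: list[dict] = []
    tracts = [v for v in variable_order if v.startswith("fa")]
    missing_tracts = [t for t in tracts if t not in fa_wide.columns]
    if missing_tracts:
        raise ValueError(f"FA table lacks tracts {missing_tracts}")
    kept = []
    for sub in subjects:
        bad_tracts = [t for t in tracts if pd.isna(fa_wide.loc[sub, t])]
        bad_rt = [c for c in conditions if pd.isna(rt.loc[sub, c])]
        if bad_tracts:
            dropped.append({"subject": sub, "reason": "missing FA",
                            "detail": bad_tracts})
        elif "rt" in variable_order and bad_rt:
            dropped.append({"subject": sub, "reason": "missing accurate RT",
                            "detail": bad_rt})
        else:
            kept.append(sub)
    if not kept:
        raise ValueError("all subjects dropped while assembling the block")
    values = np.zeros((len(kept), len(conditions), len(variable_order)))
    for vi, name in enumerate(variable_order):
        if name == "seed":
            values[:, :, vi] = seed_mean.loc[kept, conditions].to_numpy()
        elif name == "rt":
            values[:, :, vi] = rt.loc[kept, conditions].to_numpy()
        elif name.startswith("fa"):
            values[:, :, vi] = np.repeat(
                fa_wide.loc[kept, name].to_numpy()[:, None],
                len(conditions), axis=1)
        else:
            raise ValueError(f"unknown variable {name!r} in variable_order")
    if dropped:
        log.info("assemble_variable_block: dropped %d subjects: %s",
                 len(dropped), dropped)
    return VariableBlock(values=values, subjects=kept, conditions=conditions,
                         variable_order=tuple(variable_order),
                         dropped_subjects=dropped)


def exclude_outliers(block: VariableBlock, z_threshold: float = 3.0
                     ) -> tuple[VariableBlock, list[dict]]:
    """Remove subjects with any variable |z| > threshold (default 3).

    z-scores are computed across subjects within each condition x variable
    cell (sample standard deviation). Zero-variance cells score z = 0 with a
    warning. Removing subjects may not leave fewer than 3.
    """
    if len(block.subjects) < 3:
        raise ValueError("outlier exclusion needs >= 3 subjects")
    x = block.values
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    zero = sd <= 0
    if np.any(zero):
        warnings.warn("zero-variance variable cells; z treated as 0",
                      stacklevel=2)
    z = np.where(zero, 0.0, (x - mean) / np.where(zero, 1.0, sd))
    removed: list[dict] = []
    keep_mask = np.ones(len(block.subjects), dtype=bool)
    for si, sub in enumerate(block.subjects):
        hits = np.argwhere(np.abs(z[si]) > z_threshold)
        if hits.size:
            ci, vi = hits[np.argmax([abs(z[si, a, b]) for a, b in hits])]
            removed.append({"subject": sub,
                            "condition": block.conditions[ci],
                            "variable": block.variable_order[vi],
                            "z": float(z[si, ci, vi])})
            keep_mask[si] = False
    kept = [s for s, k in zip(block.subjects, keep_mask) if k]
    if len(kept) < 3:
        raise ValueError(
            f"outlier removal would leave {len(kept)} subjects (< 3)")
    if removed:
        log.info("exclude_outliers: removed %s", removed)
    out = dataclasses.replace(block, values=x[keep_mask], subjects=kept)
    return out, removed
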