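"""Cluster-extent thresholding of bootstrap-ratio maps and the LV report.

Bootstrap-ratio (BSR) maps are binarised at |BSR| > threshold separately for
the positive and negative salience poles, 3D connected components are
labelled within each post-onset lag (26-connectivity by default,
6-connectivity selectable), clusters below the extent threshold are removed,
and one peak (the max-|BSR| voxel) is reported per surviving cluster with its
MNI-mm coordinates. The per-LV report combines permutation significance,
percent covariance, task saliences, condition-wise brain-score correlations
with bootstrap confidence intervals, and the peak table, listing the two
salience poles separately (the positive and negative ends of an LV are
alternative patterns of correlated activity).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as _sk_label

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}
DEFAULT_BSR_THRESHOLD = 3.0   # approximates p < 0.001
DEFAULT_MIN_CLUSTER = 100     # voxels, per lag


@dataclasses.dataclass
class ClusterPeak:
    lv: int
    sign: str                  # "positive" | "negative"
    lag: int                   # TR index of the peak's map
    ijk: tuple[int, int, int]
    mni_xyz: tuple[float, float, float]
    peak_bsr: float
    cluster_voxels: int


def voxel_to_mni(ijk: Sequence[float], affine: np.ndarray
                 ) -> tuple[float, float, float]:
    """Voxel indices to mm coordinates via the affine."""
    hom = np.asarray(affine) @ np.array([*ijk, 1.0], dtype=float)
    return tuple(float(v) for v in hom[:3])


def mni_to_voxel(xyz: Sequence[float], affine: np.ndarray
                 ) -> tuple[float, float, float]:
    hom = np.linalg.inv(np.asarray(affine)) @ np.array([*xyz, 1.0],
                                                       dtype=float)
    return tuple(float(v) for v in hom[:3])


def _embed(values: np.ndarray, mask: np.ndarray, voxel_ids: np.ndarray
           ) -> np.ndarray:
    """Scatter a voxel-column vector back into the 3D grid (0 elsewhere)."""
    flat = np.zeros(int(mask.sum()))
    flat[voxel_ids] = values
    vol = np.zeros(mask.shape)
    vol[mask] = flat
    return vol


def _clusters_for_lag(vol: np.ndarray, inmap: np.ndarray, threshold: float,
                      connectivity: int):
    """Yield (sign, voxel ijk array, peak ijk, peak value, size) clusters."""
    for sign, sel in (("positive", vol > threshold),
                      ("negative", vol < -threshold)):
        sel = sel & inmap
        if not sel.any():
            continue
        labels = _sk_label(sel, connectivity=_CONNECTIVITY[connectivity])
        for lab in range(1, labels.max() + 1):
            coords = np.argwhere(labels == lab)
            vals = vol[tuple(coords.T)]
            peak_i = int(np.argmax(np.abs(vals)))
            yield sign, coords, tuple(int(v) for v in coords[peak_i]), \
                float(vals[peak_i]), coords.shape[0]


def threshold_bsr(bsr_map: np.ndarray, mask: np.ndarray,
                  voxel_ids: np.ndarray, affine: np.ndarray,
                  threshold: float = DEFAULT_BSR_THRESHOLD,
                  min_cluster: int = DEFAULT_MIN_CLUSTER,
                  connectivity: int = 26,
                  unstable: np.ndarray | None = None,
                  lv: int = 1) -> list[ClusterPeak]:
    """Threshold a (lags x voxels) BSR map into a cluster peak table.

    Clusters are labelled per lag and per salience pole; only clusters of at
    least ``min_cluster`` voxels survive. Peaks are sorted posterior to
    anterior (ascending MNI y) within sign, ties broken by |BSR|. Cells
    flagged unstable (zero bootstrap SE) are excluded before thresholding.
    An empty map yields an empty list.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {set(_CONNECTIVITY)}")
    bsr_map = np.asarray(bsr_map, dtype=float)
    n_lags = bsr_map.shape[0]
    peaks: list[ClusterPeak] = []
    for lag in range(n_lags):
        vals = bsr_map[lag].copy()
        if unstable is not None:
            vals = np.where(unstable[lag], 0.0, vals)
        vol = _embed(vals, mask, voxel_ids)
        inmap = _embed(np.ones(vals.size), mask, voxel_ids) > 0
        for sign, coords, peak_ijk, peak_val, size in _clusters_for_lag(
                vol, inmap, threshold, connectivity):
            if size < min_cluster:
                continue
            peaks.append(ClusterPeak(
                lv=lv, sign=sign, lag=lag, ijk=peak_ijk,
                mni_xyz=voxel_to_mni(peak_ijk, affine),
                peak_bsr=peak_val, cluster_voxels=size))
    order = {"positive": 0, "negative": 1}
    peaks.sort(key=lambda p: (order[p.sign], p.mni_xyz[1], -abs(p.peak_bsr)))
    return peaks


def detected_voxels(bsr_map: np.ndarray, mask: np.ndarray,
                    voxel_ids: np.ndarray,
                    threshold: float = DEFAULT_BSR_THRESHOLD,
                    min_cluster: int = DEFAULT_MIN_CLUSTER,
                    connectivity: int = 26,
                    unstable: np.ndarray | None = None) -> np.ndarray:
    """Mask-flat indices of voxels in surviving clusters, union over lags
    and both salience poles (the thresholded spatial support)."""
    flat_of_grid = -np.ones(mask.shape, dtype=int)
    flat_of_grid[mask] = np.arange(int(mask.sum()))
    hits: set[int] = set()
    n_lags = np.asarray(bsr_map).shape[0]
    for lag in range(n_lags):
        vals = np.asarray(bsr_map[lag], dtype=float).copy()
        if unstable is not None:
            vals = np.where(unstable[lag], 0.0, vals)
        vol = _embed(vals, mask, voxel_ids)
        inmap = _embed(np.ones(vals.size), mask, voxel_ids) > 0
        for _sign, coords, _pk, _pv, size in _clusters_for_lag(
                vol, inmap, threshold, connectivity):
            if size < min_cluster:
                continue
            hits.update(int(flat_of_grid[tuple(c)]) for c in coords)
    return np.array(sorted(hits), dtype=int)


def peaks_to_frame(peaks: Sequence[ClusterPeak]) -> pd.DataFrame:
    """Peak table in the reporting convention: lv, sign, lag, x, y, z
    (MNI mm), bsr, voxels."""
    return pd.DataFrame([{
        "lv": p.lv, "sign": p.sign, "lag": p.lag,
        "x": round(p.mni_xyz[0], 3), "y": round(p.mni_xyz[1], 3),
        "z": round(p.mni_xyz[2], 3),
        "bsr": round(p.peak_bsr, 4), "voxels": p.cluster_voxels,
    } for p in peaks], columns=["lv", "sign", "lag", "x", "y", "z",
                                "bsr", "voxels"])


def lv_report(lv, permutation, bootstrap, peaks: Sequence[ClusterPeak],
              correlations: pd.DataFrame, manifest: dict) -> dict:
    """Assemble the per-LV result document.

    ``correlations`` must carry condition/variable point estimates (column
    ``r``); CI bounds are merged from the bootstrap result and a correlation
    is flagged significant when its 95% CI excludes zero. All inputs must
    come from the same analysis manifest.
    """
    for obj, name in ((permutation, "permutation"), (bootstrap, "bootstrap")):
        tag = getattr(obj, "manifest_hash", None)
        if tag is not None and tag != manifest.get("hash"):
            raise ValueError(f"{name} result from a different analysis "
                             f"manifest ({tag} != {manifest.get('hash')})")
    k = lv.index - 1
    ci = bootstrap.correlation_ci
    ci_lv = ci[ci["lv"] == lv.index]
    merged = correlations.merge(ci_lv.drop(columns=["lv"]),
                                on=["condition", "variable"], how="left")
    merged["significant"] = ((merged["lower"] > 0) | (merged["upper"] < 0)) \
        & merged["defined"]
    pole = {s: [dataclasses.asdict(p) for p in peaks if p.sign == s]
            for s in ("positive", "negative")}
    return {
        "lv": lv.index,
        "singular_value": lv.singular_value,
        "pct_covariance": lv.pct_covariance,
        "p_value": float(permutation.p_values[k]),
        "task_salience": [float(v) for v in lv.task_salience],
        "correlations": merged.to_dict(orient="records"),
        "peaks": {"positive": pole["positive"],
                  "negative": pole["negative"]},
        "manifest_hash": manifest.get("hash"),
    }
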