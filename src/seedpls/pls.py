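"""Behavioural/seed PLS core: stacked correlation matrix, SVD, brain scores.

For each experimental condition c and each variable v (seed activity, tract
FA, reaction time), the Pearson correlation across subjects between v's value
in condition c and every (lag, voxel) datamat column in condition c forms row
(c, v) of the stacked matrix R (conditions x variables rows, condition-major).
Singular value decomposition R = U S V' yields latent variables: task
saliences (columns of U), voxel saliences (rows of V'), singular values, and
the percent cross-block covariance each LV accounts for (s_i^2 / sum s_j^2).
Brain scores project each subject's condition datamat row onto an LV's voxel
saliences.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .datamat import TrialWindowMatrix, VariableBlock

_EPS = 1e-12


@dataclasses.dataclass
class StackedCorrelationMatrix:
    values: np.ndarray                    # (n_cond * n_var, n_lags * n_vox)
    row_labels: list[tuple[str, str]]     # (condition, variable)
    conditions: list[str]
    variable_order: tuple[str, ...]
    lag_count: int
    voxel_ids: np.ndarray                 # mask-flat ids of retained voxels
    n_zero_variance_columns: int = 0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class LatentVariable:
    """One SVD component of the stacked correlation matrix."""

    index: int                       # 1-based
    singular_value: float
    voxel_salience: np.ndarray       # (n_lags * n_vox,), unit norm
    task_salience: np.ndarray        # (n_cond * n_var,), unit norm
    pct_covariance: float
    brain_scores: np.ndarray | None = None   # (S, C), filled on demand


def _standardized(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores scaled by 1/sqrt(n-1), so Z1' Z2 is the Pearson r.

    Returns the scaled z-scores and a boolean mask of zero-variance columns
    (their z columns are set to 0, i.e. r = 0 against anything).
    """
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd <= _EPS
    z = (x - mean) / np.where(zero, 1.0, sd) / np.sqrt(n - 1)
    z[:, zero] = 0.0
    return z, zero


def standardized_blocks(datamat: TrialWindowMatrix, block: VariableBlock
                        ) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Per-condition scaled z-scores of the brain and variable blocks.

    Zero variance in a variable within a condition is an error (a variable
    that does not vary cannot be correlated); zero-variance voxel columns get
    r = 0 with a warning. Columns that are identically zero are structural
    (the lag-0 percent-signal-change reference) and set to r = 0 silently.
    """
    if datamat.subjects != block.subjects:
        raise ValueError("datamat and variable block subjects differ")
    n = len(block.subjects)
    if n < 3:
        raise ValueError("need >= 3 subjects to correlate")
    x2 = datamat.as_2d()
    zb, zv, n_zero = [], [], 0
    for ci, cond in enumerate(datamat.conditions):
        z_brain, zero_cols = _standardized(x2[:, ci, :])
        identically_zero = zero_cols & (np.abs(x2[:, ci, :]).max(axis=0) == 0)
        n_zero += int((zero_cols & ~identically_zero).sum())
        z_var, zero_var = _standardized(block.values[:, ci, :])
        if np.any(zero_var):
            bad = [block.variable_order[j] for j in np.flatnonzero(zero_var)]
            raise ValueError(
                f"zero variance for variable(s) {bad} in condition {cond!r}")
        zb.append(z_brain)
        zv.append(z_var)
    if n_zero:
        warnings.warn(f"{n_zero} zero-variance voxel columns set to r = 0",
                      stacklevel=2)
    return zb, zv, n_zero


def build_stacked_correlation_matrix(datamat: TrialWindowMatrix,
                                     block: VariableBlock
                                     ) -> StackedCorrelationMatrix:
    """Condition-wise Pearson correlations of each variable with every
    (lag, voxel) column, stacked condition-major."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zb, zv, n_zero = standardized_blocks(datamat, block)
    if n_zero:
        warnings.warn(f"{n_zero} zero-variance voxel columns set to r = 0",
                      stacklevel=2)
    rows, labels = [], []
    for ci, cond in enumerate(datamat.conditions):
        r_block = zv[ci].T @ zb[ci]        # (n_var, n_cols)
        for vi, var in enumerate(block.variable_order):
            rows.append(r_block[vi])
            labels.append((cond, var))
    values = np.clip(np.vstack(rows), -1.0, 1.0)
    return StackedCorrelationMatrix(
        values=values, row_labels=labels, conditions=list(datamat.conditions),
        variable_order=block.variable_order, lag_count=datamat.lag_count,
        voxel_ids=datamat.voxel_ids, n_zero_variance_columns=n_zero)


def percent_covariance(singular_values: Sequence[float]) -> np.ndarray:
    """Percent cross-block covariance per LV: 100 * s_i^2 / sum s_j^2."""
    s = np.asarray(singular_values, dtype=float)
    if np.any(s < 0):
        raise ValueError("singular values must be >= 0")
    total = (s ** 2).sum()
    if total <= 0:
        raise ValueError("all singular values are zero")
    return 100.0 * s ** 2 / total


def _pin_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix each LV's arbitrary SVD sign: the maximum-absolute task-salience
    entry is made positive (ties resolved by the first such entry)."""
    for k in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, k])))
        if u[i, k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]
    return u, vt


def svd_decompose(scm: StackedCorrelationMatrix,
                  ) -> list[LatentVariable]:
    """Decompose R into latent variables ordered by singular value."""
    r = scm.values
    if not np.all(np.isfinite(r)):
        raise ValueError("stacked correlation matrix has non-finite entries")
    u, s, vt = np.linalg.svd(r, full_matrices=False)
    if s[0] <= _EPS:
        raise ValueError("degenerate matrix: all singular values are zero")
    u, vt = _pin_signs(u, vt)
    pct = percent_covariance(s)
    return [LatentVariable(index=k + 1, singular_value=float(s[k]),
                           voxel_salience=vt[k], task_salience=u[:, k],
                           pct_covariance=float(pct[k]))
            for k in range(s.size)]


def singular_values(r: np.ndarray) -> np.ndarray:
    """Singular values via the small-side Gram matrix (fast path for the
    permutation loop; identical to full SVD to numerical precision)."""
    if r.shape[0] <= r.shape[1]:
        g = r @ r.T
    else:
        g = r.T @ r
    ev = np.linalg.eigvalsh(g)[::-1]
    return np.sqrt(np.clip(ev, 0.0, None))


def compute_brain_scores(datamat: TrialWindowMatrix, lv: LatentVariable
                         ) -> np.ndarray:
    """Per subject x condition projection of the datamat onto the LV's voxel
    saliences (how strongly each subject expresses the pattern)."""
    x2 = datamat.as_2d()
    if x2.shape[-1] != lv.voxel_salience.size:
        raise ValueError(
            f"dimension mismatch: datamat has {x2.shape[-1]} columns, "
            f"voxel salience has {lv.voxel_salience.size}")
    return x2 @ lv.voxel_salience


def correlate_brain_scores(scores: np.ndarray, block: VariableBlock
                           ) -> pd.DataFrame:
    """Pearson r across subjects, within condition, between brain scores and
    each variable. Undefined correlations (zero variance) are flagged."""
    if scores.shape[0] < 3:
        raise ValueError("need >= 3 subjects to correlate")
    rows = []
    for ci, cond in enumerate(block.conditions):
        s = scores[:, ci]
        s_sd = s.std(ddof=1)
        for vi, var in enumerate(block.variable_order):
            v = block.values[:, ci, vi]
            v_sd = v.std(ddof=1)
            defined = s_sd > _EPS and v_sd > _EPS
            if defined:
                r = float(np.corrcoef(s, v)[0, 1])
            else:
                r = np.nan
            rows.append({"condition": cond, "variable": var, "r": r,
                         "defined": bool(defined)})
    return pd.DataFrame(rows)
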