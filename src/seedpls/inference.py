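"""Resampling inference: permutation LV significance, bootstrap salience SEs.

Permutation test: the subject assignment of the variable rows is shuffled
relative to the brain rows, independently within each condition (preserving
the condition structure and the marginal variable distributions), the stacked
correlation matrix is rebuilt and re-decomposed, and the p-value for LV i is
(count of permuted s_i >= observed s_i + 1) / (n_perm + 1) with per-index
(non-resorted) null singular values.

Bootstrap: subjects are resampled with replacement (the same resample applied
jointly to the brain and variable blocks), R is rebuilt and re-decomposed,
and the resampled saliences are aligned to the original decomposition by an
orthogonal Procrustes transform (resolving sign flips and axis swaps) before
standard errors are taken. The rotation is estimated on the low-dimensional
task-salience side, weighted by the singular values, and applied to both
sides: estimating it from the voxel saliences themselves would overfit the
reference's voxel-level noise and bias the voxel SEs downward, and the
weighting keeps near-null LVs from leaking arbitrary axes into stable ones.
Bootstrap ratios are salience / SE; correlation confidence intervals are
2.5/97.5 percentiles of the aligned brain-score / variable correlations.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .datamat import TrialWindowMatrix, VariableBlock
from .pls import (build_stacked_correlation_matrix, singular_values,
                  standardized_blocks, svd_decompose)

log = logging.getLogger("seedpls")

_EPS = 1e-12
DEFAULT_N_PERM = 500
DEFAULT_N_BOOT = 100


@dataclasses.dataclass
class PermutationResult:
    p_values: np.ndarray               # per LV, in [1/(n_perm+1), 1]
    observed_singular_values: np.ndarray
    null_singular_values: np.ndarray   # (n_perm, n_lv)
    n_perm: int
    seed: int | None


@dataclasses.dataclass
class BootstrapResult:
    salience_se: np.ndarray            # (n_lv, n_cols), >= 0
    bsr: np.ndarray                    # salience / SE; +-inf where SE == 0
    unstable: np.ndarray               # bool, SE == 0 cells (excluded later)
    correlation_ci: pd.DataFrame       # lv, condition, variable, lower, upper
    n_boot: int
    n_redraws: int
    seed: int | None


def permutation_test(datamat: TrialWindowMatrix, block: VariableBlock,
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int | None = None) -> PermutationResult:
    """Permutation significance for every LV of the stacked matrix."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(block.subjects)
    if n < 4:
        raise ValueError("permutation test needs >= 4 subjects "
                         "(too few distinct permutations)")
    if n_perm < 20:
        warnings.warn("n_perm < 20: p-value resolution is coarse",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        zb, zv, _ = standardized_blocks(datamat, block)
    n_cond = len(datamat.conditions)
    n_var = len(block.variable_order)

    def _stack(zvars: list[np.ndarray]) -> np.ndarray:
        rows = []
        for ci in range(n_cond):
            rows.append(zvars[ci].T @ zb[ci])
        return np.vstack(rows)

    obs = singular_values(_stack(zv))
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, obs.size))
    for p in range(n_perm):
        perm_zv = [zv[ci][rng.permutation(n)] for ci in range(n_cond)]
        null[p] = singular_values(_stack(perm_zv))
    p_values = ((null >= obs[None, :]).sum(axis=0) + 1) / (n_perm + 1)
    return PermutationResult(p_values=p_values, observed_singular_values=obs,
                             null_singular_values=null, n_perm=n_perm,
                             seed=seed)


def procrustes_align(boot_saliences: np.ndarray,
                     reference_saliences: np.ndarray) -> np.ndarray:
    """Align a resampled salience set (rows = LVs) to the reference set.

    Finds the orthogonal transform across LV axes (rotation / reflection,
    which subsumes per-LV sign flips and axis swaps) minimising the Frobenius
    distance to the reference. Falls back to per-LV sign alignment when the
    cross-product is rank deficient.
    """
    boot = np.asarray(boot_saliences, dtype=float)
    ref = np.asarray(reference_saliences, dtype=float)
    if boot.shape != ref.shape:
        raise ValueError(
            f"shape mismatch: boot {boot.shape}, reference {ref.shape}")
    norms = np.linalg.norm(ref, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("reference saliences must be unit norm per LV")
    q = _procrustes_transform(boot, ref)
    if q is None:
        log.warning("procrustes cross-product rank deficient; "
                    "falling back to per-LV sign alignment")
        return _sign_align(boot, ref)
    return q @ boot


def _procrustes_transform(boot: np.ndarray, ref: np.ndarray
                          ) -> np.ndarray | None:
    """Orthogonal (K, K) transform Q minimising ||Q boot - ref||_F for
    row-wise LV sets; None when the cross-product is rank deficient."""
    m = boot @ ref.T
    sv = np.linalg.svd(m, compute_uv=False)
    if sv.min() <= 1e-10 * max(sv.max(), 1.0):
        return None
    q, _ = orthogonal_procrustes(boot.T, ref.T)
    return q.T


def _sign_align(boot: np.ndarray, ref: np.ndarray) -> np.ndarray:
    signs = np.sign(np.einsum("kp,kp->k", boot, ref))
    signs[signs == 0] = 1.0
    return boot * signs[:, None]


def bootstrap_ratio(original_salience: np.ndarray, salience_se: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise salience / SE, with SE == 0 cells flagged unstable.

    Unstable cells carry signed infinity and are excluded from thresholding.
    """
    sal = np.asarray(original_salience, dtype=float)
    se = np.asarray(salience_se, dtype=float)
    if sal.shape != se.shape:
        raise ValueError("salience and SE shapes differ")
    if np.any(se < 0):
        raise ValueError("negative bootstrap SE (internal invariant violated)")
    unstable = se <= _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(unstable, np.sign(sal) * np.inf, sal / np.where(
            unstable, 1.0, se))
    bsr[unstable & (sal == 0)] = 0.0
    return bsr, unstable


def bootstrap_saliences(datamat: TrialWindowMatrix, block: VariableBlock,
                        n_boot: int = DEFAULT_N_BOOT,
                        seed: int | None = None,
                        n_ci_lvs: int = 2,
                        max_redraw_fraction: float = 0.2) -> BootstrapResult:
    """Bootstrap SEs of voxel saliences and correlation CIs.

    Each iteration resamples subjects with replacement, rebuilds the stacked
    correlation matrix, re-runs the SVD, and Procrustes-aligns the resampled
    voxel saliences to the original before accumulating (rotation estimated
    on the task-salience side, applied to both). Draws in which any variable
    has zero variance within a condition are redrawn (counted;
    > ``max_redraw_fraction`` * n_boot redraws is an error).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    n = len(block.subjects)
    scm = build_stacked_correlation_matrix(datamat, block)
    lvs = svd_decompose(scm)
    v_ref = np.vstack([lv.voxel_salience for lv in lvs])   # (K, P)
    s_ref = np.array([lv.singular_value for lv in lvs])
    # singular-value weighting: near-null LVs carry no weight in the
    # alignment, so arbitrary null-space axes cannot leak into stable LVs
    u_ref_w = np.vstack([lv.task_salience for lv in lvs]) * s_ref[:, None]
    n_lv = v_ref.shape[0]
    n_ci_lvs = min(n_ci_lvs, n_lv)
    x2 = datamat.as_2d()
    n_cond = len(block.conditions)
    n_var = len(block.variable_order)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, n_lv, v_ref.shape[1]))
    corr_draws = np.empty((n_boot, n_ci_lvs, n_cond, n_var))
    n_redraws = 0
    max_redraws = int(np.ceil(max_redraw_fraction * n_boot))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        sd = block.values[idx].std(axis=0, ddof=1)
        if np.any(sd <= _EPS):
            n_redraws += 1
            if n_redraws > max_redraws:
                raise ValueError(
                    f"more than {max_redraws} zero-variance bootstrap draws")
            continue
        sub_dm = dataclasses.replace(
            datamat, values=datamat.values[idx],
            subjects=[block.subjects[i] for i in idx])
        sub_block = dataclasses.replace(
            block, values=block.values[idx],
            subjects=[block.subjects[i] for i in idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scm_b = build_stacked_correlation_matrix(sub_dm, sub_block)
        u_b, s_b, vt_b = np.linalg.svd(scm_b.values, full_matrices=False)
        q = _procrustes_transform(u_b.T * s_b[:, None], u_ref_w)
        v_al = q @ vt_b if q is not None else _sign_align(vt_b, v_ref)
        boots[b] = v_al
        x_res = x2[idx]                                    # (n, C, P)
        for k in range(n_ci_lvs):
            scores = x_res @ v_al[k]                       # (n, C)
            for ci in range(n_cond):
                s_c = scores[:, ci]
                s_sd = s_c.std(ddof=1)
                for vi in range(n_var):
                    v_c = block.values[idx, ci, vi]
                    v_sd = v_c.std(ddof=1)
                    if s_sd > _EPS and v_sd > _EPS:
                        corr_draws[b, k, ci, vi] = np.corrcoef(s_c, v_c)[0, 1]
                    else:
                        corr_draws[b, k, ci, vi] = np.nan
        b += 1

    se = boots.std(axis=0, ddof=1)
    sal = v_ref
    bsr, unstable = bootstrap_ratio(sal, se)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = np.nanpercentile(corr_draws, 2.5, axis=0)
        hi = np.nanpercentile(corr_draws, 97.5, axis=0)
    for k in range(n_ci_lvs):
        for ci, cond in enumerate(block.conditions):
            for vi, var in enumerate(block.variable_order):
                rows.append({"lv": k + 1, "condition": cond, "variable": var,
                             "lower": float(lo[k, ci, vi]),
                             "upper": float(hi[k, ci, vi])})
    ci_df = pd.DataFrame(rows)
    if n_redraws:
        log.info("bootstrap_saliences: %d redraws due to zero variance",
                 n_redraws)
    return BootstrapResult(salience_se=se, bsr=bsr, unstable=unstable,
                           correlation_ci=ci_df, n_boot=n_boot,
                           n_redraws=n_redraws, seed=seed)
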