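"""Two-stage dual regression.

Stage 1 regresses each timepoint's masked spatial pattern on all component
maps jointly, giving one time course per component per block.  Stage 2
regresses every target voxel's time series on the (variance-normalized)
stage-1 time courses, converting coefficients to z-like statistics via the
residual error of the regression.
"""

from __future__ import annotations

import numpy as np

from .mica import ComponentSet
from .types import BoldBlock


def _check_collinearity(maps: np.ndarray):
    d = maps.shape[0]
    if d < 2:
        return
    c = np.corrcoef(maps)
    for i in range(d):
        for j in range(i + 1, d):
            if abs(c[i, j]) > 0.9999:
                raise ValueError(
                    f"stage-1 design is rank deficient: components {i} and {j} "
                    f"are collinear (|r|={abs(c[i, j]):.6f})")


def stage1_timecourses(block: BoldBlock, components: ComponentSet,
                       mask: np.ndarray) -> np.ndarray:
    """Per-component time courses for one block, shape (T, d)."""
    mask = np.asarray(mask, dtype=bool)
    maps = components.spatial_maps                  # (d, n_vox)
    _check_collinearity(maps)
    Y = block.data[mask]                            # (n_vox, T)
    # GLM with a spatial intercept: exact for maps of any mean level
    M = np.column_stack([np.ones(maps.shape[1]), maps.T])
    tc, *_ = np.linalg.lstsq(M, Y, rcond=None)      # (d+1, T)
    return tc[1:].T


def stage2_zmaps(series: np.ndarray, timecourses: np.ndarray) -> np.ndarray:
    """z-statistic maps for a set of voxel time series.

    series: (n_targets, T); timecourses: (T, d).  Returns (d, n_targets):
    per voxel, multiple regression with intercept on the variance-normalized
    time courses; z = beta / se(beta).
    """
    T, d = timecourses.shape
    tc = timecourses - timecourses.mean(axis=0, keepdims=True)
    sd = tc.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    tc = tc / sd
    X = np.column_stack([np.ones(T), tc])           # (T, d+1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    P = XtX_inv @ X.T                               # (d+1, T)
    B = P @ series.T                                # (d+1, n_targets)
    resid = series.T - X @ B
    dof = max(T - (d + 1), 1)
    sse = np.sum(resid ** 2, axis=0)
    var_scale = np.diag(XtX_inv)[1:, None]          # skip the intercept
    se = np.sqrt(np.maximum(sse[None, :] / dof * var_scale, 1e-300))
    return B[1:, :] / se


def dual_regress_block(block: BoldBlock, components: ComponentSet,
                       mask: np.ndarray,
                       target_mask: np.ndarray | None = None):
    """Stage 1 + stage 2 for one block.

    ``target_mask`` selects stage-2 voxels (None = whole volume).  Returns
    (timecourses (T, d), zmaps (d, n_targets)).
    """
    tcs = stage1_timecourses(block, components, mask)
    if target_mask is None:
        series = block.data.reshape(-1, block.n_timepoints)
    else:
        series = block.data[np.asarray(target_mask, dtype=bool)]
    z = stage2_zmaps(series, tcs)
    return tcs, z
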