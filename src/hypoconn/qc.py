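"""Temporal SNR and contrast-to-noise ratio quality metrics.

tSNR is the voxelwise temporal mean divided by the temporal standard
deviation (sample sd, n-1); the scalar summary is the mean over valid mask
voxels.  CNR is the voxelwise ratio of the 45-minute block's signal sd to
the baseline block's sd.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .types import BoldBlock


def _as_series(x) -> np.ndarray:
    """Accept a BoldBlock, a 4D array, or a (n_vox, T) matrix."""
    if isinstance(x, BoldBlock):
        return x.data
    return np.asarray(x, dtype=float)


def tsnr(series, mask: np.ndarray | None = None):
    """Voxelwise tSNR map and its mean over valid mask voxels.

    ``series`` may be one block or a temporally concatenated array.  Voxels
    with zero temporal sd are flagged NaN and excluded from the summary.
    """
    data = _as_series(series)
    if data.ndim == 4:
        if mask is not None:
            data = data[np.asarray(mask, dtype=bool)]
        else:
            data = data.reshape(-1, data.shape[-1])
    if data.shape[-1] < 2:
        raise ValueError("tSNR needs at least 2 timepoints")
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = mean / sd
    tmap[sd == 0] = np.nan
    valid = np.isfinite(tmap)
    summary = float(tmap[valid].mean()) if valid.any() else np.nan
    return tmap, summary


def cnr(baseline: BoldBlock, post45: BoldBlock, mask: np.ndarray):
    """Voxelwise sd(post45) / sd(baseline) and its mean over valid voxels."""
    mask = np.asarray(mask, dtype=bool)
    if baseline.data.shape[:3] != post45.data.shape[:3]:
        raise ValueError("blocks have mismatched geometry")
    sd_b = baseline.data[mask].std(axis=-1, ddof=1)
    sd_p = post45.data[mask].std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cmap = sd_p / sd_b
    cmap[sd_b == 0] = np.nan
    valid = np.isfinite(cmap)
    summary = float(cmap[valid].mean()) if valid.any() else np.nan
    return cmap, summary


def concatenated_tsnr(blocks: list[BoldBlock], mask: np.ndarray) -> float:
    """tSNR of the temporally concatenated series over the mask."""
    mask = np.asarray(mask, dtype=bool)
    cat = np.concatenate([b.data[mask] for b in blocks], axis=1)
    _, summary = tsnr(cat)
    return summary


def compare_block_metrics(values_a, values_b):
    """Welch two-sided t-test between two per-block metric samples.

    Returns (t, p, (mean_a, sd_a), (mean_b, sd_b)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each metric sample needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return (float(t), float(p),
            (float(a.mean()), float(a.std(ddof=1))),
            (float(b.mean()), float(b.std(ddof=1))))


def qc_report(blocks: list[BoldBlock], mask: np.ndarray) -> dict:
    """Per-block and concatenated tSNR plus per-session CNR summaries."""
    mask = np.asarray(mask, dtype=bool)
    per_block = []
    by_session = {}
    for b in blocks:
        _, s = tsnr(b, mask)
        per_block.append({"session": b.design.session_id,
                          "block": b.block_label, "tsnr": s})
        by_session.setdefault(b.design.session_id, {})[b.block_label] = b
    cnrs = []
    for ses, d in by_session.items():
        if "baseline" in d and "post45" in d:
            _, c = cnr(d["baseline"], d["post45"], mask)
            cnrs.append({"session": ses, "cnr": c})
    return {
        "per_block_tsnr": per_block,
        "per_session_cnr": cnrs,
        "concatenated_tsnr": concatenated_tsnr(blocks, mask),
        "mean_block_tsnr": float(np.mean([r["tsnr"] for r in per_block])),
        "mean_cnr": float(np.mean([r["cnr"] for r in cnrs])) if cnrs else np.nan,
    }
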