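"""Per-block signal conditioning: grand mean scaling and temporal high-pass.

The high-pass is realized as regression against a discrete-cosine
low-frequency basis (all basis frequencies below the cutoff), keeping the
residual and restoring each voxel's temporal mean.  This is deterministic,
linear and edge-safe on short blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BoldBlock


@dataclass(frozen=True)
class ConditioningParams:
    grand_mean_target: float = 10000.0
    highpass_cutoff_hz: float = 0.01


def grand_mean_scale(block: BoldBlock, mask: np.ndarray,
                     target: float = 10000.0) -> BoldBlock:
    """Rescale so the mean over (mask voxels x timepoints) equals ``target``.

    The grand mean is taken over the analysis mask, keeping the analysis
    region comparable across sessions.
    """
    mask = np.asarray(mask, dtype=bool)
    gm = float(block.data[mask].mean())
    if gm <= 0:
        raise ValueError(f"grand mean over mask is {gm:.3g}; cannot scale "
                         "non-positive data")
    return block.with_data(block.data * (target / gm))


def dct_highpass_basis(T: int, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine basis columns with frequency below ``cutoff_hz``.

    Column j (j >= 1) is cos(pi * j * (t + 0.5) / T), frequency j / (2 * T * TR).
    Returns shape (T, n_basis); may have zero columns if the block is short.
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist:.4g} Hz")
    n_basis = int(np.floor(2.0 * T * tr_seconds * cutoff_hz))
    t = np.arange(T) + 0.5
    cols = [np.cos(np.pi * j * t / T) for j in range(1, n_basis + 1)]
    if not cols:
        return np.empty((T, 0))
    basis = np.stack(cols, axis=1)
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


def highpass_filter(block: BoldBlock, cutoff_hz: float = 0.01) -> BoldBlock:
    """Remove fluctuations slower than ``cutoff_hz``; temporal means preserved."""
    T = block.n_timepoints
    if T < 8:
        raise ValueError("need at least 8 timepoints to filter")
    basis = dct_highpass_basis(T, block.design.tr_seconds, cutoff_hz)
    data = block.data
    mean = data.mean(axis=3, keepdims=True)
    if basis.shape[1] == 0:
        return block.with_data(data.copy())
    flat = (data - mean).reshape(-1, T)
    # Basis columns are orthonormal: projection = flat @ B @ B.T
    fitted = (flat @ basis) @ basis.T
    out = (flat - fitted).reshape(data.shape) + mean
    return block.with_data(out)


def condition_block(block: BoldBlock, mask: np.ndarray,
                    params: ConditioningParams = ConditioningParams()) -> BoldBlock:
    """Grand mean scaling followed by high-pass filtering (in that order)."""
    return highpass_filter(grand_mean_scale(block, mask, params.grand_mean_target),
                           params.highpass_cutoff_hz)


def condition_blocks(blocks, mask, params: ConditioningParams = ConditioningParams()):
    return [condition_block(b, mask, params) for b in blocks]
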