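"""Anatomical specificity screening of components.

Each component is dual-regressed to the whole volume; its association map is
summarized as the weighted quotient Q of mean |z| in gray matter versus
white matter plus CSF (probabilistic tissue weights).  Components with
Q < 1 couple more to WM/CSF than to gray matter and are flagged unspecific
and removed before connectivity inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dualreg import dual_regress_block
from .mica import ComponentSet
from .types import BoldBlock, TissuePriors


@dataclass
class SpecificityResult:
    quotients: np.ndarray            # (d,)
    classifications: list            # "specific" | "unspecific" | "degenerate"
    zmaps: np.ndarray                # (d, nx, ny, nz) whole-volume |association|
    tissue_weight_sums: dict = field(default_factory=dict)


def dual_regress_wholebrain(blocks: list[BoldBlock], components: ComponentSet,
                            mask: np.ndarray) -> np.ndarray:
    """Whole-volume association z-map per component, averaged over blocks."""
    shape = blocks[0].geometry.shape
    acc = np.zeros((components.d, int(np.prod(shape))))
    for b in blocks:
        _, z = dual_regress_block(b, components, mask, target_mask=None)
        acc += z
    acc /= len(blocks)
    return acc.reshape((components.d,) + tuple(shape))


def specificity_quotient(zmap: np.ndarray, priors: TissuePriors) -> float:
    """Weighted-mean quotient of |z| in GM versus WM+CSF.

    Q = (sum p_gm |z| / sum p_gm) / (sum (p_wm + p_csf) |z| / sum (p_wm + p_csf)).
    """
    absz = np.abs(zmap)
    w_gm = priors.gm
    w_nc = priors.wm + priors.csf
    sum_gm = w_gm.sum()
    sum_nc = w_nc.sum()
    if sum_gm <= 0 or sum_nc <= 0:
        raise ValueError("degenerate tissue priors: zero total weight")
    num = (w_gm * absz).sum() / sum_gm
    den = (w_nc * absz).sum() / sum_nc
    if den == 0:
        return np.inf if num > 0 else np.nan
    return float(num / den)


def screen_components(blocks: list[BoldBlock], components: ComponentSet,
                      mask: np.ndarray, priors: TissuePriors) -> SpecificityResult:
    zmaps = dual_regress_wholebrain(blocks, components, mask)
    qs = np.empty(components.d)
    cls = []
    for k in range(components.d):
        q = specificity_quotient(zmaps[k], priors)
        qs[k] = q
        if not np.isfinite(q):
            cls.append("degenerate")
        else:
            cls.append("unspecific" if q < 1.0 else "specific")
    return SpecificityResult(
        quotients=qs, classifications=cls, zmaps=zmaps,
        tissue_weight_sums={"gm": float(priors.gm.sum()),
                            "wm_csf": float((priors.wm + priors.csf).sum())})


def filter_components(components: ComponentSet, result: SpecificityResult):
    """Drop unspecific components (Q < 1); returns (subset, removal report)."""
    keep = [k for k, c in enumerate(result.classifications) if c != "unspecific"]
    removed = [k for k in range(components.d) if k not in keep]
    report = {"removed_indices": removed,
              "removed_quotients": [float(result.quotients[k]) for k in removed],
              "n_retained": len(keep)}
    subset = ComponentSet(
        d=len(keep),
        spatial_maps=components.spatial_maps[keep],
        timecourses=(components.timecourses[:, keep]
                     if components.timecourses is not None else None),
        mask=components.mask,
        voxel_index=components.voxel_index,
        seed=components.seed,
        convergence_info=components.convergence_info,
        segment_table=components.segment_table)
    return subset, report
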