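"""Nonparametric connectivity inference.

Dual regression back to the analysis mask gives one z-map per session,
block and component.  Differences across the three blocks are tested with a
repeated-measures F statistic (sessions as the blocking factor) and post-hoc
paired t statistics, both assessed by permutation: condition labels are
permuted within sessions (F) or per-session differences are sign-flipped
(t).  Every permuted statistic map is enhanced with TFCE and the maximum
over the mask forms the family-wise error null distribution.  A Bonferroni
factor across components accounts for testing many components.

TFCE is computed simultaneously for a whole stack of permuted maps by
labeling connected components of a 4D array whose structuring element has
no connectivity along the stacking axis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dualreg import dual_regress_block
from .mica import ComponentSet
from .types import BLOCK_LABELS, BoldBlock

_CONN_TO_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class TfceParams:
    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.E <= 0 or self.H < 0:
            raise ValueError("TFCE needs E > 0 and H >= 0")
        if self.n_steps < 10:
            raise ValueError("TFCE needs at least 10 integration steps")
        if self.connectivity not in _CONN_TO_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class DualRegressionMaps:
    zmaps: np.ndarray               # (n_sessions, n_blocks, d, n_vox)
    stage1_timecourses: np.ndarray  # (n_sessions, n_blocks, T, d)
    session_ids: list
    block_labels: tuple
    mask: np.ndarray                # boolean volume
    voxel_index: np.ndarray         # (n_vox, 3)


@dataclass
class ComponentInference:
    component: int
    f_map: np.ndarray               # (n_vox,)
    f_tfce: np.ndarray
    f_p_fwe: np.ndarray
    f_p_bonf: np.ndarray
    f_sig_mask: np.ndarray          # boolean (n_vox,) at alpha after Bonferroni
    contrasts: dict                 # (labA, labB) -> dict(t_map, p_fwe, p_bonf, sig_mask)
    n_permutations: int
    exhaustive: bool
    zero_variance_voxels: np.ndarray


@dataclass
class StatInferenceResult:
    per_component: list             # list[ComponentInference]
    alpha: float
    n_components: int
    seed: int
    mask: np.ndarray
    voxel_index: np.ndarray
    tfce_params: TfceParams


# ---------------------------------------------------------------------------
# dual regression to the mask

def dual_regress_mask(blocks: list[BoldBlock], components: ComponentSet,
                      mask: np.ndarray) -> DualRegressionMaps:
    """Stage-1/stage-2 dual regression restricted to the analysis mask."""
    mask = np.asarray(mask, dtype=bool)
    sessions = []
    for b in blocks:
        if b.design.session_id not in sessions:
            sessions.append(b.design.session_id)
    by_key = {(b.design.session_id, b.block_label): b for b in blocks}
    n_vox = int(mask.sum())
    T = blocks[0].n_timepoints
    S, B = len(sessions), len(BLOCK_LABELS)
    zmaps = np.empty((S, B, components.d, n_vox))
    tcs = np.empty((S, B, T, components.d))
    for i, ses in enumerate(sessions):
        for j, lab in enumerate(BLOCK_LABELS):
            blk = by_key[(ses, lab)]
            tc, z = dual_regress_block(blk, components, mask, target_mask=mask)
            tcs[i, j] = tc
            zmaps[i, j] = z
    return DualRegressionMaps(zmaps=zmaps, stage1_timecourses=tcs,
                              session_ids=sessions, block_labels=BLOCK_LABELS,
                              mask=mask, voxel_index=np.argwhere(mask))


# ---------------------------------------------------------------------------
# statistic kernels

def rm_f_stat(y: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F, sessions as blocking factor.

    y: (..., S, C, V) with S sessions, C conditions.  Returns (..., V).
    Voxels with zero residual variance get an infinite sentinel.
    """
    y = np.asarray(y, dtype=float)
    S, C = y.shape[-3], y.shape[-2]
    if S < 2 or C < 2:
        raise ValueError("repeated-measures F needs >= 2 sessions and >= 2 conditions")
    m = y.mean(axis=(-3, -2), keepdims=True)
    mc = y.mean(axis=-3, keepdims=True)
    ms = y.mean(axis=-2, keepdims=True)
    ss_cond = S * ((mc - m) ** 2).sum(axis=-2)[..., 0, :]
    resid = y - ms - mc + m
    ss_res = (resid ** 2).sum(axis=(-3, -2))
    df1 = C - 1
    df2 = (C - 1) * (S - 1)
    # sums of squares below float noise (relative to the data scale) are zero
    tol = 1e-12 * np.maximum((y ** 2).sum(axis=(-3, -2)), 1e-300)
    ss_cond = np.where(ss_cond < tol, 0.0, ss_cond)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_res / df2)
    F = np.where(ss_res < tol, np.where(ss_cond > 0, np.inf, 0.0), F)
    return F


def paired_t_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Paired t over sessions: a, b of shape (..., S, V) -> (..., V)."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    S = d.shape[-2]
    if S < 2:
        raise ValueError("paired t needs at least 2 sessions")
    mean = d.mean(axis=-2)
    sd = d.std(axis=-2, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(S))
    t = np.where(sd == 0, np.where(mean > 0, np.inf,
                                   np.where(mean < 0, -np.inf, 0.0)), t)
    return t


def bonferroni_components(p: np.ndarray, n_components: int):
    """Bonferroni adjustment across components: p_adj = min(1, p * n)."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_components)


# ---------------------------------------------------------------------------
# TFCE

def _structure4d(connectivity: int) -> np.ndarray:
    st3 = ndimage.generate_binary_structure(3, _CONN_TO_RANK[connectivity])
    st4 = np.zeros((3, 3, 3, 3), dtype=bool)
    st4[1] = st3
    return st4


def tfce_stack(stat: np.ndarray, params: TfceParams = TfceParams()) -> np.ndarray:
    """TFCE of a stack of 3D maps, shape (n, nx, ny, nz), positive tail.

    Each map integrates over its own n_steps-point threshold grid from 0 to
    its maximum: TFCE(v) = sum_h extent(v, h)^E * h^H * dh.  Maps in the
    stack are labeled jointly with a structuring element that does not
    connect across the stack axis.
    """
    stat = np.asarray(stat, dtype=float)
    n = stat.shape[0]
    st4 = _structure4d(params.connectivity)
    maxes = stat.reshape(n, -1).max(axis=1)
    dh = np.where(maxes > 0, maxes / params.n_steps, 0.0)
    out = np.zeros_like(stat)
    active = dh > 0
    if not active.any():
        return out
    E, H = params.E, params.H
    for i in range(1, params.n_steps + 1):
        h = i * dh
        sup = stat >= h[:, None, None, None]
        sup &= active[:, None, None, None]
        labels, _ = ndimage.label(sup, structure=st4)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        weight = (h ** H * dh)[:, None, None, None]
        out += (sizes[labels].astype(float) ** E) * weight * sup
    return out


def _mask_bbox(mask: np.ndarray):
    """Bounding-box slices of a boolean volume (clusters cannot leave it)."""
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi)), lo


def tfce_transform(stat_map: np.ndarray, mask: np.ndarray | None = None,
                   params: TfceParams = TfceParams()) -> np.ndarray:
    """TFCE of a single 3D statistic map (positive-tail convention).

    Infinite sentinels are replaced by the map's finite maximum before the
    transform; voxels outside ``mask`` are zeroed.
    """
    vol = np.asarray(stat_map, dtype=float).copy()
    if mask is not None:
        vol = vol * np.asarray(mask, dtype=bool)
    finite = vol[np.isfinite(vol)]
    cap = finite.max() if finite.size else 0.0
    vol[np.isposinf(vol)] = cap
    vol[~np.isfinite(vol)] = 0.0
    if mask is not None and mask.any():
        # suprathreshold sets live inside the mask: work on its bounding box
        box, _ = _mask_bbox(np.asarray(mask, dtype=bool))
        out = np.zeros_like(vol)
        out[box] = tfce_stack(vol[box][None], params)[0]
        return out
    return tfce_stack(vol[None], params)[0]


# ---------------------------------------------------------------------------
# permutation machinery

def _embed(vec: np.ndarray, mask: np.ndarray, voxel_index: np.ndarray) -> np.ndarray:
    """Embed (..., n_vox) vectors into (..., nx, ny, nz) volumes."""
    shape = vec.shape[:-1] + mask.shape
    vol = np.zeros(shape, dtype=float)
    ix, iy, iz = voxel_index.T
    vol[..., ix, iy, iz] = vec
    return vol


def _cap_inf(stat: np.ndarray) -> np.ndarray:
    out = np.asarray(stat, dtype=float).copy()
    finite = out[np.isfinite(out)]
    cap = finite.max() if finite.size else 0.0
    out[np.isposinf(out)] = cap
    out[~np.isfinite(out)] = 0.0
    return out


_COND_PERMS = list(itertools.permutations(range(3)))


def _condition_permutations(S: int, n_perm: int, rng):
    """Within-session permutations of the 3 condition labels.

    Returns (idx, exhaustive) with idx of shape (P, S, 3): idx[p, s] is the
    permutation applied to session s in permutation p.
    """
    total = 6 ** S
    if total - 1 <= n_perm:
        combos = list(itertools.product(range(6), repeat=S))[1:]  # drop identity
        idx = np.array([[_COND_PERMS[c] for c in combo] for combo in combos])
        return idx, True
    idx = np.array(_COND_PERMS)[rng.integers(0, 6, size=(n_perm, S))]
    return idx, False


def _sign_flips(S: int, n_perm: int, rng):
    total = 2 ** S
    if total - 1 <= n_perm:
        flips = np.array(list(itertools.product((1.0, -1.0), repeat=S))[1:])
        return flips, True
    return rng.choice([1.0, -1.0], size=(n_perm, S)), False


def _max_over_mask(tfce_vols: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return tfce_vols[:, mask].max(axis=1) if mask.any() else np.zeros(len(tfce_vols))


def _corrected_p(obs_tfce_vec: np.ndarray, null_max: np.ndarray) -> np.ndarray:
    n_perm = len(null_max)
    exceed = (null_max[:, None] >= obs_tfce_vec[None, :]).sum(axis=0)
    return (1.0 + exceed) / (n_perm + 1.0)


def permutation_fwe_f(y: np.ndarray, mask: np.ndarray, voxel_index: np.ndarray,
                      tfce_params: TfceParams = TfceParams(),
                      n_perm: int = 5000, seed: int = 0,
                      batch: int = 128):
    """FWE-corrected p for the repeated-measures F via max-TFCE permutation.

    y: (S, C, n_vox) per-session per-condition maps for one component.
    Condition labels are permuted within each session; the observed labeling
    is always part of the reference distribution (the +1 correction).
    """
    S, C, V = y.shape
    if C != 3:
        raise ValueError("the within-session label scheme expects 3 conditions")
    rng = np.random.default_rng(seed)
    box, lo = _mask_bbox(mask)
    sub_mask = mask[box]
    sub_vi = voxel_index - lo
    f_obs = rm_f_stat(y)
    zero_var = np.isinf(f_obs)
    svi = tuple(sub_vi.T)
    tf_obs = tfce_stack(_embed(_cap_inf(f_obs), sub_mask, sub_vi)[None],
                        tfce_params)[0][svi]
    idx, exhaustive = _condition_permutations(S, n_perm, rng)
    P = idx.shape[0]
    null_max = np.empty(P)
    s_idx = np.arange(S)[None, :, None]
    for start in range(0, P, batch):
        sl = idx[start:start + batch]
        yp = y[s_idx, sl, :]                       # (b, S, C, V)
        fp = _cap_inf(rm_f_stat(yp))
        vols = _embed(fp, sub_mask, sub_vi)
        tf = tfce_stack(vols, tfce_params)
        null_max[start:start + batch] = _max_over_mask(tf, sub_mask)
    p = _corrected_p(tf_obs, null_max)
    return {"stat": f_obs, "tfce": tf_obs, "p_fwe": p,
            "null_max": null_max, "n_permutations": P, "exhaustive": exhaustive,
            "zero_variance": zero_var}


def permutation_fwe_paired_t(a: np.ndarray, b: np.ndarray, mask: np.ndarray,
                             voxel_index: np.ndarray,
                             tfce_params: TfceParams = TfceParams(),
                             n_perm: int = 5000, seed: int = 0,
                             batch: int = 256):
    """Two-sided paired-t FWE via sign-flipping and max-TFCE.

    Each tail is tested one-sided against its own max-TFCE null; the smaller
    corrected p is doubled (capped at 1).
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    S, V = d.shape
    rng = np.random.default_rng(seed)
    box, lo = _mask_bbox(mask)
    sub_mask = mask[box]
    sub_vi = voxel_index - lo
    svi = tuple(sub_vi.T)
    t_obs = paired_t_stat(a, b)
    zero_var = np.isinf(t_obs)
    tf_pos = tfce_stack(_embed(_cap_inf(t_obs), sub_mask, sub_vi)[None],
                        tfce_params)[0][svi]
    tf_neg = tfce_stack(_embed(_cap_inf(-t_obs), sub_mask, sub_vi)[None],
                        tfce_params)[0][svi]
    flips, exhaustive = _sign_flips(S, n_perm, rng)
    P = flips.shape[0]
    null_pos = np.empty(P)
    null_neg = np.empty(P)
    for start in range(0, P, batch):
        fl = flips[start:start + batch]            # (b, S)
        dp = d[None] * fl[:, :, None]
        tp = _cap_inf(paired_t_stat(dp, np.zeros_like(dp)))
        tfp = tfce_stack(_embed(tp, sub_mask, sub_vi), tfce_params)
        tfn = tfce_stack(_embed(-tp, sub_mask, sub_vi), tfce_params)
        null_pos[start:start + batch] = _max_over_mask(tfp, sub_mask)
        null_neg[start:start + batch] = _max_over_mask(tfn, sub_mask)
    p_pos = _corrected_p(tf_pos, null_pos)
    p_neg = _corrected_p(tf_neg, null_neg)
    p = np.minimum(1.0, 2.0 * np.minimum(p_pos, p_neg))
    return {"stat": t_obs, "tfce_pos": tf_pos, "tfce_neg": tf_neg,
            "p_fwe": p, "p_pos": p_pos, "p_neg": p_neg,
            "n_permutations": P, "exhaustive": exhaustive,
            "zero_variance": zero_var}


# ---------------------------------------------------------------------------
# single-subject inference across components

# Post-hoc family: change from baseline at each post-glucose time point.
# The third pairing (post10 vs post45) can be requested explicitly.
CONTRAST_PAIRS = ((0, 2), (0, 1))
ALL_PAIRS = ((0, 2), (0, 1), (1, 2))


def infer_single_subject(drmaps: DualRegressionMaps,
                         tfce_params: TfceParams = TfceParams(),
                         n_perm: int = 5000, seed: int = 0,
                         alpha: float = 0.05,
                         posthoc: str = "if_omnibus",
                         pairs: tuple = CONTRAST_PAIRS) -> StatInferenceResult:
    """Omnibus F + post-hoc paired t per component, FWE and Bonferroni corrected.

    ``posthoc``: "always", "never" or "if_omnibus" (post-hoc pairs only for
    components whose Bonferroni-corrected omnibus survives ``alpha``).
    Post-hoc pairs default to change-from-baseline at each post-glucose
    time point; pass ``pairs=ALL_PAIRS`` for every pairwise comparison.
    """
    S, B, d, V = drmaps.zmaps.shape
    mask, vi = drmaps.mask, drmaps.voxel_index
    results = []
    ss = np.random.SeedSequence(seed)
    comp_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(d)]
    for k in range(d):
        y = drmaps.zmaps[:, :, k, :]               # (S, B, V)
        res_f = permutation_fwe_f(y, mask, vi, tfce_params, n_perm,
                                  seed=comp_seeds[k])
        p_bonf = bonferroni_components(res_f["p_fwe"], d)
        sig = p_bonf < alpha
        contrasts = {}
        if posthoc == "always" or (posthoc == "if_omnibus" and sig.any()):
            for ci, (ia, ib) in enumerate(pairs):
                res_t = permutation_fwe_paired_t(
                    y[:, ib, :], y[:, ia, :], mask, vi, tfce_params, n_perm,
                    seed=comp_seeds[k] + 17 + ci)
                pb = bonferroni_components(res_t["p_fwe"], d)
                contrasts[(drmaps.block_labels[ia], drmaps.block_labels[ib])] = {
                    "t_map": res_t["stat"], "p_fwe": res_t["p_fwe"],
                    "p_bonf": pb, "sig_mask": pb < alpha,
                    "n_permutations": res_t["n_permutations"],
                    "exhaustive": res_t["exhaustive"]}
        results.append(ComponentInference(
            component=k, f_map=res_f["stat"], f_tfce=res_f["tfce"],
            f_p_fwe=res_f["p_fwe"], f_p_bonf=p_bonf, f_sig_mask=sig,
            contrasts=contrasts, n_permutations=res_f["n_permutations"],
            exhaustive=res_f["exhaustive"],
            zero_variance_voxels=res_f["zero_variance"]))
    return StatInferenceResult(per_component=results, alpha=alpha,
                               n_components=d, seed=seed, mask=mask,
                               voxel_index=vi, tfce_params=tfce_params)


# ---------------------------------------------------------------------------
# group 2 x 3 permutation ANOVA

def _group_f_stats(y: np.ndarray):
    """Repeated-measures two-factor F maps for y: (..., n, A, B, V).

    Returns (F_A, F_B, F_AB), each (..., V); subjects are the random factor,
    each effect tested against its interaction with subjects.
    """
    n, A, B = y.shape[-4], y.shape[-3], y.shape[-2]
    m = y.mean(axis=(-4, -3, -2), keepdims=True)
    ma = y.mean(axis=(-4, -2), keepdims=True)      # diet means
    mb = y.mean(axis=(-4, -3), keepdims=True)      # time means
    ms = y.mean(axis=(-3, -2), keepdims=True)      # subject means
    msa = y.mean(axis=-2, keepdims=True)           # subject x diet
    msb = y.mean(axis=-3, keepdims=True)           # subject x time
    mab = y.mean(axis=-4, keepdims=True)           # diet x time

    ss_a = (n * B) * ((ma - m) ** 2).sum(axis=-3)[..., 0, 0, :]
    ss_b = (n * A) * ((mb - m) ** 2).sum(axis=-2)[..., 0, 0, :]
    ss_ab = n * ((mab - ma - mb + m) ** 2).sum(axis=(-3, -2))[..., 0, :]
    ss_as = B * ((msa - ms - ma + m) ** 2).sum(axis=(-4, -3))[..., 0, :]
    ss_bs = A * ((msb - ms - mb + m) ** 2).sum(axis=(-4, -2))[..., 0, :]
    resid = y - msa - msb - mab + ms + ma + mb - m
    ss_abs = (resid ** 2).sum(axis=(-4, -3, -2))
    tol = 1e-12 * np.maximum((y ** 2).sum(axis=(-4, -3, -2)), 1e-300)

    def f(ss_e, df_e, ss_err, df_err):
        ss_e = np.where(ss_e < tol, 0.0, ss_e)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_e / df_e) / (ss_err / df_err)
        return np.where(ss_err < tol, np.where(ss_e > 0, np.inf, 0.0), F)

    F_A = f(ss_a, A - 1, ss_as, (A - 1) * (n - 1))
    F_B = f(ss_b, B - 1, ss_bs, (B - 1) * (n - 1))
    F_AB = f(ss_ab, (A - 1) * (B - 1), ss_abs, (A - 1) * (B - 1) * (n - 1))
    return F_A, F_B, F_AB


def group_anova_permutation(maps: np.ndarray, mask: np.ndarray,
                            voxel_index: np.ndarray,
                            tfce_params: TfceParams = TfceParams(),
                            n_perm: int = 1000, seed: int = 0,
                            batch: int = 64) -> dict:
    """2 (diet) x 3 (time) repeated-measures permutation ANOVA with TFCE FWE.

    maps: (n_subjects, 2, 3, n_vox); subjects with any NaN cell are dropped
    (with a warning).  Permutation schemes respect the exchangeability
    blocks: time labels permute within subject x diet cells; diet labels
    swap within subject; the interaction permutes time labels of
    double-centered data within subject x diet cells.
    """
    import warnings as _w
    maps = np.asarray(maps, dtype=float)
    good = ~np.isnan(maps).any(axis=(1, 2, 3))
    if not good.all():
        _w.warn(f"dropping {int((~good).sum())} subject(s) with missing cells")
        maps = maps[good]
    n = maps.shape[0]
    if n < 2:
        raise ValueError("group ANOVA needs at least 2 complete subjects")
    rng = np.random.default_rng(seed)
    FA, FB, FAB = _group_f_stats(maps)
    out = {}
    specs = {
        "diet": (FA, "diet"),
        "time": (FB, "time"),
        "interaction": (FAB, "interaction"),
    }
    box, lo = _mask_bbox(mask)
    sub_mask = mask[box]
    sub_vi = voxel_index - lo
    svi = tuple(sub_vi.T)
    for name, (f_obs, scheme) in specs.items():
        tf_obs = tfce_stack(_embed(_cap_inf(f_obs), sub_mask, sub_vi)[None],
                            tfce_params)[0][svi]
        null_max = np.empty(n_perm)
        for start in range(0, n_perm, batch):
            nb = min(batch, n_perm - start)
            yp = _permute_group(maps, scheme, nb, rng)
            FAp, FBp, FABp = _group_f_stats(yp)
            fp = {"diet": FAp, "time": FBp, "interaction": FABp}[name]
            tf = tfce_stack(_embed(_cap_inf(fp), sub_mask, sub_vi), tfce_params)
            null_max[start:start + nb] = _max_over_mask(tf, sub_mask)
        out[name] = {"stat": f_obs, "tfce": tf_obs,
                     "p_fwe": _corrected_p(tf_obs, null_max),
                     "null_max": null_max, "n_permutations": n_perm}
    return out


def _permute_group(y: np.ndarray, scheme: str, nb: int, rng) -> np.ndarray:
    """Batch of permuted copies of y (n, A, B, V) -> (nb, n, A, B, V)."""
    n, A, B, V = y.shape
    if scheme == "time":
        idx = rng.permuted(np.tile(np.arange(B), (nb, n, A, 1)), axis=-1)
        return np.take_along_axis(np.broadcast_to(y, (nb,) + y.shape),
                                  idx[..., None], axis=3)
    if scheme == "diet":
        swap = rng.integers(0, 2, size=(nb, n))
        idx = np.where(swap[..., None], np.array([1, 0]), np.array([0, 1]))
        return np.take_along_axis(np.broadcast_to(y, (nb,) + y.shape),
                                  idx[..., None, None], axis=2)
    if scheme == "interaction":
        # remove both main effects within subject, then permute time labels
        msa = y.mean(axis=2, keepdims=True)
        msb = y.mean(axis=1, keepdims=True)
        ms = y.mean(axis=(1, 2), keepdims=True)
        yc = y - msa - msb + ms
        idx = rng.permuted(np.tile(np.arange(B), (nb, n, A, 1)), axis=-1)
        return np.take_along_axis(np.broadcast_to(yc, (nb,) + yc.shape),
                                  idx[..., None], axis=3)
    raise ValueError(f"unknown permutation scheme {scheme!r}")
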