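"""End-to-end validation measurements on synthetic data.

Each function regenerates its inputs, runs the relevant pipeline stages and
returns summary numbers.  Used by the acceptance machinery and reusable for
benchmarking; problem sizes are scaled so a full battery runs on one CPU in
minutes (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .conditioning import condition_blocks
from .inference import (TfceParams, infer_single_subject, paired_t_stat,
                        permutation_fwe_f, rm_f_stat, tfce_transform)
from .mica import (ComponentSet, _cross_correlation, build_masked_matrix,
                   estimate_dimensionality, run_masked_ica)
from .qc import cnr, qc_report, tsnr
from .specificity import screen_components
from .synthetic import generate_study
from .types import VolumeGeometry


def _truth_component_set(dataset) -> ComponentSet:
    M = dataset.truth.component_maps
    Mz = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
    return ComponentSet(d=M.shape[0], spatial_maps=Mz, timecourses=None,
                        mask=dataset.mask, voxel_index=np.argwhere(dataset.mask))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# TFCE oracle

def tfce_bruteforce(vol: np.ndarray, params: TfceParams) -> np.ndarray:
    """Independent reference: per-voxel threshold sweep on the same grid."""
    out = np.zeros_like(vol, dtype=float)
    vmax = vol.max()
    if vmax <= 0:
        return out
    dh = vmax / params.n_steps
    st = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[params.connectivity])
    for i in range(1, params.n_steps + 1):
        h = i * dh
        sup = vol >= h
        labels, _ = ndimage.label(sup, structure=st)
        for p in map(tuple, np.argwhere(sup)):
            extent = (labels == labels[p]).sum()
            out[p] += extent ** params.E * h ** params.H * dh
    return out


def measure_tfce_oracle(seed: int = 0, n_maps: int = 20) -> dict:
    """Fast TFCE vs brute-force sweep on random 6x6x6 maps + closed form."""
    rng = np.random.default_rng(seed)
    params = TfceParams()
    max_diff = 0.0
    for _ in range(n_maps):
        vol = np.maximum(rng.normal(0, 1, (6, 6, 6)), 0)
        fast = tfce_transform(vol, None, params)
        slow = tfce_bruteforce(vol, params)
        max_diff = max(max_diff, float(np.abs(fast - slow).max()))
    # constant 8-voxel cluster at height v: TFCE -> n^E * v^(H+1) / (H+1)
    vol = np.zeros((8, 8, 8))
    vol[2:4, 2:4, 2:4] = 2.0
    got = tfce_transform(vol, None, TfceParams(n_steps=1000))[2, 2, 2]
    expect = 8 ** 0.5 * 2.0 ** 3 / 3
    return {"max_abs_diff": max_diff,
            "closed_form_rel_err": abs(got - expect) / expect,
            "n_maps": n_maps}


# ---------------------------------------------------------------------------
# ICA recovery and model order

def measure_ica_recovery(seed: int = 0, n_datasets: int = 10) -> dict:
    """Hungarian-matched mean |spatial correlation| of recovered vs planted
    maps (K=4 planted, 10 sessions x 3 blocks x 100 timepoints, SNR 1)."""
    scores = []
    for s in _spawn_seeds(seed, n_datasets):
        ds = generate_study(n_sessions=10, K=4, snr=1.0, seed=s)
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        mat = build_masked_matrix(blocks, ds.mask)
        comp = run_masked_ica(mat, 4, seed=s)
        c = _cross_correlation(comp.spatial_maps, ds.truth.component_maps)
        r, cix = linear_sum_assignment(-np.abs(c))
        scores.append(float(np.abs(c[r, cix]).mean()))
    return {"mean_matched_correlation": float(np.mean(scores)),
            "per_dataset": scores, "n": n_datasets}


def measure_dimensionality_selection(seed: int = 0, n_seeds: int = 10,
                                     d_range=range(1, 9),
                                     n_splits: int = 20) -> dict:
    """Fraction of simulated studies whose chosen model order lands in
    [K-1, K+2] around the planted K=4."""
    chosen = []
    for s in _spawn_seeds(seed, n_seeds):
        ds = generate_study(n_sessions=10, K=4, snr=1.0, seed=s)
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        curve = estimate_dimensionality(blocks, ds.mask, d_range,
                                        n_splits=n_splits, seed=s, ica_seed=s)
        chosen.append(int(curve.chosen_d))
    n_in = sum(3 <= c <= 6 for c in chosen)
    return {"chosen": chosen, "n_in_range": n_in, "n_seeds": n_seeds,
            "fraction_in_range": n_in / n_seeds}


# ---------------------------------------------------------------------------
# error rate / power

NULL_GEO = VolumeGeometry(shape=(9, 9, 8))
NULL_MASK_SPEC = {"kind": "box", "radii_vox": (2.0, 2.0, 1.5)}   # 5x5x4 box


def measure_null_fwe(seed: int = 0, n_reps: int = 200, n_perm: int = 500,
                     alpha: float = 0.05) -> dict:
    """Empirical FWE of the permutation F-test on null data (all amplitude
    multipliers equal): 4 sessions, 5x5x4 mask, 500 permutations."""
    rejects = 0
    for s in _spawn_seeds(seed, n_reps):
        ds = generate_study(n_sessions=4, K=2, geometry=NULL_GEO,
                            mask_shape_spec=NULL_MASK_SPEC, n_timepoints=60,
                            snr=1.0, seed=s)
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        comp = _truth_component_set(ds)
        from .inference import dual_regress_mask
        dr = dual_regress_mask(blocks, comp, ds.mask)
        res = permutation_fwe_f(dr.zmaps[:, :, 0, :], ds.mask, dr.voxel_index,
                                TfceParams(), n_perm=n_perm, seed=s)
        rejects += bool(res["p_fwe"].min() < alpha)
    return {"fwe_rate": rejects / n_reps, "n_rejections": rejects,
            "n_reps": n_reps, "alpha": alpha}


def measure_effect_detection(seed: int = 0, n_reps: int = 25,
                             lam_ratio: float = 1.8, n_perm: int = 500,
                             affected: int = 1) -> dict:
    """Full single-subject pipeline on data with a post45-only coupling
    increase: detection rate, contrast attribution, and support overlap."""
    from .inference import dual_regress_mask
    detected = 0
    post45_hits = 0
    post10_hits = 0
    dices = []
    for s in _spawn_seeds(seed, n_reps):
        ds = generate_study(n_sessions=10, K=4, snr=1.0,
                            effect_spec={affected: (1.0, 1.0, lam_ratio)},
                            seed=s)
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        mat = build_masked_matrix(blocks, ds.mask)
        comp = run_masked_ica(mat, 4, seed=s)
        dr = dual_regress_mask(blocks, comp, ds.mask)
        res = infer_single_subject(dr, TfceParams(), n_perm=n_perm, seed=s,
                                   posthoc="if_omnibus")
        sig_any = np.zeros(dr.zmaps.shape[-1], bool)
        rep_post45 = rep_post10 = False
        for ci in res.per_component:
            sig_any |= ci.f_sig_mask
            for pair, r in ci.contrasts.items():
                if r["sig_mask"].any():
                    if pair == ("baseline", "post45"):
                        rep_post45 = True
                    elif pair == ("baseline", "post10"):
                        rep_post10 = True
        if sig_any.any():
            detected += 1
            support = ds.truth.support_masks[affected]
            dices.append(2 * (sig_any & support).sum()
                         / (sig_any.sum() + support.sum()))
        post45_hits += rep_post45
        post10_hits += rep_post10
    return {"detection_rate": detected / n_reps,
            "n_detected": detected, "n_reps": n_reps,
            "post45_contrast_reps": post45_hits,
            "post10_contrast_reps": post10_hits,
            "mean_dice": float(np.mean(dices)) if dices else 0.0}


# ---------------------------------------------------------------------------
# specificity / QC

def measure_specificity_screen(seed: int = 0, n_sims: int = 10) -> dict:
    """Planted CSF artifact gets Q < 1, planted GM components get Q > 1."""
    gm_ok = artifact_ok = 0
    for s in _spawn_seeds(seed, n_sims):
        ds = generate_study(n_sessions=4, K=2, snr=1.0, csf_artifact=True,
                            n_timepoints=60, seed=s)
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        comp = _truth_component_set(ds)
        res = screen_components(blocks, comp, ds.mask, ds.priors)
        gm_ok += bool(np.all(res.quotients[:2] > 1))
        artifact_ok += bool(res.quotients[2] < 1)
    return {"gm_specific_sims": gm_ok, "csf_artifact_flagged_sims": artifact_ok,
            "n_sims": n_sims}


def measure_qc(seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    series = rng.normal(1000, 100, size=(200, 500))
    _, tsnr_summary = tsnr(series)
    # doubled fluctuations in the third block
    from .types import BlockDesign, BoldBlock
    geo = VolumeGeometry(shape=(4, 4, 3))
    mask = np.ones(geo.shape, bool)
    design = BlockDesign(n_timepoints_per_block=60, tr_seconds=1.18,
                         session_id="qc")
    base_data = rng.normal(100, 5, geo.shape + (60,))
    mean = base_data.mean(axis=-1, keepdims=True)
    doubled = 2 * (base_data - mean) + mean
    base = BoldBlock(data=base_data, geometry=geo, design=design,
                     block_label="baseline")
    p45 = BoldBlock(data=doubled, geometry=geo, design=design,
                    block_label="post45")
    _, cnr_summary = cnr(base, p45, mask)
    # between-block mean shifts deflate the pooled tSNR
    blocks = []
    for s in range(3):
        d2 = BlockDesign(n_timepoints_per_block=60, tr_seconds=1.18,
                         session_id=f"s{s}")
        for j, lab in enumerate(("baseline", "post10", "post45")):
            data = rng.normal(100, 5, geo.shape + (60,)) + 20 * j + 10 * s
            blocks.append(BoldBlock(data=data, geometry=geo, design=d2,
                                    block_label=lab))
    rep = qc_report(blocks, mask)
    return {"tsnr_normal_1000_100": tsnr_summary,
            "cnr_doubled_fluctuation": cnr_summary,
            "concatenated_tsnr": rep["concatenated_tsnr"],
            "mean_block_tsnr": rep["mean_block_tsnr"]}


def measure_stat_kernels() -> dict:
    t123 = float(paired_t_stat(np.array([[1.0], [2.0], [3.0]]),
                               np.zeros((3, 1)))[0])
    y = np.random.default_rng(0).normal(size=(6, 2, 50))
    F = rm_f_stat(y)
    t2 = paired_t_stat(y[:, 0, :], y[:, 1, :]) ** 2
    from .inference import bonferroni_components
    return {"paired_t_123": t123,
            "f_vs_t2_max_abs_diff": float(np.abs(F - t2).max()),
            "bonferroni_0001_28": float(bonferroni_components(0.001, 28)),
            "bonferroni_0002_43": float(bonferroni_components(0.002, 43))}


def measure_atlas_rule() -> dict:
    from .reporting import AtlasVolume, atlas_overlap
    labels = np.zeros((5, 5, 5), dtype=int)
    coords = [(i, j, 0) for i in range(5) for j in range(4)][:20]
    for p in coords:
        labels[p] = 1
    active = np.zeros((5, 5, 5), bool)
    active[coords[0]] = True
    rep = atlas_overlap(active, AtlasVolume(labels, {1: "r1"}))
    row = rep.iloc[0]
    rep0 = atlas_overlap(np.zeros((5, 5, 5), bool), AtlasVolume(labels, {1: "r1"}))
    return {"boundary_fraction": float(row.fraction),
            "boundary_reported": bool(row.reported),
            "zero_overlap_reported": bool(rep0.reported.any())}
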