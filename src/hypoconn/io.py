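"""NIfTI / TSV / JSON plumbing around the in-memory containers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BlockDesign, BoldBlock, StudyDataset, TissuePriors, VolumeGeometry


def save_volume(data: np.ndarray, geometry: VolumeGeometry, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), geometry.affine)
    img.header.set_zooms(tuple(geometry.voxel_size_mm) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_volume(path) -> tuple[np.ndarray, VolumeGeometry]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    zooms = img.header.get_zooms()[:3]
    geo = VolumeGeometry(shape=tuple(int(s) for s in img.shape[:3]),
                         voxel_size_mm=tuple(float(z) for z in zooms),
                         affine=np.asarray(img.affine))
    return data, geo


def save_study(dataset: StudyDataset, outdir) -> Path:
    """Write a StudyDataset as NIfTI volumes plus a TSV design table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geo = dataset.truth.geometry
    save_volume(dataset.mask.astype(np.float32), geo, outdir / "mask.nii.gz")
    for name in ("gm", "wm", "csf"):
        save_volume(getattr(dataset.priors, name), geo, outdir / f"{name}.nii.gz")
    rows = []
    for design in dataset.designs:
        for lab in design.block_labels:
            blk = dataset.blocks[(design.session_id, lab)]
            fname = f"{design.subject_id}_{design.session_id}_{lab}.nii.gz"
            save_volume(blk.data, geo, outdir / fname)
            rows.append({"subject": design.subject_id, "session": design.session_id,
                         "block": lab, "diet": design.diet or "",
                         "tr_seconds": design.tr_seconds,
                         "n_timepoints": design.n_timepoints_per_block,
                         "path": fname})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "design.tsv", sep="\t", index=False)
    # ground truth: component maps as 4D NIfTI + parameters as JSON
    K = dataset.truth.n_components
    vols = np.zeros(tuple(geo.shape) + (K,), dtype=np.float32)
    for k in range(K):
        vols[dataset.mask, k] = dataset.truth.component_maps[k]
    save_volume(vols, geo, outdir / "truth_components.nii.gz")
    with open(outdir / "truth.json", "w") as fh:
        json.dump({
            "amplitude_multipliers": dataset.truth.amplitude_multipliers.tolist(),
            "noise_sigma": dataset.truth.noise_sigma,
            "baseline_mean": dataset.truth.baseline_mean,
            "drift_spec": dataset.truth.drift_spec,
            "component_scales": dataset.truth.component_scales.tolist(),
        }, fh, indent=2)
    return outdir


def load_blocks(design_table, datadir, mask_path=None):
    """Read BOLD blocks listed in a design TSV; returns (blocks, mask or None)."""
    datadir = Path(datadir)
    table = pd.read_csv(design_table, sep="\t") \
        if not isinstance(design_table, pd.DataFrame) else design_table
    designs = {}
    blocks = []
    for (subject, session), grp in table.groupby(["subject", "session"], sort=False):
        first = grp.iloc[0]
        diet = first.get("diet", "") or None
        if isinstance(diet, float) and np.isnan(diet):
            diet = None
        design = BlockDesign(
            n_timepoints_per_block=int(first["n_timepoints"]),
            tr_seconds=float(first["tr_seconds"]),
            session_id=str(session), subject_id=str(subject), diet=diet)
        designs[(subject, session)] = design
        for _, row in grp.iterrows():
            data, geo = load_volume(datadir / row["path"])
            blocks.append(BoldBlock(data=data, geometry=geo, design=design,
                                    block_label=row["block"]))
    mask = None
    if mask_path is not None:
        mdata, _ = load_volume(mask_path)
        mask = mdata > 0.5
    return blocks, mask


def load_priors(gm_path, wm_path, csf_path) -> TissuePriors:
    gm, geo = load_volume(gm_path)
    wm, _ = load_volume(wm_path)
    csf, _ = load_volume(csf_path)
    return TissuePriors(gm=np.clip(gm, 0, 1), wm=np.clip(wm, 0, 1),
                        csf=np.clip(csf, 0, 1), geometry=geo)


def embed_in_volume(vec: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Place a mask-voxel vector (or stack of them) into full volume(s)."""
    mask = np.asarray(mask, dtype=bool)
    vec = np.asarray(vec)
    if vec.ndim == 1:
        vol = np.zeros(mask.shape, dtype=float)
        vol[mask] = vec
        return vol
    vols = np.zeros(vec.shape[:-1] + mask.shape, dtype=float)
    vols[..., mask] = vec
    return vols
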