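"""End-to-end orchestration: conditioning -> masked ICA -> specificity ->
dual regression -> permutation inference -> reporting/QC, with a manifest
recording every parameter and seed."""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .conditioning import ConditioningParams, condition_blocks
from .inference import (TfceParams, bonferroni_components, dual_regress_mask,
                        group_anova_permutation, infer_single_subject)
from .mica import (build_masked_matrix, estimate_dimensionality, run_masked_ica,
                   threshold_map_mixture)
from .qc import qc_report
from .reporting import AtlasVolume, atlas_overlap, netmat_cluster
from .specificity import filter_components, screen_components
from .types import StudyDataset


@dataclass
class PipelineConfig:
    mode: str = "single_subject"            # or "group"
    d: int | None = None                    # fixed ICA order; None -> estimate
    d_range: tuple = (1, 12)
    n_splits: int = 20
    grand_mean_target: float = 10000.0
    highpass_cutoff_hz: float = 0.01
    variance_normalize: bool = True
    tfce: TfceParams = field(default_factory=TfceParams)
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0
    posthoc: str = "if_omnibus"
    mixture_threshold: float = 0.5
    atlas_min_fraction: float = 0.05
    overlap_source: str = "significance"    # or "mixture"


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[stage {stage}] {err}")
        self.stage = stage


def run_pipeline(dataset: StudyDataset, config: PipelineConfig = PipelineConfig(),
                 atlas: AtlasVolume | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run all stages on an in-memory dataset; returns a result dict.

    When ``outdir`` is given, tables / maps / manifest are written there and
    the manifest is updated after every completed stage (a rerun can resume
    from the JSON state by inspecting which stages completed).
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": _config_dict(config),
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = {"manifest": manifest}
    mask = dataset.mask

    def _record(stage):
        manifest["stages"].append(stage)
        if out is not None:
            with open(out / "manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2, default=_json_default)

    def _run(stage, fn):
        try:
            value = fn()
        except Exception as err:   # annotate failures with the stage name
            manifest["failed_stage"] = stage
            manifest["error"] = "".join(traceback.format_exception_only(err)).strip()
            if out is not None:
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, default=_json_default)
            raise StageError(stage, err) from err
        _record(stage)
        return value

    # 1. conditioning
    params = ConditioningParams(grand_mean_target=config.grand_mean_target,
                                highpass_cutoff_hz=config.highpass_cutoff_hz)
    blocks = _run("conditioning",
                  lambda: condition_blocks(dataset.blocks_in_order(), mask, params))

    # 2. masked ICA (+ optional model-order estimation)
    def _mica():
        d = config.d
        curve = None
        if d is None:
            lo, hi = config.d_range
            curve = estimate_dimensionality(blocks, mask, range(lo, hi + 1),
                                            n_splits=config.n_splits,
                                            seed=config.seed,
                                            ica_seed=config.seed)
            d = curve.chosen_d
        matrix = build_masked_matrix(blocks, mask,
                                     variance_normalize=config.variance_normalize)
        comp = run_masked_ica(matrix, d, seed=config.seed)
        return comp, curve
    components, curve = _run("mica", _mica)
    result["reproducibility_curve"] = curve
    if out is not None and curve is not None:
        pd.DataFrame({"d": curve.dims, "score": curve.score}).to_csv(
            out / "reproducibility.tsv", sep="\t", index=False)

    # 3. specificity screen
    def _spec():
        res = screen_components(blocks, components, mask, dataset.priors)
        kept, report = filter_components(components, res)
        return res, kept, report
    spec_res, specific, removal = _run("specificity", _spec)
    result["specificity"] = spec_res
    result["removal_report"] = removal
    if out is not None:
        pd.DataFrame({"component": np.arange(components.d),
                      "quotient": spec_res.quotients,
                      "classification": spec_res.classifications}).to_csv(
            out / "specificity.tsv", sep="\t", index=False)

    # 4. dual regression to the mask
    drmaps = _run("dual_regression",
                  lambda: dual_regress_mask(blocks, specific, mask))
    result["drmaps"] = drmaps

    # 5. inference
    def _infer():
        if config.mode == "group":
            return _group_inference(drmaps, dataset, config)
        return infer_single_subject(drmaps, config.tfce, config.n_perm,
                                    seed=config.seed, alpha=config.alpha,
                                    posthoc=config.posthoc)
    inference = _run("inference", _infer)
    result["inference"] = inference

    # 6. reporting: mixture thresholding, atlas overlap, netmat
    def _report():
        rep = {"mixture": [], "overlap": {}, "netmat": None}
        for k in range(specific.d):
            rep["mixture"].append(threshold_map_mixture(
                specific.spatial_maps[k], config.mixture_threshold, component=k))
        if atlas is not None:
            for k in range(specific.d):
                if config.overlap_source == "mixture":
                    active = hio.embed_in_volume(
                        rep["mixture"][k].active.astype(float), mask) > 0.5
                else:
                    active = _significance_volume(inference, k, mask, config)
                rep["overlap"][k] = atlas_overlap(active, atlas,
                                                  config.atlas_min_fraction)
        if specific.d >= 2:
            rep["netmat"] = netmat_cluster(specific.timecourses)
        return rep
    report = _run("reporting", _report)
    result["report"] = report

    # 7. QC
    qc = _run("qc", lambda: qc_report(blocks, mask))
    result["qc"] = qc
    if out is not None:
        with open(out / "qc_summary.json", "w") as fh:
            json.dump(qc, fh, indent=2, default=_json_default)
        _write_summary(out, inference, config)
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["n_stages_completed"] = len(manifest["stages"])
    if out is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=_json_default)
    return result


def _significance_volume(inference, k, mask, config):
    if config.mode == "group":
        sig = inference["per_component"][k]["time"]["p_bonf"] < config.alpha
    else:
        sig = inference.per_component[k].f_sig_mask
    return hio.embed_in_volume(sig.astype(float), mask) > 0.5


def _group_inference(drmaps, dataset, config):
    """Assemble (subject, diet, time, voxel) arrays and run the 2x3 ANOVA."""
    from .types import DIETS
    designs = {d.session_id: d for d in dataset.designs}
    subjects = sorted({d.subject_id for d in dataset.designs})
    S, B, d, V = drmaps.zmaps.shape
    per_component = []
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(d)]
    for k in range(d):
        y = np.full((len(subjects), len(DIETS), B, V), np.nan)
        for i, ses in enumerate(drmaps.session_ids):
            des = designs[ses]
            si = subjects.index(des.subject_id)
            di = DIETS.index(des.diet)
            y[si, di] = drmaps.zmaps[i, :, k, :]
        res = group_anova_permutation(y, drmaps.mask, drmaps.voxel_index,
                                      config.tfce, config.n_perm, seed=seeds[k])
        for eff in res.values():
            eff["p_bonf"] = bonferroni_components(eff["p_fwe"], d)
        per_component.append(res)
    return {"per_component": per_component, "n_components": d,
            "alpha": config.alpha}


def _write_summary(out: Path, inference, config):
    rows = []
    if config.mode == "group":
        for k, res in enumerate(inference["per_component"]):
            for eff, r in res.items():
                rows.append({"component": k, "contrast": eff,
                             "min_p_fwe": float(np.min(r["p_fwe"])),
                             "min_p_bonf": float(np.min(r["p_bonf"])),
                             "n_sig": int((r["p_bonf"] < config.alpha).sum())})
    else:
        for ci in inference.per_component:
            rows.append({"component": ci.component, "contrast": "omnibus_F",
                         "min_p_fwe": float(np.min(ci.f_p_fwe)),
                         "min_p_bonf": float(np.min(ci.f_p_bonf)),
                         "n_sig": int(ci.f_sig_mask.sum())})
            for pair, r in ci.contrasts.items():
                rows.append({"component": ci.component,
                             "contrast": f"{pair[1]}_vs_{pair[0]}",
                             "min_p_fwe": float(np.min(r["p_fwe"])),
                             "min_p_bonf": float(np.min(r["p_bonf"])),
                             "n_sig": int(r["sig_mask"].sum())})
    pd.DataFrame(rows).to_csv(out / "inference_summary.tsv", sep="\t", index=False)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
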