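# hypoconn

Functional-connectivity mapping **inside small brain structures** from
block-design fMRI: masked spatial ICA with reproducibility-based model-order
selection, tissue-specificity screening, dual-regression connectivity per
measurement block, and nonparametric permutation inference with TFCE
family-wise error correction.

The motivating design is a glucose-challenge experiment on the hypothalamus:
each session records three ~9-minute BOLD blocks — at baseline, 10 minutes
and 45 minutes after ingestion of 75 g glucose — either as repeated sessions
in one subject (an n-of-1 trial) or once per diet condition in a group.  The
package answers: *which sub-regions of the structure change their intrinsic
coupling after the challenge, and at which time point?*

Because such datasets are rarely shareable, the package ships a first-class
synthetic-data module that generates template-aligned multi-session studies
with planted spatial components, tissue priors, slow drift and noise — so the
entire pipeline is testable end to end against known ground truth.

## Method

Given preprocessed, template-aligned 4D volumes `Y_sb` (session `s`, block
`b`) and a binary analysis mask:

1. **Conditioning** — grand mean scaling to 10 000 over the mask, then a
   0.01 Hz high-pass (regression on a discrete-cosine basis, voxel means
   restored).
2. **Masked ICA** — stack mask voxels × concatenated timepoints, whiten to
   `d` dimensions, and run a fixed-point ICA over *spatial* sources.  The
   model order `d` maximizes split-half reproducibility: sessions are split
   in half 20 times, ICA runs on each half, components are matched by the
   Hungarian algorithm on |spatial correlation|, and the mean matched
   correlation is the score (`d̂ = argmax`, ties to the smallest order).
3. **Specificity screen** — dual regression of each component to the whole
   volume; the weighted quotient
   `Q = mean_gm(|z|) / mean_wm+csf(|z|)` (probabilistic tissue weights)
   flags components with `Q < 1` as unspecific, and they are removed.
4. **Connectivity per block** — dual regression back to the mask gives one
   z-map per session × block × component (stage 1: spatial GLM for time
   courses; stage 2: voxelwise temporal GLM, coefficients scaled by their
   residual error).
5. **Inference** — per component, a repeated-measures F across the three
   blocks (sessions as blocking factor) with post-hoc paired t versus
   baseline; significance by permutation (condition relabeling within
   session / sign flipping) of TFCE-enhanced maps with the max-statistic
   FWE rule, then Bonferroni across components.  Group designs use a
   2 (diet) × 3 (time) repeated-measures permutation ANOVA with
   exchangeability-block-respecting schemes.
6. **Reporting & QC** — mixture-model thresholded component maps, atlas
   overlap (a region is reported when ≥ 5 % of its voxels fall inside the
   component), hierarchical netmat clustering of component time courses
   (average linkage on 1 − r), tSNR and CNR maps/summaries.

## Worked example

```python
from hypoconn import (generate_study, condition_blocks, build_masked_matrix,
                      run_masked_ica, dual_regress_mask, infer_single_subject)
from hypoconn.synthetic import generate_atlas

# 10-session n-of-1 study; component 2 couples 1.8x stronger 45 min post
ds = generate_study(n_sessions=10, K=4, snr=1.0,
                    effect_spec={2: (1.0, 1.0, 1.8)}, seed=0)
blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
comp = run_masked_ica(build_masked_matrix(blocks, ds.mask), d=4, seed=0)
dr = dual_regress_mask(blocks, comp, ds.mask)
res = infer_single_subject(dr, n_perm=500, seed=0)
for ci in res.per_component:
    if ci.f_sig_mask.any():
        print(f"component {ci.component}: {ci.f_sig_mask.sum()} significant "
              f"voxels (min corrected p = {ci.f_p_bonf.min():.4f})")
        for pair, r in ci.contrasts.items():
            print(f"  {pair[1]} vs {pair[0]}: {r['sig_mask'].sum()} voxels, "
              f"min p = {r['p_bonf'].min():.4f}")
```

Output:

```
component 2: 71 significant voxels (min corrected p = 0.0080)
  post45 vs baseline: 75 voxels, min p = 0.0319
  post10 vs baseline: 0 voxels, min p = 1.0000
```

The recovered component matching the planted one shows a significant omnibus
difference across the three blocks; the post-hoc contrasts attribute the
change to 45 minutes after ingestion (the 10-minute contrast is null), and
the significant voxels sit inside the planted support.  The same run is
available from the shell:

```bash
hypoconn run --n-sessions 10 --k 4 --d 4 --effect 2:1,1,1.8 \
             --nperm 500 --seed 0 --out results/demo
```

which writes `manifest.json`, `specificity.tsv`, `inference_summary.tsv` and
`qc_summary.json` under `results/demo/`.

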