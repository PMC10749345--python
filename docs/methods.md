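# Methods

## Scope and data model

The pipeline consumes preprocessed, template-aligned 4D BOLD volumes — one
per measurement block — together with a binary analysis mask, probabilistic
gray-matter / white-matter / CSF maps, and optionally an integer-labeled
atlas.  Motion correction, distortion correction, brain extraction and
template normalization are upstream concerns and out of scope.  Each session
consists of exactly three blocks in fixed order (baseline, 10 min and 45 min
after glucose ingestion); a study is either `single_subject` (repeated
sessions in one person) or `group` (each subject measured once per diet,
normocaloric and hypercaloric).

## Synthetic data generator

The generator emulates the study conditions the pipeline targets, at a scale
that keeps a full run in minutes:

* **Geometry** — 16×16×12 voxels of 2 mm (default); an ellipsoidal analysis
  mask of ≈ 176 voxels strictly inside a gray-matter-dominant core, with a
  white-matter shell and a CSF rim described by smooth radial profiles plus
  a small seeded perturbation.
* **Components** — K unit-norm Gaussian blobs (default K = 4, smoothness
  3 mm) centered on the centroids of a k-means parcellation of the mask, the
  way anatomical subnuclei tile a small structure.  Adjacent blobs overlap
  partially (pairwise |r| typically 0.1–0.4, rejected above 0.95).
* **Time courses** — independent unit-variance series per component and
  block, band-limited to 0.02–0.12 Hz (inside the analysis passband,
  above the 0.01 Hz high-pass).
* **Signal scale** — the per-component amplitude is set so the
  root-mean-square temporal sd over the component's support (voxels above
  half its peak) equals `snr × noise_sigma`; SNR 1 is the default test
  condition.
* **Effects** — a per-block amplitude multiplier per component; a coupling
  increase confined to the third block (e.g. `(1.0, 1.0, 1.8)`) raises the
  within-component signal relative to noise, which is precisely what
  dual-regression stage-2 z-maps measure.  λ-ratio 1.8 at SNR 1 is the
  default power condition.
* **Noise and drift** — i.i.d. Gaussian noise, sd modulated by total tissue
  probability (signal-free outside the mask); drift is a per-voxel linear +
  quadratic polynomial (amplitudes 2 and 1 × noise sd).  A polynomial is the
  classic scanner-drift model and lies in the high-pass stopband at any
  block length; at the scaled-down 118-s blocks a sub-cutoff *sinusoid*
  cannot be represented by the 0.01 Hz DCT basis (only 2 basis functions
  fit in the window) and would leak through the filter, so the sinusoid
  drift term is off by default and available via `drift_spec`.
* **Negative control** — `csf_artifact=True` appends a component whose mask
  footprint sits at the mask edge while its time course drives a 3×-stronger
  signal across the CSF rim outside the mask.
* **Baseline** — mean level 1000 × (0.1 + 0.9 × tissue probability), in
  arbitrary scanner units.

What the generator does **not** emulate: scanner physics, motion, spatially
correlated (smooth) noise, physiological (cardiac/respiratory) cycles,
session-to-session amplitude variability, or plasma glucose/insulin
dynamics.  Passing tests therefore demonstrate correctness of the estimators
under the stated generative law, not robustness to every artifact of real
acquisitions.

## Conditioning

Grand mean scaling divides each block by the mean over (mask voxels ×
timepoints) and multiplies by 10 000; the mask (not the whole volume) defines
the grand mean so the analysis region is comparable across sessions.  The
high-pass regresses each voxel's series on the orthonormal discrete-cosine
vectors with frequency below the cutoff (`floor(2·T·TR·cutoff)` of them) and
keeps residual + mean: deterministic, linear, edge-safe, and exactly
mean-preserving.  Blocks are separate acquisitions and are filtered
independently.

## Masked ICA

The data matrix is mask voxels × concatenated timepoints (design order),
voxelwise demeaned and variance-normalized.  After PCA whitening to order
`d` (voxels as samples), a symmetric fixed-point iteration maximizes
non-Gaussianity of the spatial sources.  Two numerical choices matter:

* **Contrast** — the default is the skewness contrast `G(s) = s³/3`.
  Spatial components of a small structure are one-sided (a blob is a heavy
  *positive* tail), and skewness is the matching non-Gaussianity measure;
  the symmetric tanh-family contrasts are available (`contrast=` "logcosh",
  "exp", "cube") but on this class of sources they converge poorly and tend
  toward a global-mean attractor.
* **Damped update** — each iterate is sign-aligned with its predecessor and
  relaxed halfway toward it before re-orthonormalization.  The undamped
  fixed-point map overshoots and cycles on noisy data; the damped map
  contracts (typically < 20 iterations to tol 1e-4).  Restarts (default 5)
  are scored by the negentropy objective and the best converged solution is
  returned; progressive damping (0.5 → 0.25 → 0.1) is tried before a restart
  is declared unconverged.

Maps are z-scaled over mask voxels with the scale folded into the time
courses, and signs fixed so each map's skewness is ≥ 0.  The span of the
returned time courses equals the top-`d` principal subspace by construction.

**Model-order selection** splits *sessions* (not timepoints, preserving
within-block autocorrelation) in half `n_splits = 20` times, runs ICA on
both halves at each candidate order, Hungarian-matches the half
decompositions on |spatial correlation| and averages the matched values;
`chosen_d` is the argmax, ties to the smallest order.  Half-runs that fail
to converge contribute their best-effort decomposition — instability at an
order is what the score is meant to penalize.  A caveat observed in
simulation: when all planted sources are strong, orders *below* the truth
are also highly reproducible (a 1-dimensional decomposition of stable data
is trivially stable), so the argmax can land slightly below K; the collapse
of the curve just past the true order is the sharper signature.  The
scaled-down default candidate range is 1–12 (1–100 at full scale).

## Specificity screen

Each component is dual-regressed to the whole volume (stage-2 run per block
and averaged).  "Activation" is |z| — anticorrelation with CSF signals
non-specificity as much as correlation.  The quotient is the ratio of
tissue-probability-weighted means,

    Q = [ Σ p_gm |z| / Σ p_gm ] / [ Σ (p_wm + p_csf) |z| / Σ (p_wm + p_csf) ],

scale-invariant by construction; `Q < 1` classifies the component as
unspecific and removes it before inference.

## Dual regression and inference

Stage 1 regresses each timepoint's masked pattern on all component maps
jointly, with a spatial intercept (exact for maps of any mean level).
Stage 2 regresses each target voxel's series on the variance-normalized
stage-1 time courses plus an intercept; the coefficient divided by its
standard error is the association statistic ("z-map").

The omnibus test per component is a one-way repeated-measures F (sessions
blocking, conditions fixed): `F = MS_cond / MS_cond×session`.  Post-hoc
paired t tests compare each post-glucose block against baseline (the
change-from-baseline family; the post10-vs-post45 pairing is available via
`pairs=ALL_PAIRS`).  Zero-variance voxels receive infinite sentinels,
replaced by the finite map maximum before TFCE and excluded from
max-statistic bookkeeping.

**TFCE** integrates `extent^E · height^H` over `n_steps = 100` equal
thresholds from 0 to the map maximum (E = 0.5, H = 2, 26-connectivity — the
standard recommended values).  For permutation nulls, all permuted maps are
enhanced *simultaneously*: the stack is labeled as one 4D array whose
structuring element has no connectivity along the stacking axis, and the
computation is confined to the mask bounding box (clusters cannot leave the
mask).  This one-label-call-per-threshold scheme is what makes hundreds of
permutations per second feasible on one CPU.

**Permutation schemes** — omnibus F: the three condition labels are permuted
within each session (6^S possibilities); paired t: per-session differences
are sign-flipped (2^S).  When the exhaustive count (minus the identity) is
within the requested budget, the full enumeration is used and flagged.
Corrected p = (1 + #{perm: max-TFCE ≥ observed}) / (n_perm + 1), so p is
never 0 and the smallest attainable exhaustive p is 1/2^S.  Two-sided t
tests run the positive and negative tails one-sided against their own
max-TFCE nulls and double the smaller corrected p (capped at 1).  Bonferroni
across components multiplies p by the number of retained components (capped
at 1).

**Group design** — a 2 (diet) × 3 (time) repeated-measures ANOVA per voxel,
each effect tested against its interaction with subjects.  Permutations
respect exchangeability blocks: time labels permute within subject × diet
cells; diet labels swap within subject; the interaction permutes time labels
of doubly-centered (both main effects removed within subject) data.
Subjects with missing cells are dropped listwise with a warning.

## QC metrics

tSNR = temporal mean / temporal sd (sample sd, n−1) per voxel; the scalar
summary is the mean over valid mask voxels (voxels with zero sd are flagged
and excluded).  CNR = sd(post45-block) / sd(baseline-block) per voxel, same
summary convention.  The block-metric comparison uses Welch's unequal-
variance two-sided t.  Concatenating blocks whose means differ inflates the
pooled sd, so concatenated tSNR is systematically below the mean per-block
tSNR — the direction of the published single-block versus concatenated
contrast.

## Reporting

Mixture-model thresholding fits null + positive-signal Gaussians by EM to
each z-scaled map and marks voxels with posterior signal probability > 0.5;
degenerate fits fall back to an empty active set with a warning flag.  Atlas
overlap reports every region with ≥ 5 % of its voxels inside the active map
(the significance mask by default, the mixture-thresholded map by option).
Netmats are full Pearson correlation matrices of component time courses,
clustered by average linkage on distance 1 − r (not 1 − |r|); constant time
courses are excluded with a warning.

## Problem sizes used in validation

The validation battery (`scripts/acceptance.py`, `tests/test_acceptance.py`)
runs at deliberately reduced scales chosen to finish in minutes on a single
CPU while keeping each measurement statistically meaningful: 20 random
6×6×6 maps for the TFCE oracle; 10 simulated studies (10 sessions × 3
blocks × 100 timepoints, ~176-voxel mask, K = 4, SNR 1) for component
recovery and for model-order selection (candidate orders 1–8, 20 splits);
200 null replicates at 4 sessions / 5×5×4 mask / 500 permutations for the
family-wise error rate; 25 replicates of the full pipeline at λ-ratio 1.8
for detection power; 10 simulations for the specificity screen.  Full-scale
parameters (472 timepoints at TR 1.18 s, orders 1–100) remain configurable
throughout.

## Known limitations

* ICA recovery is bounded by source overlap: strongly overlapping planted
  components violate spatial independence, and the weakest component of a
  hard configuration may be recovered at |r| ≈ 0.8 rather than ≈ 0.95.
* The reproducibility curve is flat below the true order for uniformly
  strong sources (see above), so `chosen_d` is best read together with the
  curve, not alone.
* The EM mixture threshold assumes a dominant null mode; on maps that are
  mostly signal it is conservative.
* Permutation p-values are exact only in the exhaustive regime; sampled
  permutations add Monte-Carlo noise of order 1/√n_perm.
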