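"""Synthetic block-design fMRI with planted spatial components.

Emulates the study layout this package targets: repeated three-block
sessions (baseline, 10 min and 45 min after glucose ingestion), a small
analysis mask inside a gray-matter core, smooth partially overlapping
spatial components with band-limited time courses, slow drift and Gaussian
noise.  A block-specific amplitude multiplier on a component's time course
plants a "coupling increase" — the quantity dual-regression stage-2 maps
measure — with known ground truth for recovery tests.

Defaults are scaled down (16x16x12 grid, ~150-voxel mask, 100 timepoints
per block) so a full pipeline run takes minutes; the full-scale acquisition
(472 timepoints at TR 1.18 s) is available by argument.
"""

from __future__ import annotations

import numpy as np

from .types import (
    BLOCK_LABELS,
    BlockDesign,
    BoldBlock,
    GroundTruth,
    StudyDataset,
    TissuePriors,
    VolumeGeometry,
)

DEFAULT_GEOMETRY = VolumeGeometry(shape=(16, 16, 12), voxel_size_mm=(2.0, 2.0, 2.0))
DEFAULT_MASK_SPEC = {"kind": "ellipsoid", "radii_vox": (3.6, 3.6, 2.8)}


def n_timepoints_for(block_duration_seconds: float, tr_seconds: float) -> int:
    """Number of volumes acquired in a block: floor(duration / TR)."""
    return int(np.floor(block_duration_seconds / tr_seconds))


def _normalized_radius(geometry, center_vox, radii_vox):
    """Ellipsoidal radius field: 1.0 on the mask boundary."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in geometry.shape],
                        indexing="ij")
    r2 = np.zeros(geometry.shape)
    for g, c, r in zip(grids, center_vox, radii_vox):
        r2 += ((g - c) / r) ** 2
    return np.sqrt(r2)


def generate_tissue_priors(geometry: VolumeGeometry = DEFAULT_GEOMETRY,
                           mask_shape_spec: dict | None = None,
                           seed: int = 0) -> tuple[TissuePriors, np.ndarray]:
    """Smooth tissue probability maps plus a binary analysis mask.

    The mask is an ellipsoid (or box) strictly inside the volume, embedded in
    a gray-matter-dominant core, with a white-matter shell and a CSF rim
    further out.  Deterministic given the seed.
    """
    spec = dict(DEFAULT_MASK_SPEC if mask_shape_spec is None else mask_shape_spec)
    rng = np.random.default_rng(seed)
    shape = geometry.shape
    center = spec.get("center_vox", tuple((n - 1) / 2.0 for n in shape))
    radii = spec.get("radii_vox", DEFAULT_MASK_SPEC["radii_vox"])

    for axis, name in enumerate("xyz"):
        lo = center[axis] - radii[axis]
        hi = center[axis] + radii[axis]
        if lo < 0.5 or hi > shape[axis] - 1.5:
            raise ValueError(
                f"mask region exceeds volume bounds along {name}: "
                f"[{lo:.1f}, {hi:.1f}] outside [0.5, {shape[axis] - 1.5}]"
            )

    r = _normalized_radius(geometry, center, radii)
    if spec.get("kind", "ellipsoid") == "box":
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        inside = np.ones(shape, dtype=bool)
        for g, c, rad in zip(grids, center, radii):
            inside &= np.abs(g - c) <= rad
        mask = inside
    else:
        mask = r <= 1.0
    if mask.sum() < 50:
        raise ValueError(f"mask has only {int(mask.sum())} voxels; need >= 50")

    # Radially structured tissue classes with a small smooth seeded perturbation.
    gm = 0.90 * np.exp(-((r / 1.5) ** 4))
    wm = 0.85 * np.exp(-(((r - 2.1) / 0.55) ** 2))
    csf = 0.85 * np.exp(-(((r - 3.1) / 0.65) ** 2))
    jitter = rng.normal(0.0, 1.0, size=shape)
    from scipy.ndimage import gaussian_filter
    jitter = gaussian_filter(jitter, sigma=2.0)
    jitter = 0.02 * jitter / max(np.abs(jitter).max(), 1e-12)
    gm = np.clip(gm + jitter, 0.0, 1.0)
    wm = np.clip(wm + jitter * 0.5, 0.0, 1.0)
    csf = np.clip(csf, 0.0, 1.0)
    total = gm + wm + csf
    over = total > 1.0
    for vol in (gm, wm, csf):
        vol[over] /= total[over]
    priors = TissuePriors(gm=gm, wm=wm, csf=csf, geometry=geometry)
    return priors, mask


def _pick_centers(mask_coords: np.ndarray, K: int, rng) -> np.ndarray:
    """Nuclei-like placement: centroids of a K-way k-means parcellation.

    Components tile the structure as adjacent compact parcels, the way
    anatomical subnuclei subdivide a small structure; a small seeded jitter
    keeps placements distinct across seeds.
    """
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=K, n_init=5,
                random_state=int(rng.integers(2 ** 31))).fit(mask_coords)
    jitter = rng.uniform(-0.5, 0.5, size=km.cluster_centers_.shape)
    return km.cluster_centers_ + jitter


def _edge_voxel(mask_coords: np.ndarray) -> np.ndarray:
    """The mask voxel farthest from the mask centroid (for edge artifacts)."""
    centroid = mask_coords.mean(axis=0)
    return mask_coords[np.argmax(np.linalg.norm(mask_coords - centroid, axis=1))]


def generate_ground_truth(mask: np.ndarray,
                          K: int = 4,
                          smoothness_mm: float = 3.0,
                          effect_spec: dict | None = None,
                          seed: int = 0,
                          geometry: VolumeGeometry = DEFAULT_GEOMETRY,
                          snr: float = 1.0,
                          noise_sigma: float = 1.0,
                          baseline_mean: float = 1000.0,
                          drift: bool = True,
                          csf_artifact: bool = False,
                          priors: TissuePriors | None = None) -> GroundTruth:
    """Plant K smooth overlapping unit-norm component maps inside the mask.

    ``effect_spec`` maps a component index to its per-block amplitude
    multipliers, e.g. ``{3: (1.0, 1.0, 1.8)}`` for a coupling increase
    confined to the 45-minute block.  ``snr`` sets each component's
    root-mean-square temporal signal sd over its support, in units of
    ``noise_sigma``.  ``csf_artifact`` appends one extra component whose
    signal sits mainly in the CSF rim outside the mask (negative control
    for the specificity screen).
    """
    mask = np.asarray(mask, dtype=bool)
    n_vox = int(mask.sum())
    if K > n_vox // 10:
        raise ValueError(f"K={K} too large for a {n_vox}-voxel mask (max {n_vox // 10})")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask).astype(float)
    sigma_vox = smoothness_mm / np.mean(geometry.voxel_size_mm)

    n_total = K + (1 if csf_artifact else 0)
    for attempt in range(20):
        centers = _pick_centers(coords, K, rng)
        if csf_artifact:  # the artifact footprint sits at the mask edge
            centers = np.vstack([centers, _edge_voxel(coords)])
        maps = np.empty((n_total, n_vox))
        for k in range(n_total):
            d2 = np.sum((coords - centers[k]) ** 2, axis=1)
            maps[k] = np.exp(-d2 / (2 * sigma_vox ** 2))
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        if n_total == 1:
            break
        c = np.corrcoef(maps)
        if np.abs(c[~np.eye(n_total, dtype=bool)]).max() < 0.95:
            break
    else:
        raise RuntimeError("could not place sufficiently distinct component maps")

    multipliers = np.ones((n_total, len(BLOCK_LABELS)))
    if effect_spec:
        for k, mult in effect_spec.items():
            if len(mult) != len(BLOCK_LABELS):
                raise ValueError("effect_spec needs one multiplier per block")
            multipliers[k] = np.asarray(mult, dtype=float)
    if np.any(multipliers <= 0):
        raise ValueError("amplitude multipliers must be positive")

    support = maps >= 0.5 * maps.max(axis=1, keepdims=True)
    # Scale so rms signal sd over the support equals snr * noise_sigma.
    scales = np.empty(n_total)
    for k in range(n_total):
        rms = np.sqrt(np.mean(maps[k, support[k]] ** 2))
        scales[k] = snr * max(noise_sigma, 1e-12) / max(rms, 1e-12)
    if noise_sigma == 0:
        scales[:] = 1.0

    artifact = None
    if csf_artifact:
        if priors is None:
            raise ValueError("csf_artifact requires tissue priors")
        # Outside-mask CSF footprint sharing the artifact's time course.
        outside = priors.csf * (~mask)
        outside = outside / max(np.abs(outside).max(), 1e-12)
        artifact = {
            "component_index": n_total - 1,
            "outside_map": outside,
            "outside_scale": 3.0 * snr * noise_sigma if noise_sigma > 0 else 3.0,
        }

    # Slow drift: low-order polynomial (the classic scanner-drift model, and
    # inside the high-pass stopband at any block length); an additional
    # sub-cutoff sinusoid can be switched on via sin_amplitude.
    drift_spec = {
        "enabled": bool(drift),
        "linear_amplitude": 2.0 * noise_sigma,
        "quadratic_amplitude": 1.0 * noise_sigma,
        "sin_amplitude": 0.0,
        "sin_freq_hz": 0.003,
    }
    return GroundTruth(
        component_maps=maps,
        component_timecourses={},
        amplitude_multipliers=multipliers,
        noise_sigma=float(noise_sigma),
        baseline_mean=float(baseline_mean),
        drift_spec=drift_spec,
        mask=mask,
        geometry=geometry,
        component_scales=scales,
        support_masks=support,
        csf_artifact=artifact,
    )


def _bandlimited_series(rng, T: int, tr: float, f_lo=0.02, f_hi=0.12) -> np.ndarray:
    """Unit-variance zero-mean series with power confined to [f_lo, f_hi] Hz."""
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    if keep.sum() < 2:  # short series: keep low bins above DC
        keep = np.zeros_like(freqs, dtype=bool)
        keep[1:max(2, T // 6) + 1] = True
    spec = np.zeros(len(freqs), dtype=complex)
    n_keep = int(keep.sum())
    spec[keep] = rng.normal(size=n_keep) + 1j * rng.normal(size=n_keep)
    x = np.fft.irfft(spec, n=T)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_session(truth: GroundTruth, design: BlockDesign,
                     priors: TissuePriors, seed: int) -> list[BoldBlock]:
    """Simulate the three BOLD blocks of one session.

    Within the mask, ``data(v,t) = mu(v) + sum_k lambda_kb c_k S_k(v) a_kb(t)
    + drift(v,t) + noise``; outside, tissue-modulated baseline and noise only
    (plus the CSF artifact's rim signal when planted).
    """
    if tuple(truth.geometry.shape) != tuple(priors.geometry.shape):
        raise ValueError("ground truth and tissue priors have mismatched geometry")
    rng = np.random.default_rng(seed)
    shape = truth.geometry.shape
    T = design.n_timepoints_per_block
    mask = truth.mask
    K = truth.n_components
    tissue = priors.gm + priors.wm + priors.csf
    mu = truth.baseline_mean * (0.1 + 0.9 * tissue)
    sigma_vox = truth.noise_sigma * (0.2 + 0.8 * tissue)

    # Per-voxel drift parameters are drawn once per session.
    ds = truth.drift_spec
    if ds.get("enabled"):
        lin_coeff = rng.normal(0, ds["linear_amplitude"], size=shape)
        quad_coeff = rng.normal(0, ds.get("quadratic_amplitude", 0.0), size=shape)
        sin_amp = rng.normal(0, ds["sin_amplitude"], size=shape) \
            if ds.get("sin_amplitude", 0.0) > 0 else None
        sin_phase = rng.uniform(0, 2 * np.pi, size=shape)
    tcs = np.empty((design.n_blocks, K, T))
    blocks = []
    for b, label in enumerate(design.block_labels):
        for k in range(K):
            tcs[b, k] = _bandlimited_series(rng, T, design.tr_seconds)
        data = np.empty(shape + (T,))
        data[:] = mu[..., None]
        lam = truth.amplitude_multipliers[:, b]
        sig = (truth.component_maps * (lam * truth.component_scales)[:, None]).T @ tcs[b]
        data[mask] += sig
        if truth.csf_artifact is not None:
            ai = truth.csf_artifact["component_index"]
            out = truth.csf_artifact["outside_map"] * truth.csf_artifact["outside_scale"]
            data += out[..., None] * tcs[b, ai][None, None, None, :]
        if ds.get("enabled"):
            t = np.arange(T) * design.tr_seconds
            tt = (t - t.mean()) / max(t[-1] - t[0], 1e-12)
            data += lin_coeff[..., None] * tt
            data += quad_coeff[..., None] * (tt ** 2 - np.mean(tt ** 2))
            if sin_amp is not None:
                data += sin_amp[..., None] * np.sin(
                    2 * np.pi * ds["sin_freq_hz"] * t + sin_phase[..., None])
        if truth.noise_sigma > 0:
            data += sigma_vox[..., None] * rng.standard_normal(shape + (T,))
        blocks.append(BoldBlock(data=data, geometry=truth.geometry,
                                design=design, block_label=label))
    truth.component_timecourses[design.session_id] = tcs
    return blocks


def generate_study(n_sessions: int = 10,
                   group_mode: bool = False,
                   n_subjects: int = 20,
                   K: int = 4,
                   geometry: VolumeGeometry = DEFAULT_GEOMETRY,
                   mask_shape_spec: dict | None = None,
                   n_timepoints: int = 100,
                   tr_seconds: float = 1.18,
                   effect_spec: dict | None = None,
                   snr: float = 1.0,
                   noise_sigma: float = 1.0,
                   smoothness_mm: float = 3.0,
                   drift: bool = True,
                   csf_artifact: bool = False,
                   seed: int = 0) -> StudyDataset:
    """Generate a full simulated study.

    Single-subject mode: ``n_sessions`` repeated glucose challenges on one
    subject (default 10).  Group mode: ``n_subjects`` each measured once per
    diet (normocaloric / hypercaloric), i.e. ``2 * n_subjects`` sessions.
    """
    if not group_mode and n_sessions < 2:
        raise ValueError("need at least 2 sessions (split-half reproducibility "
                         "is undefined otherwise)")
    if group_mode and n_subjects < 2:
        raise ValueError("group mode needs at least 2 subjects")
    ss = np.random.SeedSequence(seed)
    prior_seed, truth_seed, *rest = [int(s.generate_state(1)[0] % (2 ** 31))
                                     for s in ss.spawn(3)]
    priors, mask = generate_tissue_priors(geometry, mask_shape_spec, seed=prior_seed)
    truth = generate_ground_truth(mask, K=K, smoothness_mm=smoothness_mm,
                                  effect_spec=effect_spec, seed=truth_seed,
                                  geometry=geometry, snr=snr,
                                  noise_sigma=noise_sigma, drift=drift,
                                  csf_artifact=csf_artifact, priors=priors)
    designs = []
    if group_mode:
        from .types import DIETS
        for s in range(n_subjects):
            for diet in DIETS:
                designs.append(BlockDesign(
                    n_timepoints_per_block=n_timepoints, tr_seconds=tr_seconds,
                    session_id=f"sub-{s + 1:02d}_{diet}",
                    subject_id=f"sub-{s + 1:02d}", diet=diet))
    else:
        for s in range(n_sessions):
            designs.append(BlockDesign(
                n_timepoints_per_block=n_timepoints, tr_seconds=tr_seconds,
                session_id=f"ses-{s + 1:02d}", subject_id="sub-01"))
    session_ss = ss.spawn(len(designs))
    blocks = {}
    for d, sss in zip(designs, session_ss):
        sseed = int(sss.generate_state(1)[0] % (2 ** 31))
        for blk in generate_session(truth, d, priors, seed=sseed):
            blocks[(d.session_id, blk.block_label)] = blk
    return StudyDataset(blocks=blocks, designs=designs, truth=truth,
                        priors=priors, mask=mask)


def generate_atlas(mask: np.ndarray, n_regions: int = 8, seed: int = 0):
    """Partition the mask into labeled regions (a toy anatomical atlas).

    Voxels are assigned to the nearest of ``n_regions`` seeded centers;
    labels are 1..n_regions, 0 outside the mask.  Returns (labels volume,
    {label: name}).
    """
    mask = np.asarray(mask, dtype=bool)
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask).astype(float)
    if n_regions > len(coords):
        raise ValueError("more regions than mask voxels")
    centers = _pick_centers(coords, n_regions, rng)
    d = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    assign = np.argmin(d, axis=1) + 1
    labels = np.zeros(mask.shape, dtype=int)
    labels[mask] = assign
    names = {k: f"region-{k:02d}" for k in range(1, n_regions + 1)}
    return labels, names
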