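"""Masked spatial ICA with reproducibility-based model-order selection.

The decomposition is spatial: the data matrix is (mask voxels x concatenated
timepoints), sources are spatial maps over mask voxels, the mixing matrix
holds the associated time courses.  Model order is chosen by maximizing
split-half reproducibility: sessions are split in half, ICA is run on each
half, components are matched with the Hungarian algorithm on absolute
spatial correlation, and the mean matched |correlation| is the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .types import BoldBlock


@dataclass
class MaskedDataMatrix:
    """Mask-voxels x concatenated-timepoints matrix with its bookkeeping."""

    values: np.ndarray                       # (n_vox, n_cols)
    voxel_index: np.ndarray                  # (n_vox, 3) voxel coordinates
    segment_table: list                      # [(start, stop, session_id, block_label)]
    mask: np.ndarray = None                  # boolean volume
    normalization: dict = field(default_factory=dict)

    def segment_for_column(self, col: int) -> tuple[str, str]:
        for start, stop, ses, blk in self.segment_table:
            if start <= col < stop:
                return ses, blk
        raise IndexError(f"column {col} outside all segments")

    def columns_for(self, session_id: str, block_label: str | None = None):
        sel = []
        for start, stop, ses, blk in self.segment_table:
            if ses == session_id and (block_label is None or blk == block_label):
                sel.append((start, stop))
        return sel


@dataclass
class ComponentSet:
    """d spatial maps over mask voxels (z-scaled) plus their time courses."""

    d: int
    spatial_maps: np.ndarray        # (d, n_vox), zero mean / unit variance rows
    timecourses: np.ndarray         # (n_cols, d)
    mask: np.ndarray                # boolean volume
    voxel_index: np.ndarray
    seed: int | None = None
    convergence_info: dict = field(default_factory=dict)
    segment_table: list = field(default_factory=list)


@dataclass
class ReproducibilityCurve:
    dims: list
    score: np.ndarray
    n_splits: int
    chosen_d: int
    per_split_scores: np.ndarray = None  # (n_dims, n_splits)


@dataclass
class MixtureThresholdedMap:
    component: int
    posterior: np.ndarray
    active: np.ndarray
    params: dict
    converged: bool


def build_masked_matrix(blocks: list[BoldBlock], mask: np.ndarray,
                        demean: bool = True,
                        variance_normalize: bool = True) -> MaskedDataMatrix:
    """Stack mask-voxel time series of all blocks, columns in design order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty mask")
    geo = blocks[0].geometry
    for b in blocks:
        if not b.geometry.matches(geo):
            raise ValueError("blocks have mismatched geometry")
    voxel_index = np.argwhere(mask)
    parts, table, col = [], [], 0
    for b in blocks:
        seg = b.data[mask]                       # (n_vox, T)
        table.append((col, col + seg.shape[1], b.design.session_id, b.block_label))
        col += seg.shape[1]
        parts.append(seg)
    values = np.concatenate(parts, axis=1)
    if demean:
        values = values - values.mean(axis=1, keepdims=True)
    if variance_normalize:
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = values / sd
    return MaskedDataMatrix(values=values, voxel_index=voxel_index,
                            segment_table=table, mask=mask,
                            normalization={"demean": demean,
                                           "variance_normalize": variance_normalize})


# Fixed-point contrast functions: g(s), g'(s), and the Gaussian expectation
# E[G(nu)] used in the negentropy objective J = (E[G(s)] - E[G(nu)])^2.
def _g_skew(s):
    # G(s) = s^3/3: targets skewness, apt for one-sided (positively loaded)
    # spatial sources such as blob-like components
    return s ** 2, 2 * s, (lambda x: x ** 3 / 3), 0.0


def _g_logcosh(s):
    t = np.tanh(s)
    return t, 1 - t ** 2, (lambda x: np.log(np.cosh(x))), 0.3746


def _g_exp(s):
    e = np.exp(-s ** 2 / 2)
    return s * e, (1 - s ** 2) * e, (lambda x: -np.exp(-x ** 2 / 2)), -0.7071

def _g_cube(s):
    return s ** 3, 3 * s ** 2, (lambda x: x ** 4 / 4), 0.75


_CONTRASTS = {"skew": _g_skew, "logcosh": _g_logcosh, "exp": _g_exp,
              "cube": _g_cube}


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(W @ W.T)
    return vecs @ np.diag(1.0 / np.sqrt(np.maximum(vals, 1e-12))) @ vecs.T @ W


def _fastica_core(Z: np.ndarray, W0: np.ndarray, contrast: str,
                  tol: float, max_iter: int, damping: float = 0.5):
    """Damped symmetric fixed-point ICA on whitened data Z (d, n).

    Each iterate is sign-aligned with and relaxed toward the previous one
    (W <- decorrelate(mu * W_update + (1 - mu) * W)); the undamped update
    overshoots and cycles on noisy data, while the damped map contracts.
    Returns (W, n_iter, converged).
    """
    d, n = Z.shape
    gfun = _CONTRASTS[contrast]
    W = _sym_decorrelate(W0)
    for it in range(1, max_iter + 1):
        S = W @ Z
        g, gp, _, _ = gfun(S)
        W_new = (g @ Z.T) / n - gp.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        signs = np.sign(np.sum(W_new * W, axis=1))
        signs[signs == 0] = 1.0
        W_new *= signs[:, None]
        W_new = _sym_decorrelate(damping * W_new + (1 - damping) * W)
        lim = np.max(np.abs(np.abs(np.sum(W_new * W, axis=1)) - 1.0))
        W = W_new
        if lim < tol:
            return W, it, True
    return W, max_iter, False


def _negentropy(S: np.ndarray, contrast: str) -> float:
    _, _, G, EGnu = _CONTRASTS[contrast](np.zeros(1))
    return float((((G(S)).mean(axis=1) - EGnu) ** 2).sum())


def run_masked_ica(matrix: MaskedDataMatrix, d: int, seed: int = 0,
                   max_restarts: int = 5, tol: float = 1e-4,
                   max_iter: int = 500, contrast: str = "skew",
                   strict: bool = True) -> ComponentSet:
    """Spatial FastICA (negentropy fixed-point iteration) at order d.

    The default contrast targets skewness (G(s) = s^3/3), which is the
    appropriate non-Gaussianity measure for one-sided spatial sources;
    tanh-family contrasts ("logcosh", "exp") and kurtosis ("cube") are
    available via ``contrast``.  Maps are z-scaled over mask voxels with
    skewness >= 0 per map; the span of the returned time courses equals the
    top-d principal subspace.
    """
    X = matrix.values
    n_vox, n_cols = X.shape
    rank = min(n_vox, n_cols)
    if not 1 <= d <= rank:
        raise ValueError(f"d={d} outside achievable rank 1..{rank}")
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {list(_CONTRASTS)}")
    # PCA whitening over voxels-as-samples
    Xc = X - X.mean(axis=0)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    if sv[d - 1] <= 1e-10 * sv[0]:
        eff_rank = int(np.sum(sv > 1e-10 * sv[0]))
        raise ValueError(f"d={d} exceeds the achievable rank {eff_rank}")
    Z = U[:, :d].T * np.sqrt(n_vox)               # (d, n_vox), whitened

    rng = np.random.default_rng(seed)
    best = None
    fallback = None
    n_conv = 0
    for r in range(max_restarts):
        W0 = rng.standard_normal((d, d))
        for damping in (0.5, 0.25, 0.1):   # progressively stronger damping
            W, n_iter, converged = _fastica_core(Z, W0, contrast, tol,
                                                 max_iter, damping)
            if converged:
                break
        n_conv += converged
        J = _negentropy(W @ Z, contrast)
        if converged and (best is None or J > best[0]):
            best = (J, W, n_iter)
        if fallback is None or J > fallback[0]:
            fallback = (J, W, n_iter)
    if best is None:
        if strict:
            raise RuntimeError(
                f"masked ICA did not converge in any of {max_restarts} restarts "
                f"(tol={tol}, max_iter={max_iter}, contrast={contrast!r})")
        best = fallback
    _, W, n_iter = best

    maps = W @ Z                                  # (d, n_vox)
    # time courses from the rank-d reconstruction: Xc ~ maps.T @ tcs.T
    tcs = (W @ (np.diag(sv[:d] / np.sqrt(n_vox)) @ Vt[:d])).T  # (n_cols, d)
    # z-scale maps; fold the scale into the time courses; fix sign by skewness.
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = (maps - mu) / sd
    tcs = tcs * sd.T
    sk = stats.skew(maps, axis=1)
    flip = np.where(sk < 0, -1.0, 1.0)
    maps *= flip[:, None]
    tcs *= flip[None, :]
    return ComponentSet(d=d, spatial_maps=maps, timecourses=tcs,
                        mask=matrix.mask, voxel_index=matrix.voxel_index, seed=seed,
                        convergence_info={"n_iter": int(n_iter),
                                          "n_converged_restarts": int(n_conv),
                                          "tol": tol, "contrast": contrast},
                        segment_table=matrix.segment_table)


def match_components(A: ComponentSet, B: ComponentSet):
    """Hungarian matching of two component sets on |spatial correlation|.

    Returns (pairing, mean matched |correlation|) where pairing[i] = j matches
    A's component i with B's component j.
    """
    if A.d != B.d:
        raise ValueError(f"component sets have different orders ({A.d} vs {B.d})")
    corr = _cross_correlation(A.spatial_maps, B.spatial_maps)
    row, col = linear_sum_assignment(-np.abs(corr))
    pairing = np.empty(A.d, dtype=int)
    pairing[row] = col
    score = float(np.abs(corr[row, col]).mean())
    return pairing, score


def _cross_correlation(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    a = M1 - M1.mean(axis=1, keepdims=True)
    b = M2 - M2.mean(axis=1, keepdims=True)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return a @ b.T


def estimate_dimensionality(blocks: list[BoldBlock], mask: np.ndarray,
                            d_range=range(1, 13), n_splits: int = 20,
                            seed: int = 0, ica_seed: int = 0,
                            max_restarts: int = 5) -> ReproducibilityCurve:
    """Choose the ICA model order by split-half test-retest reproducibility.

    Sessions (not timepoints) are split in half ``n_splits`` times; for each
    candidate order the mean Hungarian-matched |spatial correlation| between
    the two half decompositions is recorded.  Ties in the argmax go to the
    smallest order.  Half-runs that fail to converge contribute their
    best-effort decomposition: instability at an order is exactly what the
    reproducibility score is meant to penalize.
    """
    sessions = []
    for b in blocks:
        if b.design.session_id not in sessions:
            sessions.append(b.design.session_id)
    if len(sessions) < 2:
        raise ValueError("split-half reproducibility needs at least 2 sessions")
    rng = np.random.default_rng(seed)
    dims = list(d_range)
    scores = np.full((len(dims), n_splits), np.nan)
    by_session = {s: [b for b in blocks if b.design.session_id == s]
                  for s in sessions}
    half = len(sessions) // 2
    for j in range(n_splits):
        perm = rng.permutation(len(sessions))
        half_a = [sessions[i] for i in perm[:half]]
        half_b = [sessions[i] for i in perm[half:]]
        mat_a = build_masked_matrix(sum((by_session[s] for s in half_a), []), mask)
        mat_b = build_masked_matrix(sum((by_session[s] for s in half_b), []), mask)
        for i, d in enumerate(dims):
            A = run_masked_ica(mat_a, d, seed=ica_seed + 7919 * j,
                               max_restarts=max_restarts, strict=False)
            B = run_masked_ica(mat_b, d, seed=ica_seed + 7919 * j + 1,
                               max_restarts=max_restarts, strict=False)
            _, scores[i, j] = match_components(A, B)
    mean_scores = scores.mean(axis=1)
    chosen = dims[int(np.argmax(mean_scores))]   # argmax takes first (smallest d) on ties
    return ReproducibilityCurve(dims=dims, score=mean_scores, n_splits=n_splits,
                                chosen_d=chosen, per_split_scores=scores)


def threshold_map_mixture(spatial_map: np.ndarray, threshold: float = 0.5,
                          component: int = 0, max_iter: int = 500,
                          tol: float = 1e-8) -> MixtureThresholdedMap:
    """Two-class Gaussian mixture (null + positive signal) fitted by EM.

    Returns the per-voxel posterior probability of belonging to the signal
    class and the binary active map at ``posterior > threshold``.  If EM
    degenerates the null-only model is kept (empty active set, flagged).
    """
    x = np.asarray(spatial_map, dtype=float).ravel()
    n = x.size
    if n < 50:
        raise ValueError("mixture fit needs a map over at least 50 voxels")
    if x.std() < 1e-12:
        return MixtureThresholdedMap(component, np.zeros(n), np.zeros(n, bool),
                                     {"degenerate": "constant map"}, False)
    # init: null ~ bulk, signal ~ upper tail
    mu0, s0, w1 = 0.0, 1.0, 0.05
    hi = np.quantile(x, 0.95)
    mu1 = max(float(x[x >= hi].mean()), mu0 + 1.0)
    s1 = max(float(x[x >= hi].std()), 0.5)
    ll_old = -np.inf
    ok = False
    for _ in range(max_iter):
        p0 = (1 - w1) * stats.norm.pdf(x, mu0, s0)
        p1 = w1 * stats.norm.pdf(x, mu1, s1)
        tot = p0 + p1
        tot[tot == 0] = 1e-300
        r1 = p1 / tot
        w1 = float(np.clip(r1.mean(), 1e-4, 0.5))
        n1 = r1.sum()
        n0 = n - n1
        mu0 = float((x * (1 - r1)).sum() / max(n0, 1e-9))
        s0 = float(np.sqrt(((x - mu0) ** 2 * (1 - r1)).sum() / max(n0, 1e-9)))
        mu1 = float((x * r1).sum() / max(n1, 1e-9))
        s1 = float(np.sqrt(((x - mu1) ** 2 * r1).sum() / max(n1, 1e-9)))
        s0 = max(s0, 1e-3)
        s1 = max(s1, 1e-3)
        mu1 = max(mu1, mu0 + 0.5 * s0)   # keep the signal class in the upper tail
        ll = float(np.log(tot).sum())
        if abs(ll - ll_old) < tol * abs(ll_old or 1.0):
            ok = True
            break
        ll_old = ll
    if not ok and not np.isfinite(ll):
        return MixtureThresholdedMap(component, np.zeros(n), np.zeros(n, bool),
                                     {"degenerate": "EM failed"}, False)
    posterior = r1
    active = posterior > threshold
    params = {"null_mean": mu0, "null_sd": s0, "signal_mean": mu1,
              "signal_sd": s1, "signal_weight": w1}
    return MixtureThresholdedMap(component, posterior, active, params, True)
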