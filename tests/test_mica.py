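"""Masked ICA, Hungarian matching, model-order selection, mixture thresholding."""

import itertools

import numpy as np
import pytest

from hypoconn.mica import (ComponentSet, build_masked_matrix,
                           estimate_dimensionality, match_components,
                           run_masked_ica, threshold_map_mixture,
                           _cross_correlation)
from hypoconn.synthetic import generate_session, generate_study, generate_tissue_priors, \
    generate_ground_truth
from hypoconn.types import BlockDesign, BoldBlock, VolumeGeometry
from scipy.optimize import linear_sum_assignment


def _component_set(maps):
    return ComponentSet(d=maps.shape[0], spatial_maps=maps, timecourses=None,
                        mask=None, voxel_index=None)


class TestBuildMatrix:
    def test_shape_and_normalization(self, small_study):
        blocks = small_study.blocks_in_order()
        mat = build_masked_matrix(blocks, small_study.mask)
        n_vox = int(small_study.mask.sum())
        assert mat.values.shape == (n_vox, 9 * 60)
        assert np.allclose(mat.values.std(axis=1), 1.0, atol=1e-6)

    def test_segment_table_round_trip(self, small_study):
        blocks = small_study.blocks_in_order()
        mat = build_masked_matrix(blocks, small_study.mask)
        # 60-timepoint blocks, session-major: column 250 is in block 4 (0-based
        # segment 4), i.e. session 2, block post10
        ses, blk = mat.segment_for_column(250)
        assert ses == small_study.designs[1].session_id
        assert blk == "post10"

    def test_empty_mask_rejected(self, small_study):
        with pytest.raises(ValueError, match="empty mask"):
            build_masked_matrix(small_study.blocks_in_order(),
                                np.zeros_like(small_study.mask))


class TestRunMaskedIca:
    def test_rank_one_identifiability(self):
        priors, mask = generate_tissue_priors(seed=1)
        truth = generate_ground_truth(mask, K=1, seed=2, noise_sigma=0.0,
                                      drift=False)
        design = BlockDesign(n_timepoints_per_block=60, tr_seconds=1.18,
                             session_id="s1")
        blocks = generate_session(truth, design, priors, seed=3)
        mat = build_masked_matrix(blocks, mask, variance_normalize=False)
        comp = run_masked_ica(mat, d=1, seed=0)
        r = np.corrcoef(comp.spatial_maps[0], truth.component_maps[0])[0, 1]
        assert abs(r) > 1 - 1e-6

    def test_deterministic(self, small_study):
        mat = build_masked_matrix(small_study.blocks_in_order(), small_study.mask)
        a = run_masked_ica(mat, d=2, seed=9)
        b = run_masked_ica(mat, d=2, seed=9)
        assert np.array_equal(a.spatial_maps, b.spatial_maps)
        assert np.array_equal(a.timecourses, b.timecourses)

    def test_maps_z_scaled_and_skew_positive(self, small_study):
        mat = build_masked_matrix(small_study.blocks_in_order(), small_study.mask)
        comp = run_masked_ica(mat, d=2, seed=0)
        assert np.allclose(comp.spatial_maps.mean(axis=1), 0, atol=1e-8)
        assert np.allclose(comp.spatial_maps.std(axis=1), 1, atol=1e-8)
        from scipy.stats import skew
        assert np.all(skew(comp.spatial_maps, axis=1) >= 0)

    def test_subspace_matches_top_principal_subspace(self, small_study):
        mat = build_masked_matrix(small_study.blocks_in_order(), small_study.mask)
        d = 3
        comp = run_masked_ica(mat, d=d, seed=0)
        Xc = mat.values - mat.values.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        # principal angles between span(timecourses) and top-d right-singular span
        Qa, _ = np.linalg.qr(comp.timecourses)
        Qb, _ = np.linalg.qr(Vt[:d].T)
        angles = np.arccos(np.clip(np.linalg.svd(Qa.T @ Qb, compute_uv=False), -1, 1))
        assert angles.max() < 1e-3

    def test_rank_violation_rejected(self, small_study):
        mat = build_masked_matrix(small_study.blocks_in_order(), small_study.mask)
        with pytest.raises(ValueError, match="rank"):
            run_masked_ica(mat, d=10 ** 6)


class TestMatchComponents:
    def test_self_match_identity(self, small_study):
        mat = build_masked_matrix(small_study.blocks_in_order(), small_study.mask)
        comp = run_masked_ica(mat, d=2, seed=0)
        pairing, score = match_components(comp, comp)
        assert list(pairing) == [0, 1]
        assert score == pytest.approx(1.0)

    def test_permutation_and_sign_invariance(self):
        rng = np.random.default_rng(0)
        maps = rng.normal(size=(3, 150))
        perm = [2, 0, 1]
        flipped = maps[perm] * np.array([-1, 1, -1])[:, None]
        pairing, score = match_components(_component_set(maps),
                                          _component_set(flipped))
        assert score == pytest.approx(1.0)
        assert [perm[j] for j in pairing] == [0, 1, 2] or \
            [pairing[p] for p in range(3)] == [perm.index(i) for i in range(3)]

    def test_matches_brute_force_assignment(self):
        rng = np.random.default_rng(1)
        A = _component_set(rng.normal(size=(3, 150)))
        B = _component_set(rng.normal(size=(3, 150)))
        _, score = match_components(A, B)
        corr = np.abs(_cross_correlation(A.spatial_maps, B.spatial_maps))
        best = max(np.mean([corr[i, p[i]] for i in range(3)])
                   for p in itertools.permutations(range(3)))
        assert score == pytest.approx(best)

    def test_unequal_order_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="different orders"):
            match_components(_component_set(rng.normal(size=(2, 100))),
                             _component_set(rng.normal(size=(3, 100))))


class TestDimensionality:
    def test_identical_halves_score_one(self):
        # two sessions with byte-identical data: every split pairs identical
        # halves, so matched correlation is 1 at every achievable order
        ds = generate_study(n_sessions=2, K=2, n_timepoints=40, seed=4,
                            geometry=VolumeGeometry(shape=(12, 12, 10)),
                            mask_shape_spec={"radii_vox": (3.2, 3.2, 2.4)})
        blocks = ds.blocks_in_order()
        twin = []
        for b in blocks[:3]:
            twin.append(b)
        for b in blocks[:3]:
            d2 = BlockDesign(n_timepoints_per_block=b.design.n_timepoints_per_block,
                             tr_seconds=b.design.tr_seconds, session_id="twin")
            twin.append(BoldBlock(data=b.data.copy(), geometry=b.geometry,
                                  design=d2, block_label=b.block_label))
        curve = estimate_dimensionality(twin, ds.mask, d_range=range(1, 4),
                                        n_splits=3, seed=0)
        assert np.all(curve.score > 0.999)

    def test_curve_collapses_beyond_true_order(self):
        """With K=2 planted sources the curve stays high up to d=2 and drops
        sharply beyond: every order up to the truth is reproducible, orders
        above it are dominated by unmatched noise components."""
        for seed in range(3):
            # compact blobs (small smoothness) so the two sources barely overlap
            ds = generate_study(n_sessions=6, K=2, snr=2.5, n_timepoints=80,
                                smoothness_mm=2.0, seed=100 + seed)
            from hypoconn.conditioning import condition_blocks
            blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
            curve = estimate_dimensionality(blocks, ds.mask, d_range=range(1, 7),
                                            n_splits=8, seed=seed)
            assert np.all(curve.score[:2] > 0.9)
            assert np.all(curve.score[2:] < 0.8)
            assert curve.chosen_d in (1, 2)

    def test_single_session_rejected(self, small_study):
        one = [b for b in small_study.blocks_in_order()
               if b.design.session_id == small_study.designs[0].session_id]
        with pytest.raises(ValueError, match="2 sessions"):
            estimate_dimensionality(one, small_study.mask, d_range=range(1, 3))


class TestMixtureThreshold:
    def test_null_map_mostly_inactive(self):
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(20):
            res = threshold_map_mixture(rng.standard_normal(400))
            fracs.append(res.active.mean())
        assert np.mean(fracs) <= 0.05

    def test_bimodal_map_separated(self):
        rng = np.random.default_rng(1)
        hits = np.zeros(2)
        labels = np.r_[np.zeros(360, bool), np.ones(40, bool)]
        x = np.r_[rng.normal(0, 1, 360), rng.normal(6, 1, 40)]
        res = threshold_map_mixture(x)
        assert res.active[labels].mean() >= 0.95
        assert res.active[~labels].mean() <= 0.05

    def test_constant_map_degenerate(self):
        res = threshold_map_mixture(np.zeros(100))
        assert not res.converged
        assert not res.active.any()
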