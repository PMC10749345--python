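"""Dual regression stages and the gray-matter specificity quotient."""

import numpy as np
import pytest

from hypoconn.dualreg import dual_regress_block, stage1_timecourses, stage2_zmaps
from hypoconn.mica import ComponentSet
from hypoconn.specificity import (dual_regress_wholebrain, filter_components,
                                  screen_components, specificity_quotient)
from hypoconn.synthetic import (generate_ground_truth, generate_session,
                                generate_study, generate_tissue_priors)
from hypoconn.types import BlockDesign, TissuePriors, VolumeGeometry
from conftest import truth_component_set


class TestStage1:
    def test_orthonormal_maps_reduce_to_projection(self, small_study):
        blk = small_study.blocks_in_order()[0]
        mask = small_study.mask
        n_vox = int(mask.sum())
        rng = np.random.default_rng(0)
        A = rng.normal(size=(n_vox, 2))
        A -= A.mean(axis=0)                    # orthogonal to the intercept
        Q, _ = np.linalg.qr(A)
        comp = ComponentSet(d=2, spatial_maps=Q.T, timecourses=None,
                            mask=mask, voxel_index=np.argwhere(mask))
        tcs = stage1_timecourses(blk, comp, mask)
        proj = Q.T @ blk.data[mask]            # simple inner products
        assert np.allclose(tcs.T, proj, atol=1e-6)

    def test_noiseless_timecourse_recovery(self):
        priors, mask = generate_tissue_priors(seed=1)
        truth = generate_ground_truth(mask, K=2, seed=2, noise_sigma=0.0,
                                      drift=False)
        design = BlockDesign(n_timepoints_per_block=60, tr_seconds=1.18,
                             session_id="s1")
        blocks = generate_session(truth, design, priors, seed=3)
        comp = ComponentSet(d=2, spatial_maps=truth.component_maps,
                            timecourses=None, mask=mask,
                            voxel_index=np.argwhere(mask))
        tcs = stage1_timecourses(blocks[0], comp, mask)
        planted = truth.component_timecourses["s1"][0]
        for k in range(2):
            r = np.corrcoef(tcs[:, k], planted[k])[0, 1]
            assert abs(r) >= 0.99

    def test_collinear_maps_rejected(self, small_study):
        mask = small_study.mask
        n_vox = int(mask.sum())
        m = np.random.default_rng(0).normal(size=n_vox)
        comp = ComponentSet(d=2, spatial_maps=np.stack([m, m * 1.000001]),
                            timecourses=None, mask=mask,
                            voxel_index=np.argwhere(mask))
        with pytest.raises(ValueError, match="collinear"):
            stage1_timecourses(small_study.blocks_in_order()[0], comp, mask)


class TestStage2:
    def test_null_voxel_z_is_small(self, small_study):
        # voxels independent of the components rarely exceed |z| = 3.1
        comp = truth_component_set(small_study)
        zs = []
        for blk in small_study.blocks_in_order():
            rng = np.random.default_rng(hash(blk.block_label) % 1000)
            noise = rng.normal(0, 1, (500, blk.n_timepoints))
            tcs = stage1_timecourses(blk, comp, small_study.mask)
            zs.append(stage2_zmaps(noise, tcs))
        z = np.concatenate(zs, axis=1)
        assert (np.abs(z) < 3.1).mean() >= 0.99


class TestQuotient:
    def _priors(self, gm, wm, csf):
        geo = VolumeGeometry(shape=np.shape(gm))
        return TissuePriors(gm=np.asarray(gm, float), wm=np.asarray(wm, float),
                            csf=np.asarray(csf, float), geometry=geo)

    def test_uniform_activation_gives_unity(self):
        rng = np.random.default_rng(0)
        priors, _ = generate_tissue_priors(seed=0)
        z = np.full(priors.geometry.shape, 2.5)
        assert specificity_quotient(z, priors) == pytest.approx(1.0)

    def test_three_voxel_hand_example(self):
        gm = np.array([[[1.0, 0.0, 0.0]]])
        wmcsf = np.array([[[0.0, 1.0, 1.0]]])
        priors = self._priors(gm, wmcsf * 0.5, wmcsf * 0.5)
        z = np.array([[[2.0, 4.0, 0.0]]])
        # (2/1) / ((4+0)/2) = 1.0 exactly
        assert specificity_quotient(z, priors) == 1.0

    def test_gm_only_mass_is_specific(self):
        gm = np.array([[[1.0, 0.0, 0.0]]])
        priors = self._priors(gm, 1 - gm, np.zeros_like(gm))
        z = np.array([[[5.0, 0.0, 0.0]]])
        assert specificity_quotient(z, priors) > 1

    def test_scale_invariance(self):
        priors, _ = generate_tissue_priors(seed=0)
        rng = np.random.default_rng(1)
        z = rng.normal(size=priors.geometry.shape)
        q1 = specificity_quotient(z, priors)
        q2 = specificity_quotient(z * 7.3, priors)
        assert q1 == pytest.approx(q2)


class TestScreening:
    def test_planted_artifact_removed_gm_kept(self):
        ds = generate_study(n_sessions=3, K=2, snr=1.0, csf_artifact=True,
                            n_timepoints=60, seed=5)
        from hypoconn.conditioning import condition_blocks
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        comp = truth_component_set(ds)
        res = screen_components(blocks, comp, ds.mask, ds.priors)
        assert res.classifications[:2] == ["specific", "specific"]
        assert res.classifications[2] == "unspecific"
        kept, report = filter_components(comp, res)
        assert kept.d == 2
        assert report["removed_indices"] == [2]

    def test_no_removal_when_all_specific(self, small_study):
        comp = truth_component_set(small_study)
        res = screen_components(small_study.blocks_in_order(), comp,
                                small_study.mask, small_study.priors)
        kept, report = filter_components(comp, res)
        assert kept.d == comp.d
        assert report["removed_indices"] == []

    def test_removal_counts_match_quotient_rule(self):
        # d components with known quotients: those below one are dropped
        from hypoconn.specificity import SpecificityResult
        rng = np.random.default_rng(0)
        d = 31
        maps = rng.normal(size=(d, 80))
        comp = ComponentSet(d=d, spatial_maps=maps,
                            timecourses=rng.normal(size=(200, d)),
                            mask=None, voxel_index=None)
        q = np.ones(d) * 1.5
        q[[4, 11, 27]] = 0.4
        res = SpecificityResult(quotients=q,
                                classifications=["unspecific" if x < 1 else "specific"
                                                 for x in q],
                                zmaps=None)
        kept, report = filter_components(comp, res)
        assert kept.d == 28
        assert report["removed_indices"] == [4, 11, 27]
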