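"""Statistic kernels, TFCE, and permutation FWE machinery."""

import numpy as np
import pytest
from scipy import ndimage

from hypoconn.inference import (TfceParams, bonferroni_components,
                                group_anova_permutation, paired_t_stat,
                                permutation_fwe_f, permutation_fwe_paired_t,
                                rm_f_stat, tfce_stack, tfce_transform)


def tfce_bruteforce(vol, params):
    """Independent per-voxel threshold sweep (the slow reference)."""
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


class TestStatKernels:
    def test_f_zero_without_condition_variance(self):
        y = np.tile(np.random.default_rng(0).normal(size=(4, 1, 6)), (1, 3, 1))
        assert np.allclose(rm_f_stat(y), 0.0)

    def test_f_matches_hand_decomposition(self):
        # 3 sessions x 3 conditions, values chosen with a nonzero residual
        y = np.array([[1.0, 2.0, 4.0],
                      [2.0, 4.0, 5.0],
                      [4.0, 3.0, 8.0]])[..., None]
        m, mc, ms = y[..., 0].mean(), y[..., 0].mean(0), y[..., 0].mean(1)
        ss_cond = 3 * ((mc - m) ** 2).sum()
        resid = y[..., 0] - ms[:, None] - mc[None, :] + m
        expect = (ss_cond / 2) / ((resid ** 2).sum() / 4)
        assert rm_f_stat(y)[0] == pytest.approx(expect)

    def test_f_equals_t_squared_on_two_conditions(self):
        y = np.random.default_rng(1).normal(size=(6, 2, 40))
        F = rm_f_stat(y)
        t = paired_t_stat(y[:, 0, :], y[:, 1, :])
        assert np.allclose(F, t ** 2, atol=1e-6)

    def test_f_larger_under_condition_effect(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(8, 3, 200))
        y[:, 2, :100] += 1.0
        F = rm_f_stat(y)
        assert F[:100].mean() > F[100:].mean()

    def test_paired_t_closed_form_and_antisymmetry(self):
        d = np.array([[1.0], [2.0], [3.0]])
        t = paired_t_stat(d, np.zeros_like(d))
        assert t[0] == pytest.approx(2 / (1 / np.sqrt(3)))
        assert paired_t_stat(np.zeros_like(d), d)[0] == pytest.approx(-t[0])

    def test_paired_t_zero_when_equal(self):
        a = np.random.default_rng(3).normal(size=(5, 9))
        assert np.allclose(paired_t_stat(a, a), 0.0)

    def test_bonferroni_arithmetic(self):
        assert bonferroni_components(0.001, 28) == pytest.approx(0.028)
        assert bonferroni_components(0.002, 43) == pytest.approx(0.086)
        assert bonferroni_components(0.3, 1) == pytest.approx(0.3)
        assert bonferroni_components(0.2, 10) == 1.0


class TestTfce:
    def test_zero_map(self):
        assert np.all(tfce_transform(np.zeros((5, 5, 5))) == 0)

    def test_single_cluster_closed_form(self):
        vol = np.zeros((8, 8, 8))
        vol[2:4, 2:4, 2:4] = 2.0              # 8-voxel cluster at height 2
        params = TfceParams(n_steps=1000)
        got = tfce_transform(vol, None, params)[2, 2, 2]
        expect = 8 ** 0.5 * 2.0 ** 3 / 3
        assert abs(got - expect) / expect < 0.02

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bruteforce_oracle(self, connectivity):
        rng = np.random.default_rng(connectivity)
        params = TfceParams(n_steps=40, connectivity=connectivity)
        for _ in range(3):
            vol = np.maximum(rng.normal(0, 1, (6, 6, 6)), 0)
            fast = tfce_transform(vol, None, params)
            slow = tfce_bruteforce(vol, params)
            assert np.allclose(fast, slow, atol=1e-12)

    def test_monotone_in_scale(self):
        rng = np.random.default_rng(5)
        vol = np.maximum(rng.normal(0, 1, (6, 6, 6)), 0)
        a = tfce_transform(vol)
        b = tfce_transform(2.5 * vol)
        nz = a > 0
        assert np.all(b[nz] > a[nz])

    def test_stack_agrees_with_per_map(self):
        rng = np.random.default_rng(6)
        stack = np.maximum(rng.normal(0, 1, (4, 5, 5, 4)), 0)
        joint = tfce_stack(stack)
        single = np.stack([tfce_stack(stack[i][None])[0] for i in range(4)])
        assert np.allclose(joint, single)


MASK = np.zeros((6, 6, 5), dtype=bool)
MASK[1:5, 1:5, 1:4] = True
VI = np.argwhere(MASK)


class TestPermutationFwe:
    def test_exhaustive_sign_flip_minimum_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, size=(3, VI.shape[0]))   # strong effect
        b = np.zeros_like(a)
        res = permutation_fwe_paired_t(a, b, MASK, VI, n_perm=1000, seed=0)
        assert res["exhaustive"]
        assert res["n_permutations"] == 7                 # 2^3 - identity
        # two one-sided tests, doubled: smallest attainable two-sided p = 2/8
        assert res["p_fwe"].min() == pytest.approx(2 / 8)
        assert res["p_pos"].min() == pytest.approx(1 / 8)

    def test_p_floor_and_determinism(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(5, 3, VI.shape[0]))
        r1 = permutation_fwe_f(y, MASK, VI, n_perm=200, seed=3)
        r2 = permutation_fwe_f(y, MASK, VI, n_perm=200, seed=3)
        assert np.array_equal(r1["p_fwe"], r2["p_fwe"])
        assert r1["p_fwe"].min() >= 1 / (r1["n_permutations"] + 1)
        assert r1["p_fwe"].max() <= 1.0

    def test_f_permutation_detects_planted_condition_effect(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(8, 3, VI.shape[0]))
        y[:, 2, :10] += 2.0
        res = permutation_fwe_f(y, MASK, VI, n_perm=300, seed=0)
        assert res["p_fwe"][:10].min() < 0.05


class TestGroupAnova:
    def test_detects_common_time_effect_not_diet(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 2, 3, VI.shape[0]))
        y[:, :, 2, :12] += 1.5
        res = group_anova_permutation(y, MASK, VI, n_perm=300, seed=0)
        assert res["time"]["p_fwe"].min() < 0.05
        assert res["diet"]["p_fwe"].min() > 0.05

    def test_missing_cells_drop_subject_with_warning(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(4, 2, 3, VI.shape[0]))
        y[1, 0, 2, 0] = np.nan
        with pytest.warns(UserWarning, match="dropping 1"):
            group_anova_permutation(y, MASK, VI, n_perm=50, seed=0)

    def test_too_few_subjects_rejected(self):
        y = np.random.default_rng(5).normal(size=(1, 2, 3, VI.shape[0]))
        with pytest.raises(ValueError, match="2 complete subjects"):
            group_anova_permutation(y, MASK, VI, n_perm=50, seed=0)


def test_effect_raises_stage1_variance_in_post45():
    """A planted post45 amplitude increase shows up as higher stage-1
    time-course variance in the third block (the coupling surrogate)."""
    from hypoconn.conditioning import condition_blocks
    from hypoconn.inference import dual_regress_mask
    from hypoconn.synthetic import generate_study
    from conftest import truth_component_set
    wins = 0
    for seed in range(5):
        ds = generate_study(n_sessions=4, K=2, snr=1.0, n_timepoints=80,
                            effect_spec={0: (1.0, 1.0, 1.8)}, seed=50 + seed)
        blocks = condition_blocks(ds.blocks_in_order(), ds.mask)
        dr = dual_regress_mask(blocks, truth_component_set(ds), ds.mask)
        var_b = dr.stage1_timecourses[:, 0, :, 0].var(axis=1).mean()
        var_p45 = dr.stage1_timecourses[:, 2, :, 0].var(axis=1).mean()
        wins += var_p45 > var_b
    assert wins >= 5 * 0.9 - 1e-9  # >= 90% of simulated datasets
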