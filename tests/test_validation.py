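"""Validation statistics: windowed/inter-section Dice, patch validation,
ROI accuracy, regression, SUVR, permutation test."""

import numpy as np
import pytest

from cortexrecon import phantom as ph
from cortexrecon import validation as va
from cortexrecon.core import GMMask, Rigid2D, TransformChain, Volume3D, dice
from cortexrecon.multires import assemble_gm_volume
from cortexrecon.surface import (DepthSurfaceSet, VertexField, apply_upsample,
                                 generate_depth_surfaces, inflate_to_sphere,
                                 upsample_pattern)


def naive_windowed_dice(pred, ref, w=5):
    scores = []
    for i in range(pred.shape[0] - w + 1):
        for j in range(pred.shape[1] - w + 1):
            a = pred[i:i + w, j:j + w]
            b = ref[i:i + w, j:j + w]
            if a.sum() == 0:
                continue
            scores.append(2 * (a & b).sum() / (a.sum() + b.sum()))
    return float(np.mean(scores))


class TestWindowedDice:
    def test_identical_masks_score_one(self):
        m = np.zeros((12, 12), bool)
        m[3:9, 3:9] = True
        assert va.windowed_dice(m, m) == 1.0

    def test_damaged_but_aligned_prediction_penalized_far_less(self):
        # half the tissue deleted but the remainder perfectly aligned: the
        # skip rule discards tissue-free windows, so only windows straddling
        # the damage edge lose score
        ref = np.zeros((20, 20), bool)
        ref[4:16, 4:16] = True
        pred = ref.copy()
        pred[:, 10:] = False
        wd = va.windowed_dice(pred, ref)
        assert wd > dice(pred, ref) + 0.15
        # interior windows all score 1; with no damage edge the score is 1
        assert va.windowed_dice(ref, ref) == 1.0

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            pred = rng.random((30, 30)) > 0.6
            ref = rng.random((30, 30)) > 0.6
            if not pred.any():
                continue
            assert va.windowed_dice(pred, ref) == \
                pytest.approx(naive_windowed_dice(pred, ref), abs=1e-12)

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError):
            va.windowed_dice(np.zeros((10, 10), bool), np.ones((10, 10), bool))

    def test_skip_rule_helps_contiguous_damage(self):
        # contiguous missing chunks (torn tissue) are what the rule targets
        rng = np.random.default_rng(1)
        for _ in range(10):
            ref = np.zeros((30, 30), bool)
            ref[3:27, 3:27] = True
            r0 = rng.integers(3, 15)
            pred = ref.copy()
            pred[r0:, 18:] = False     # one missing corner block
            assert va.windowed_dice(pred, ref) >= dice(pred, ref)


class TestIntersectionDice:
    def test_identical_masks_all_one(self):
        m = np.zeros((10, 10), bool)
        m[2:8, 2:8] = True
        out = va.intersection_dice({0: m, 1: m, 3: m})
        assert all(v == 1.0 for v in out.values())

    def test_ends_use_single_neighbor(self):
        rng = np.random.default_rng(2)
        masks = {i: rng.random((10, 10)) > 0.5 for i in (0, 2, 5)}
        out = va.intersection_dice(masks)
        assert out[0] == dice(masks[0], masks[2])
        assert out[5] == dice(masks[5], masks[2])
        assert out[2] == pytest.approx(
            (dice(masks[2], masks[0]) + dice(masks[2], masks[5])) / 2)

    def test_single_section_rejected(self):
        with pytest.raises(ValueError):
            va.intersection_dice({0: np.ones((4, 4), bool)})


class TestPatchValidation:
    @pytest.fixture(scope="class")
    def setup(self, small_phantom):
        depth = generate_depth_surfaces(small_phantom.wm_mesh,
                                        small_phantom.pial_mesh, 4)
        pat = upsample_pattern([small_phantom.wm_mesh,
                                small_phantom.pial_mesh], 1.0)
        mid = apply_upsample(depth.meshes[2], pat)
        sph = apply_upsample(
            inflate_to_sphere(depth.meshes[2], center=small_phantom.center_mm),
            pat)
        return mid, sph

    def test_constant_field_reproduced_exactly(self, setup):
        mid, sph = setup
        known = np.ones(mid.n_vertices, bool)
        fld = VertexField(np.full(mid.n_vertices, 42.0), known)
        spec = va.PatchSpec(n_seeds=50, seed=0)
        t, e, r2 = va.patch_interpolation_validation(mid, sph, fld, spec)
        assert r2 is None               # zero-variance: exact-match flag
        assert np.allclose(t, e)

    def test_smooth_field_high_r2_and_determinism(self, setup, small_phantom):
        mid, sph = setup
        vals = small_phantom.truth_fields["acq0"](
            (mid.vertices - small_phantom.center_mm)
            / np.linalg.norm(mid.vertices - small_phantom.center_mm,
                             axis=1, keepdims=True)) * 100
        fld = VertexField(vals, np.ones(mid.n_vertices, bool))
        spec = va.PatchSpec(n_seeds=150, seed=3)
        t1, e1, r2a = va.patch_interpolation_validation(mid, sph, fld, spec)
        t2, e2, r2b = va.patch_interpolation_validation(mid, sph, fld, spec)
        assert np.array_equal(t1, t2) and np.array_equal(e1, e2)
        assert r2a == r2b and r2a >= 0.95

    def test_insufficient_known_vertices_rejected(self, setup):
        mid, sph = setup
        known = np.zeros(mid.n_vertices, bool)
        known[:5] = True
        with pytest.raises(ValueError):
            va.patch_interpolation_validation(
                mid, sph, VertexField(np.zeros(mid.n_vertices), known),
                va.PatchSpec(n_seeds=5, seed=0))


class TestRoiParcellation:
    def test_region_count_tracks_target_area(self):
        img = np.zeros((20, 60))
        mask = np.zeros((20, 60), bool)
        mask[5:15, 5:55] = True          # 500 px tissue strip
        img[mask] = 100.0
        parc = va.make_roi_parcellation(img, mask, target_mean_area_mm2=50.0,
                                        pixel_size_mm=1.0)
        assert 8 <= parc.n_rois <= 12

    def test_single_pixel_mask_single_roi(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True
        img = np.where(mask, 9.0, 0.0)
        parc = va.make_roi_parcellation(img, mask, 21.0)
        assert parc.n_rois == 1

    def test_partition_covers_tissue_exactly(self):
        rng = np.random.default_rng(4)
        img = rng.random((30, 30)) * 200
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        parc = va.make_roi_parcellation(img, mask, 40.0)
        assert np.all((parc.labels > 0) == mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            va.make_roi_parcellation(np.zeros((5, 5)), np.zeros((5, 5), bool),
                                     21.0)


class TestInterpolationAccuracy:
    def test_identity_transforms_exact(self, small_phantom):
        scheme = ph.SamplingScheme(coverage_fraction=0.5, acquisitions=("acq0",),
                                   n_slabs=1, rigid_jitter=(0.0, 0.0),
                                   warp_amplitude_px=0.0,
                                   slab_affine_jitter=(0.0, 0.0))
        stack, _ = ph.slice_sections(small_phantom, scheme, seed=31)
        raws, parcs = {}, {}
        chains = {}
        vol = np.zeros(small_phantom.truth_volume.shape)
        for r in stack.records:
            k = (1, r.sample_index)
            raws[k] = small_phantom.sections[k]
            parcs[k] = va.make_roi_parcellation(
                small_phantom.sections[k], small_phantom.truth_masks[k], 21.0)
            chains[k] = TransformChain()
            vol[:, r.sample_index, :] = small_phantom.sections[k]
        v = Volume3D(vol, spacing_mm=small_phantom.truth_volume.spacing_mm)
        out = va.interpolation_accuracy(raws, parcs, chains, v,
                                        pixel_size_mm=1.0, thickness_mm=0.5,
                                        mode="nearest")
        assert out["mean_2d"] == 1.0
        assert out["mean_3d"] == 1.0

    def test_known_warps_order_2d_over_3d(self, small_phantom):
        scheme = ph.SamplingScheme(coverage_fraction=0.5, acquisitions=("acq0",),
                                   n_slabs=1, slab_affine_jitter=(0.0, 0.0))
        stack, chains = ph.slice_sections(small_phantom, scheme, seed=33)
        raws, parcs = {}, {}
        for r in stack.records:
            k = (1, r.sample_index)
            raws[k] = small_phantom.sections[k]
            parcs[k] = va.make_roi_parcellation(
                small_phantom.sections[k], small_phantom.truth_masks[k], 21.0)
        recon = assemble_gm_volume(raws, chains, stack, 1.0, 1.0, clip01=False)
        out = va.interpolation_accuracy(raws, parcs, chains, recon,
                                        pixel_size_mm=1.0, thickness_mm=0.5)
        assert out["mean_2d"] >= out["mean_3d"]
        assert out["mean_3d"] >= 0.90


class TestRegression:
    def test_identity_pairs(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        slope, intercept, r2 = va.regional_regression(a, a)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)

    def test_affine_relation(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        slope, intercept, r2 = va.regional_regression(a, 2 * a + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.random(20)
            b = 1.5 * a + rng.normal(0, 0.1, 20)
            X = np.stack([a, np.ones_like(a)], axis=1)
            beta = np.linalg.solve(X.T @ X, X.T @ b)
            slope, intercept, _ = va.regional_regression(a, b)
            assert slope == pytest.approx(beta[0])
            assert intercept == pytest.approx(beta[1])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            va.regional_regression([1, 1, 1], [1, 2, 3])


class TestSuvr:
    def test_volume_equal_to_wm_mean_becomes_ones(self):
        vals = np.full((6, 6, 6), 8.0)
        wm = np.zeros((6, 6, 6))
        wm[2:4, 2:4, 2:4] = 1
        out = va.suvr(Volume3D(vals), GMMask(wm))
        assert np.allclose(out.values, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        vals = rng.random((6, 6, 6)) + 0.5
        wm = (rng.random((6, 6, 6)) > 0.7).astype(float)
        a = va.suvr(Volume3D(vals), GMMask(wm))
        b = va.suvr(Volume3D(2 * vals), GMMask(wm))
        assert np.allclose(a.values, b.values)

    def test_wm_mean_matches_masked_average(self):
        rng = np.random.default_rng(7)
        vals = rng.random((5, 5, 5)) + 1
        wm = (rng.random((5, 5, 5)) > 0.5).astype(float)
        out = va.suvr(Volume3D(vals), GMMask(wm))
        assert np.allclose(out.values * vals[wm.astype(bool)].mean(), vals)

    def test_zero_wm_mean_rejected(self):
        wm = np.zeros((4, 4, 4))
        wm[0, 0, 0] = 1
        with pytest.raises(ValueError):
            va.suvr(Volume3D(np.zeros((4, 4, 4))), GMMask(wm))


class TestPermutationTest:
    def test_identical_lists_give_p_near_one(self):
        w = [0.5, 0.5, 0.5, 0.5]
        p = va.permutation_corr_test(w, list(w), n_perm=500, seed=0)
        assert p > 0.9

    def test_separated_lists_give_small_p(self):
        p = va.permutation_corr_test([0.9] * 5, [0.1] * 5, n_perm=10000, seed=0)
        assert p <= 0.01

    def test_agrees_with_exhaustive_enumeration(self):
        from itertools import combinations
        rng = np.random.default_rng(8)
        w = rng.random(5)
        b = rng.random(5)
        pooled = np.concatenate([w, b])
        obs = abs(w.mean() - b.mean())
        count = total = 0
        for idx in combinations(range(10), 5):
            sel = np.zeros(10, bool)
            sel[list(idx)] = True
            stat = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += stat >= obs - 1e-15
            total += 1
        exact = count / total
        p = va.permutation_corr_test(w, b, n_perm=20000, seed=1)
        assert p == pytest.approx(exact, abs=0.02)

    def test_monotone_in_effect_size(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0.5, 0.05, 8)
        ps = []
        for shift in (0.0, 0.05, 0.15):
            p = va.permutation_corr_test(base + shift, base, n_perm=2000, seed=2)
            ps.append(p)
        assert ps[0] >= ps[1] >= ps[2]

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning):
            va.permutation_corr_test([0.5], [0.4], n_perm=50, seed=0)
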