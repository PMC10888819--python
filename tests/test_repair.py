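import numpy as np
import pytest

from fetalcortex.repair import (
    RepairConfig,
    detect_artifacts,
    fit_label_appearance,
    n_patches,
    poisson_repair,
    repair_section,
    robust_outlier_scores,
    synthesize_section,
    tile_and_stitch,
)
from fetalcortex.synthetic.histology import ConfigurationError


def constant_section(color, shape=(32, 32)):
    img = np.zeros((*shape, 3), dtype=np.uint8)
    img[:] = color
    return img


class TestAppearanceModel:
    def test_constant_color_gives_exact_mean_zero_cov(self):
        img = constant_section((200, 100, 50))
        labels = np.ones(img.shape[:2], dtype=np.int32)
        model = fit_label_appearance(img, labels, min_pixels=10)
        st = model.get(1)
        assert np.allclose(st.mean, (200, 100, 50))
        assert np.allclose(st.cov, 0.0)

    def test_two_disjoint_labels_exact_means(self):
        img = constant_section((10, 20, 30))
        img[:, 16:] = (200, 210, 220)
        labels = np.ones(img.shape[:2], dtype=np.int32)
        labels[:, 16:] = 2
        model = fit_label_appearance(img, labels, min_pixels=10)
        assert np.allclose(model.get(1).mean, (10, 20, 30))
        assert np.allclose(model.get(2).mean, (200, 210, 220))

    def test_gaussian_label_mean_within_three_se(self, rng):
        n = 64 * 64
        img = np.rint(rng.normal(120.0, 10.0, (64, 64, 3)).clip(0, 255)
                      ).astype(np.uint8)
        labels = np.ones((64, 64), dtype=np.int32)
        model = fit_label_appearance(img, labels, min_pixels=10)
        assert np.abs(model.get(1).mean - 120.0).max() < 3 * 10.0 / np.sqrt(n)

    def test_sparse_label_falls_back_to_global(self):
        img = constant_section((50, 60, 70))
        labels = np.ones(img.shape[:2], dtype=np.int32)
        labels[0, 0] = 2
        model = fit_label_appearance(img, labels, min_pixels=100)
        assert model.errors
        assert np.allclose(model.get(2).mean, model.global_stats.mean)


class TestSynthesize:
    def test_zero_covariance_reproduces_means_exactly(self):
        img = constant_section((120, 40, 220))
        labels = np.ones(img.shape[:2], dtype=np.int32)
        model = fit_label_appearance(img, labels, min_pixels=10)
        out = synthesize_section(labels, model, seed=1)
        assert np.array_equal(out, img)

    def test_relabeling_equivariance(self):
        img = constant_section((10, 20, 30), (16, 16))
        img[8:] = (100, 110, 120)
        labels = np.ones((16, 16), dtype=np.int32)
        labels[8:] = 2
        model = fit_label_appearance(img, labels, min_pixels=5)
        out1 = synthesize_section(labels, model, seed=3)
        permuted = np.where(labels == 1, 2, 1)
        model.stats = {2: model.stats[1], 1: model.stats[2]}
        out2 = synthesize_section(permuted, model, seed=3)
        assert np.array_equal(out1, out2)

    def test_sampled_mean_matches_model(self, rng):
        img = rng.normal(140.0, 8.0, (64, 64, 3)).clip(0, 255).astype(np.uint8)
        labels = np.ones((64, 64), dtype=np.int32)
        model = fit_label_appearance(img, labels, min_pixels=10)
        out = synthesize_section(labels, model, seed=5).astype(float)
        se = 8.0 / np.sqrt(64 * 64)
        assert np.abs(out.mean(axis=(0, 1)) - model.get(1).mean).max() < 5 * se

    def test_unknown_label_without_fallback_raises(self):
        img = constant_section((1, 2, 3))
        labels = np.ones(img.shape[:2], dtype=np.int32)
        model = fit_label_appearance(img, labels, min_pixels=10)
        with pytest.raises(KeyError):
            synthesize_section(labels * 7, model, seed=0, fallback=False)


class TestTileAndStitch:
    def test_identity_operator_is_exact(self, rng):
        img = rng.random((300, 300, 3)) * 255
        cfg = RepairConfig(patch_size=256, patch_overlap=8)
        out = tile_and_stitch(img, cfg, lambda p: p)
        assert np.abs(out - img).max() < 1e-9

    def test_constant_shift_has_no_seams(self, rng):
        img = rng.random((70, 90)) * 10
        cfg = RepairConfig(patch_size=32, patch_overlap=8)
        out = tile_and_stitch(img, cfg, lambda p: p + 5.0)
        assert np.abs(out - (img + 5.0)).max() < 1e-9

    def test_tiling_arithmetic(self):
        # ceil((300 - 8) / (256 - 8)) = 2 per axis
        assert n_patches(300, 256, 8) == 2
        assert n_patches(256, 256, 8) == 1
        assert n_patches(257, 256, 8) == 2

    def test_overlap_must_be_smaller_than_patch(self):
        with pytest.raises(ConfigurationError):
            tile_and_stitch(np.zeros((64, 64)),
                            RepairConfig(patch_size=16, patch_overlap=16),
                            lambda p: p)

    def test_small_image_single_padded_patch(self, rng):
        img = rng.random((20, 25)) * 255
        cfg = RepairConfig(patch_size=64, patch_overlap=8)
        out = tile_and_stitch(img, cfg, lambda p: p)
        assert out.shape == img.shape
        assert np.abs(out - img).max() < 1e-9


class TestDetectArtifacts:
    def test_identical_images_give_empty_mask(self, rng):
        img = (rng.random((40, 40, 3)) * 255).astype(np.uint8)
        mask = detect_artifacts(img, img.copy(), RepairConfig())
        assert not mask.any()

    def test_hand_computed_robust_scores(self):
        # d = [1,1,2,2,3,100]: median 2, MAD 1 -> scores [1,1,0,0,1,98]
        d = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 100.0])
        scores = robust_outlier_scores(d)
        assert np.allclose(scores, [1, 1, 0, 0, 1, 98])
        assert (scores > 2.5).sum() == 1

    def test_lowering_theta_never_shrinks_outlier_set(self, aligned_histology):
        t = aligned_histology
        img = t.corrupted_stack.images[0]
        model = fit_label_appearance(t.corrupted_stack.images,
                                     t.corrupted_stack.labels,
                                     t.artifact_masks)
        synth = synthesize_section(t.corrupted_stack.labels[0], model, seed=0)
        masks = []
        for theta in (4.0, 2.5, 1.5, 0.8):
            cfg = RepairConfig(theta=theta, opening_iterations=0)
            masks.append(detect_artifacts(img, synth, cfg))
        for tight, loose in zip(masks[:-1], masks[1:]):
            assert not (tight & ~loose).any()

    def test_tear_detection_recall(self, aligned_histology):
        t = aligned_histology
        model = fit_label_appearance(t.corrupted_stack.images,
                                     t.corrupted_stack.labels,
                                     t.artifact_masks)
        cfg = RepairConfig()
        recalls = []
        for s in range(t.corrupted_stack.n_sections):
            synth = synthesize_section(t.corrupted_stack.labels[s], model,
                                       seed=s)
            mask = detect_artifacts(t.corrupted_stack.images[s], synth, cfg)
            gt = t.artifact_masks[s]
            recalls.append((mask & gt).sum() / gt.sum())
        assert np.mean(recalls) >= 0.8


class TestPoissonRepair:
    def test_empty_mask_returns_original(self, rng):
        img = (rng.random((16, 16, 3)) * 255).astype(np.uint8)
        out = poisson_repair(img, img[::-1], np.zeros((16, 16), bool))
        assert np.array_equal(out, img)

    def test_identical_images_fixed_point(self, rng):
        img = (rng.random((16, 16)) * 255).astype(float)
        mask = np.zeros((16, 16), bool)
        mask[5:10, 5:10] = True
        out = poisson_repair(img, img, mask)
        assert np.abs(out - img).max() < 1e-6

    def test_matches_dense_solver_oracle(self, rng):
        h = w = 8
        orig = rng.random((h, w)) * 255
        synth = rng.random((h, w)) * 255
        mask = np.zeros((h, w), bool)
        mask[3:6, 3:6] = True
        out = poisson_repair(orig, synth, mask)

        # dense oracle: assemble the full linear system explicitly
        idx = {tuple(p): i for i, p in enumerate(np.argwhere(mask))}
        n = len(idx)
        A = np.zeros((n, n))
        b = np.zeros(n)
        for (r, c), i in idx.items():
            A[i, i] = -4
            lap = (-4 * synth[r, c] + synth[r - 1, c] + synth[r + 1, c]
                   + synth[r, c - 1] + synth[r, c + 1])
            b[i] = lap
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nb = (r + dr, c + dc)
                if nb in idx:
                    A[i, idx[nb]] = 1
                else:
                    b[i] -= orig[nb]
        x = np.linalg.solve(A, b)
        expected = orig.copy()
        for (r, c), i in idx.items():
            expected[r, c] = x[i]
        expected = np.clip(expected, 0, 255)
        assert np.abs(out - expected).max() < 1e-6

    def test_poisson_equation_residual(self, rng):
        # smooth fields keep the solution inside [0, 255] so no clipping
        h = w = 12
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        orig = 60.0 + 8.0 * yy + 3.0 * xx
        synth = 150.0 - 4.0 * yy + 2.0 * xx + 0.5 * yy * xx
        mask = np.zeros((h, w), bool)
        mask[4:8, 4:8] = True
        out = poisson_repair(orig, synth, mask)
        for r in range(5, 7):
            for c in range(5, 7):
                lap_out = (-4 * out[r, c] + out[r - 1, c] + out[r + 1, c]
                           + out[r, c - 1] + out[r, c + 1])
                lap_s = (-4 * synth[r, c] + synth[r - 1, c]
                         + synth[r + 1, c] + synth[r, c - 1]
                         + synth[r, c + 1])
                assert lap_out == pytest.approx(lap_s, abs=1e-6)

    def test_outside_mask_untouched(self, rng):
        img = (rng.random((20, 20, 3)) * 255).astype(np.uint8)
        synth = (rng.random((20, 20, 3)) * 255).astype(np.uint8)
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        out = poisson_repair(img, synth, mask)
        assert np.array_equal(out[~mask], img[~mask])


class TestRepairSection:
    def test_clean_section_unchanged(self, aligned_histology):
        t = aligned_histology
        model = fit_label_appearance(t.clean_stack.images,
                                     t.clean_stack.labels)
        cfg = RepairConfig(patch_size=64)
        repaired, mask = repair_section(t.clean_stack.images[0],
                                        t.clean_stack.labels[0], model, cfg,
                                        seed=1)
        assert mask.mean() < 0.01
        assert np.array_equal(repaired[~mask], t.clean_stack.images[0][~mask])

    def test_repair_reduces_error_inside_tear(self, aligned_histology):
        t = aligned_histology
        model = fit_label_appearance(t.corrupted_stack.images,
                                     t.corrupted_stack.labels,
                                     t.artifact_masks)
        cfg = RepairConfig(patch_size=64)
        for s in range(2):
            clean = t.clean_stack.images[s].astype(float)
            corrupted = t.corrupted_stack.images[s]
            repaired, _ = repair_section(corrupted, t.corrupted_stack.labels[s],
                                         model, cfg, seed=s)
            gt = t.artifact_masks[s]
            before = np.abs(corrupted.astype(float) - clean)[gt].mean()
            after = np.abs(repaired.astype(float) - clean)[gt].mean()
            assert after < before

    def test_deterministic_for_fixed_seed(self, aligned_histology):
        t = aligned_histology
        model = fit_label_appearance(t.corrupted_stack.images,
                                     t.corrupted_stack.labels,
                                     t.artifact_masks)
        cfg = RepairConfig(patch_size=64)
        r1, m1 = repair_section(t.corrupted_stack.images[0],
                                t.corrupted_stack.labels[0], model, cfg, 7)
        r2, m2 = repair_section(t.corrupted_stack.images[0],
                                t.corrupted_stack.labels[0], model, cfg, 7)
        assert np.array_equal(r1, r2) and np.array_equal(m1, m2)
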