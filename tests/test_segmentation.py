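"""Segmentation-chain tests against brute-force oracles and ground truth."""

import numpy as np
import pytest
from scipy import ndimage

from segclock.scenes import AppearanceParams, generate_brightfield_scene
from segclock.segmentation import (Mask, NoCellFoundError, SegmentationParams,
                                   extract_intensities, morph_gradient,
                                   otsu_threshold, preprocess_gradient,
                                   refine_active_contour, segment_sequence,
                                   select_central_blob, smooth_frame)
from segclock.synth import draw_cell_program
from segclock.trace import PeakParams, analyze_trace

from conftest import deterministic_preset


def jaccard(a, b):
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


def small_scene(n_frames=8, seed=3, **appearance):
    preset = deterministic_preset(n_peaks=3, duration=400.0)
    prog = draw_cell_program(preset, 7, cell_id="scene")
    ap = AppearanceParams(image_size=80, radius=16.0, background_speckle=0.0,
                          **appearance)
    scene = generate_brightfield_scene(prog, preset, ap, seed=seed,
                                       n_frames=n_frames)
    return scene, preset


class TestGradient:
    def test_constant_image_gives_zero_gradient(self):
        grad = preprocess_gradient(np.full((64, 64), 3.7))
        np.testing.assert_allclose(grad, 0.0, atol=1e-12)

    def test_single_bright_pixel_gives_ring(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        grad = morph_gradient(img, disk_radius=2)
        yy, xx = np.mgrid[0:33, 0:33]
        d = np.hypot(yy - 16, xx - 16)
        assert np.all(grad[d <= 2] > 0)  # ring of width ~2 * disk radius
        assert np.all(grad[d > 3] == 0)

    def test_matches_brute_force_disk_morphology(self, rng):
        # exhaustive oracle: max-over-disk minus min-over-disk at every pixel
        img = smooth_frame(rng.random((32, 32)))
        r = 2
        grad = morph_gradient(img, disk_radius=r)
        from skimage.morphology import disk
        selem = disk(r).astype(bool)
        pad = np.pad(img, r, mode="reflect")
        expected = np.empty_like(img)
        for i in range(32):
            for j in range(32):
                neigh = pad[i:i + 2 * r + 1, j:j + 2 * r + 1][selem]
                expected[i, j] = neigh.max() - neigh.min()
        np.testing.assert_allclose(grad, expected, atol=1e-12)

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            preprocess_gradient(np.zeros((4, 4, 4)))


class TestOtsu:
    def test_two_valued_image(self):
        img = np.where(np.arange(100).reshape(10, 10) % 3 == 0, 10, 200)
        binary = otsu_threshold(img)
        assert np.array_equal(binary, img == 200)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 5.0))

    def test_matches_exhaustive_between_class_variance_search(self, rng):
        # toy 8-level histogram; exhaustive search over all cut points
        img = rng.integers(0, 8, size=(20, 20)).astype(float)
        binary = otsu_threshold(img)
        vals = img.ravel()
        best_t, best_var = None, -1.0
        for t in np.unique(vals)[:-1]:
            lo, hi = vals[vals <= t], vals[vals > t]
            w0, w1 = len(lo) / len(vals), len(hi) / len(vals)
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var + 1e-12:
                best_var, best_t = var, t
        np.testing.assert_array_equal(binary, img > best_t)

    def test_inversion_swaps_foreground(self, rng):
        img = rng.normal(size=(16, 16))
        img[4:9, 4:9] += 4.0
        assert np.array_equal(otsu_threshold(-img), ~otsu_threshold(img))


class TestCentralBlob:
    def test_single_central_blob_unchanged(self):
        img = np.zeros((40, 40), bool)
        img[16:24, 16:24] = True
        out = select_central_blob(img)
        assert np.array_equal(out.image, img)

    def test_centrality_dominates_size(self):
        img = np.zeros((40, 40), bool)
        img[0:12, 0:12] = True  # large corner blob
        img[18:22, 18:22] = True  # small central blob
        out = select_central_blob(img)
        assert out.image[19, 19] and not out.image[2, 2]

    def test_largest_central_blob_wins(self):
        img = np.zeros((40, 40), bool)
        img[14:18, 14:24] = True  # 40 px
        img[22:28, 14:29] = True  # 90 px
        out = select_central_blob(img)
        # oracle: exhaustive connected-component enumeration
        lbl, n = ndimage.label(img, structure=np.ones((3, 3)))
        areas = ndimage.sum_labels(img, lbl, index=range(1, n + 1))
        expected = lbl == (int(np.argmax(areas)) + 1)
        assert np.array_equal(out.image, expected)
        assert out.area == 90

    def test_no_central_blob_raises(self):
        img = np.zeros((40, 40), bool)
        img[0:4, 0:4] = True
        with pytest.raises(NoCellFoundError):
            select_central_blob(img)


class TestActiveContour:
    def _blob_image(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        yy, xx = np.mgrid[0:64, 0:64]
        gt = np.hypot(yy - 32, xx - 32) <= 14
        img = np.where(gt, 1.0, 0.0)
        if noise:
            img = img + rng.normal(0, noise, img.shape)
        return img, gt

    def test_zero_iterations_is_identity(self):
        img, gt = self._blob_image()
        init = Mask(image=gt.copy())
        out = refine_active_contour(img, init,
                                    SegmentationParams(ac_iterations=0))
        assert np.array_equal(out.image, gt)

    def test_sharp_uniform_blob_stays_put(self):
        img, gt = self._blob_image()
        out = refine_active_contour(img, Mask(image=gt.copy()))
        assert jaccard(out.image, gt) >= 0.95

    def test_contraction_bias_shrinks_result(self):
        img, gt = self._blob_image(noise=0.15, seed=1)
        a = refine_active_contour(img, Mask(image=gt.copy()),
                                  SegmentationParams(ac_contraction_bias=0.1))
        b = refine_active_contour(img, Mask(image=gt.copy()),
                                  SegmentationParams(ac_contraction_bias=0.3))
        assert b.area <= a.area

    def test_empty_init_rejected(self):
        with pytest.raises(ValueError):
            refine_active_contour(np.zeros((8, 8)), Mask(image=np.zeros((8, 8), bool)))


class TestSegmentSequence:
    def test_noiseless_scene_jaccard(self):
        scene, _ = small_scene(n_frames=8)
        masks = segment_sequence(scene.frames)
        js = [jaccard(m.image, gt) for m, gt in zip(masks, scene.masks)]
        assert np.mean(js) >= 0.8

    def test_repeated_frame_gives_identical_masks(self):
        scene, _ = small_scene(n_frames=1)
        stack = np.repeat(scene.frames[:1], 4, axis=0)
        masks = segment_sequence(stack)
        for m in masks[1:]:
            assert np.array_equal(m.image, masks[0].image)

    def test_determinism(self):
        scene, _ = small_scene(n_frames=4)
        a = segment_sequence(scene.frames)
        b = segment_sequence(scene.frames)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.image, mb.image)

    def test_disappearing_cell_flagged(self):
        scene, _ = small_scene(n_frames=4)
        stack = scene.frames.copy()
        stack[2:] = stack[0, 0, 0]  # cell vanishes from frame 2
        masks = segment_sequence(stack)
        assert any(m.flagged for m in masks[2:])

    def test_blank_first_frame_rejects_sequence(self):
        with pytest.raises((NoCellFoundError, ValueError)):
            segment_sequence(np.full((3, 64, 64), 0.5))


class TestExtractIntensities:
    def _mask(self, shape=(10, 10)):
        img = np.zeros(shape, bool)
        img[3:7, 3:7] = True
        return Mask(image=img)

    def test_uniform_intensity_recovered(self):
        m = self._mask()
        stack = np.full((3, 10, 10), 7.0)
        tr, _ = extract_intensities([m] * 3, stack, stack, frame_interval=10.0)
        np.testing.assert_allclose(tr.values, 7.0)

    def test_single_pixel_mask(self):
        img = np.zeros((10, 10), bool)
        img[4, 5] = True
        stack = np.arange(300, dtype=float).reshape(3, 10, 10)
        tr, _ = extract_intensities([Mask(image=img)] * 3, stack, stack, 10.0)
        np.testing.assert_allclose(tr.values, stack[:, 4, 5])

    def test_empty_mask_gives_missing_value(self):
        m_ok, m_empty = self._mask(), Mask(image=np.zeros((10, 10), bool))
        stack = np.ones((2, 10, 10))
        tr, _ = extract_intensities([m_ok, m_empty], stack, stack, 10.0)
        assert tr.values[0] == 1.0 and np.isnan(tr.values[1])

    def test_max_variant(self):
        m = self._mask()
        stack = np.zeros((1, 10, 10))
        stack[0, 4, 4] = 9.0
        tr, _ = extract_intensities([m], stack, stack, 10.0, stat="max")
        assert tr.values[0] == 9.0

    def test_extracted_trace_matches_rendered_signal(self):
        scene, preset = small_scene(n_frames=8)
        masks = segment_sequence(scene.frames)
        tr, _ = extract_intensities(masks, scene.her1_stack, scene.mesp_stack,
                                    preset.frame_interval,
                                    preset.imaging_start_offset)
        clean = np.array([scene.her1_stack[t][scene.masks[t]].mean()
                          for t in range(len(masks))])
        r = np.corrcoef(tr.values, clean)[0, 1]
        assert r >= 0.95


class TestFullChain:
    def test_peak_counts_recovered_through_segmentation(self):
        # noiseless scenes -> segmentation -> intensity traces -> peak counts
        preset = deterministic_preset(n_peaks=3, duration=330.0,
                                      first_peak_mean=110.0, p0=60.0)
        ap = AppearanceParams(image_size=64, radius=13.0,
                              background_speckle=0.0)
        hits = 0
        n_cells = 6
        for i in range(n_cells):
            prog = draw_cell_program(preset, 100 + i, cell_id=f"c{i}")
            scene = generate_brightfield_scene(prog, preset, ap, seed=i)
            masks = segment_sequence(scene.frames)
            her1, _ = extract_intensities(masks, scene.her1_stack,
                                          scene.mesp_stack,
                                          preset.frame_interval,
                                          preset.imaging_start_offset)
            tab = analyze_trace(her1, PeakParams.culture())
            if tab is not None and tab.n_peaks == prog.n_peaks:
                hits += 1
        assert hits >= n_cells - 1
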