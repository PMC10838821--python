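"""Classical bone segmentation, metrics, and the trainable backend."""

import numpy as np
import pytest

from usbonereg.bone_segmentation import (
    FrameMask,
    TrainConfig,
    bone_probability_map,
    coverage_and_distance,
    dice,
    evaluate_segmentation,
    extract_surface,
    largest_component,
    segment_frame,
    train_segmenter,
)
from usbonereg.phantom_sim import make_segmentation_dataset, render_bmode_frame


def _band_frame(band_row=60, shape=(128, 128), snr=20.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = np.full(shape[1], float(band_row))
    return render_bmode_frame(rows, shape, snr, rng)


class TestBoneProbabilityMap:
    def test_band_over_shadow_peaks_at_band_center(self):
        frame = _band_frame(band_row=60)
        score = bone_probability_map(frame)
        argmax_rows = score.argmax(axis=0)
        assert np.abs(argmax_rows - 60).max() <= 1

    def test_uniform_image_gives_zero_map(self):
        score = bone_probability_map(np.full((64, 64), 127.0))
        assert np.all(score == 0.0)

    def test_shadow_raises_band_score(self):
        # equal band intensity, shadowed columns vs bright-below columns in
        # the same frame (so the per-frame normalisation is shared): the
        # shadowed band must score strictly higher
        base = np.full((100, 40), 30.0)
        rows = np.arange(100)[:, None]
        band = 220.0 * np.exp(-0.5 * ((rows - 50) / 2.0) ** 2)
        frame = base.copy()
        frame[rows[:, 0] > 52, :20] = 6.0     # acoustic shadow
        frame[rows[:, 0] > 52, 20:] = 200.0   # bright below: no shadow
        frame = np.clip(frame + band, 0, 255)
        score = bone_probability_map(frame)[50]
        shadow_cols, bright_cols = score[:14], score[26:]
        assert shadow_cols.min() > bright_cols.max()

    def test_rejects_non_2d_input(self):
        with pytest.raises(ValueError):
            bone_probability_map(np.zeros((4, 4, 3)))

    def test_scores_in_unit_interval(self, rng):
        score = bone_probability_map(rng.uniform(0, 255, (64, 64)))
        assert score.min() >= 0.0 and score.max() <= 1.0

    def test_lateral_translation_equivariance(self):
        # shifting the band k columns shifts detections k columns
        # (checked away from the borders; lateral smoothing spans ~4 px)
        shape = (96, 96)
        rows = np.full(shape[1], np.nan)
        rows[10:60] = 40.0 + 5.0 * np.sin(np.arange(50) / 8.0)
        rng = np.random.default_rng(0)
        frame = render_bmode_frame(rows, shape, 1e6, rng)
        k = 12
        shifted = np.roll(frame, k, axis=1)
        m0 = segment_frame(frame).mask
        m1 = segment_frame(shifted).mask
        interior = slice(10 + k + 6, 60 - 6)
        r0 = [np.nonzero(m0[:, c])[0] for c in range(*interior.indices(96))]
        r1 = [np.nonzero(m1[:, c + k])[0]
              for c in range(*interior.indices(96))]
        for a, b in zip(r0, r1):
            assert a.size == b.size == 1
            assert abs(int(a[0]) - int(b[0])) <= 1


class TestExtractSurface:
    def test_clean_band_gives_polyline(self):
        frame = _band_frame(band_row=45)
        fm = extract_surface(bone_probability_map(frame))
        per_col = fm.mask.sum(axis=0)
        assert np.all(per_col == 1)
        rows = fm.mask.argmax(axis=0)
        assert np.abs(rows - 45).max() <= 1

    def test_zero_map_gives_empty_mask(self):
        fm = extract_surface(np.zeros((32, 32)))
        assert fm.n_pixels == 0

    def test_two_stacked_bands_deeper_selected(self):
        score = np.zeros((60, 8))
        score[20] = 0.9   # shallow band
        score[40] = 0.8   # deep band, above threshold
        fm = extract_surface(score, threshold=0.3)
        assert np.all(fm.mask[40])
        assert not fm.mask[20].any()

    def test_at_most_one_pixel_per_column_on_random_maps(self, rng):
        for _ in range(20):
            score = rng.uniform(0, 1, (40, 30))
            fm = extract_surface(score)
            assert fm.mask.sum(axis=0).max() <= 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            extract_surface(np.zeros((8, 8)), threshold=1.5)

    def test_masked_pixels_meet_threshold(self, rng):
        score = rng.uniform(0, 1, (40, 30))
        fm = extract_surface(score, threshold=0.3)
        assert np.all(score[fm.mask] >= 0.3)


class TestLargestComponent:
    def test_keeps_bigger_blob(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[10, 0:20] = True          # 20-px blob
        mask[40, 30:35] = True         # 5-px blob
        out = largest_component(FrameMask(mask=mask))
        assert out.mask[10, 0:20].all()
        assert not out.mask[40].any()

    def test_empty_mask_passes_through(self):
        out = largest_component(FrameMask(mask=np.zeros((8, 8), dtype=bool)))
        assert out.n_pixels == 0

    def test_tie_keeps_shallower_blob(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[5, 0:10] = True           # shallow, 10 px
        mask[45, 20:30] = True         # deep, 10 px
        out = largest_component(FrameMask(mask=mask))
        assert out.mask[5].any()
        assert not out.mask[45].any()


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.uniform(0, 1, (20, 20)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_hand_computed_half_overlap(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a.ravel()[:100] = True
        b.ravel()[50:150] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        e = np.zeros((4, 4), dtype=bool)
        assert dice(e, e) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), dtype=bool), np.zeros((4, 4), dtype=bool))

    def test_symmetric_and_bounded_on_random_masks(self, rng):
        for _ in range(30):
            a = rng.uniform(0, 1, (15, 15)) > rng.uniform(0.2, 0.8)
            b = rng.uniform(0, 1, (15, 15)) > rng.uniform(0.2, 0.8)
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0


class TestCoverageAndDistance:
    def test_identical_masks(self):
        truth = np.zeros((30, 20), dtype=bool)
        truth[12, 3:15] = True
        cov, msd = coverage_and_distance(truth, truth, (0.3, 0.3))
        assert cov == 100.0 and msd == 0.0

    def test_half_coverage(self):
        truth = np.zeros((30, 20), dtype=bool)
        truth[12, 0:10] = True
        pred = np.zeros_like(truth)
        pred[12, 0:5] = True
        cov, msd = coverage_and_distance(pred, truth, (0.3, 0.3))
        assert cov == 50.0 and msd == 0.0

    def test_uniform_two_row_shift(self):
        truth = np.zeros((30, 20), dtype=bool)
        truth[10, :] = True
        pred = np.zeros_like(truth)
        pred[12, :] = True
        cov, msd = coverage_and_distance(pred, truth, (0.1, 0.1))
        assert cov == 100.0
        assert msd == pytest.approx(0.2)

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            coverage_and_distance(np.zeros((5, 5), dtype=bool),
                                  np.zeros((5, 5), dtype=bool), (0.3, 0.3))

    def test_evaluate_segmentation_bundles_metrics(self):
        truth = np.zeros((30, 20), dtype=bool)
        truth[10, :] = True
        m = evaluate_segmentation(truth, truth, (0.3, 0.3))
        assert m.dice == 1.0
        assert m.coverage_pct == 100.0
        assert m.mean_surface_distance_mm == 0.0


def _curve_frames(n, shape, snr, seed):
    """Simulator frames with a single-pixel truth mask per column."""
    rng = np.random.default_rng(seed)
    H, W = shape
    cols = np.arange(W)
    out = []
    for _ in range(n):
        base = rng.uniform(0.35, 0.7) * H
        amp = rng.uniform(0.0, 0.1) * H
        phase = rng.uniform(0, 2 * np.pi)
        curve = np.clip(
            base + amp * np.sin(2 * np.pi * cols / W + phase), 2, H - 3)
        frame = render_bmode_frame(curve, shape, snr, rng)
        truth = np.zeros(shape, dtype=bool)
        truth[np.round(curve).astype(int), cols] = True
        out.append((frame, truth))
    return out


class TestClassicalAccuracy:
    @pytest.mark.parametrize("snr", [4.0, 8.0])
    def test_mean_surface_distance_below_two_spacings(self, snr):
        # simulator frames with known surface rows; axial spacing 0.3 mm
        spacing = (0.3, 0.3)
        msds = []
        for frame, truth in _curve_frames(6, (128, 128), snr, seed=5):
            fm = segment_frame(frame, spacing)
            _, msd = coverage_and_distance(fm, truth, spacing)
            msds.append(msd)
        assert float(np.mean(msds)) < 2 * spacing[0]


class TestTrainSegmenter:
    _small_cfg = TrainConfig(epochs=1, base_filters=4, depth=2, seed=3)

    def test_deterministic_given_seed(self):
        data = make_segmentation_dataset(n_frames=10, shape=(32, 32), seed=2)
        b1 = train_segmenter(data, self._small_cfg)
        b2 = train_segmenter(data, self._small_cfg)
        frame = data[0][0]
        assert np.array_equal(b1.predict(frame, (0.3, 0.3)),
                              b2.predict(frame, (0.3, 0.3)))

    def test_predict_contract(self):
        data = make_segmentation_dataset(n_frames=10, shape=(32, 32), seed=2)
        backend = train_segmenter(data, self._small_cfg)
        score = backend.predict(data[0][0], (0.3, 0.3))
        assert score.shape == data[0][0].shape
        assert score.min() >= 0.0 and score.max() <= 1.0

    def test_too_small_dataset_rejected(self):
        data = make_segmentation_dataset(n_frames=4, shape=(32, 32))
        with pytest.raises(ValueError):
            train_segmenter(data, self._small_cfg)

    def test_single_class_labels_rejected(self):
        data = make_segmentation_dataset(n_frames=10, shape=(32, 32))
        blank = [(f, np.zeros_like(m)) for f, m in data]
        with pytest.raises(ValueError):
            train_segmenter(blank, self._small_cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(augment_fraction=1.5)
        with pytest.raises(ValueError):
            TrainConfig(split_ratio=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
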