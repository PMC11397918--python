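"""ROI masking, normalization, sliding gate/window, and class balancing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfpipe import roispec
from rfpipe.spectra import SpectrumFrame


def make_roi(values, mask, label=0, fid="r0", normalized=False):
    return roispec.ROISpectrumFrame(values=values, kind="amplitude",
                                    mask=mask, label=label,
                                    source_frame_id=fid,
                                    normalized=normalized)


def column_frame(run_len, n_lines=1, n_samples=1247, start=0):
    """ROI frame whose every line has one liver run of ``run_len``."""
    mask = np.zeros((n_samples, n_lines), np.uint8)
    mask[start:start + run_len] = 1
    rng = np.random.default_rng(run_len)
    values = rng.random((n_samples, n_lines)) * mask
    return make_roi(values, mask, normalized=True)


class TestApplyMask:
    def test_identity_and_zero_masks(self, rng):
        spec = SpectrumFrame(values=rng.random((16, 8)), kind="amplitude")
        ones = np.ones((16, 8), np.uint8)
        np.testing.assert_array_equal(
            roispec.apply_mask(spec, ones).values, spec.values)
        assert np.all(roispec.apply_mask(spec, 0 * ones).values == 0)

    def test_checkerboard_support_matches_mask(self, rng):
        spec = SpectrumFrame(values=rng.random((16, 8)) + 0.5, kind="power")
        mask = np.indices((16, 8)).sum(axis=0) % 2
        out = roispec.apply_mask(spec, mask)
        np.testing.assert_array_equal(out.values != 0, mask.astype(bool))

    def test_shape_mismatch_rejected(self, rng):
        spec = SpectrumFrame(values=rng.random((16, 8)), kind="phase")
        with pytest.raises(ValueError):
            roispec.apply_mask(spec, np.ones((8, 16), np.uint8))


class TestNormalize:
    def test_affine_map_examples(self):
        mask = np.ones((2, 2), np.uint8)
        roi = make_roi(np.array([[0.0, 1.0], [1.5, 2.0]]), mask)
        np.testing.assert_allclose(roispec.normalize(roi).values,
                                   [[0, 0.5], [0.75, 1.0]])
        ph = make_roi(np.array([[-np.pi, 0.0], [np.pi, 0.0]]), mask)
        np.testing.assert_allclose(roispec.normalize(ph).values,
                                   [[0, 0.5], [1.0, 0.5]])

    def test_idempotent_on_random_frames(self, rng):
        for _ in range(10):
            roi = make_roi(rng.standard_normal((12, 6)),
                           np.ones((12, 6), np.uint8))
            once = roispec.normalize(roi)
            twice = roispec.normalize(once)
            np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
            assert once.values.min() == 0.0 and once.values.max() == 1.0

    def test_degenerate_frame_rejected(self):
        roi = make_roi(np.full((4, 4), 2.0), np.ones((4, 4), np.uint8))
        with pytest.raises(ValueError):
            roispec.normalize(roi)


class TestGateLines:
    @pytest.mark.parametrize("run_len,expected", [
        (1247, 24),   # floor((1247-768)/20) + 1
        (768, 1),
        (788, 2),
        (767, 0),
    ])
    def test_segment_counts(self, run_len, expected):
        assert roispec.segments_per_line(run_len) == expected

    def test_full_line_yields_24_segments(self):
        gated = roispec.gate_lines(column_frame(1247))
        assert gated.shape == (768, 24)

    def test_run_767_line_excluded(self):
        roi = column_frame(767)
        with pytest.raises(ValueError, match="0 lines"):
            roispec.gate_lines(roi)

    def test_strict_mode_excludes_exact_fit(self):
        roi = column_frame(768)
        assert roispec.gate_lines(roi).shape == (768, 1)
        with pytest.raises(ValueError):
            roispec.gate_lines(roi, strict=True)

    def test_segments_are_the_expected_slices(self):
        roi = column_frame(808, start=100)
        gated = roispec.gate_lines(roi)
        assert gated.shape == (768, 3)
        for j, off in enumerate((100, 120, 140)):
            np.testing.assert_array_equal(gated[:, j],
                                          roi.values[off:off + 768, 0])

    def test_longest_run_is_used_on_fragmented_masks(self):
        mask = np.zeros((1247, 1), np.uint8)
        mask[:100] = 1          # short run, ineligible
        mask[200:1000] = 1      # 800-run -> 2 segments
        values = np.random.default_rng(0).random((1247, 1)) * mask
        gated = roispec.gate_lines(make_roi(values, mask, normalized=True))
        assert gated.shape == (768, 2)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(768, 1247))
    def test_count_formula_equals_enumeration(self, run_len):
        brute = 0
        off = 0
        while off + 768 <= run_len:
            brute += 1
            off += 20
        assert roispec.segments_per_line(run_len) == brute


class TestWindowFrames:
    def test_example_starts(self, rng):
        gated = rng.random((768, 512))
        out = roispec.window_frames(gated, 4)
        # step (512-256)/4 = 64
        for w, start in zip(out, (0, 64, 128, 192)):
            np.testing.assert_array_equal(w.values,
                                          gated[:, start:start + 256])

    def test_exact_width_repeats_single_placement(self, rng):
        gated = rng.random((768, 256))
        out = roispec.window_frames(gated, 3)
        assert len(out) == 3
        for w in out:
            np.testing.assert_array_equal(w.values, gated)

    def test_single_window_at_zero(self, rng):
        gated = rng.random((768, 300))
        (w,) = roispec.window_frames(gated, 1)
        np.testing.assert_array_equal(w.values, gated[:, :256])

    def test_narrow_frame_errors_unless_padded(self, rng):
        gated = rng.random((768, 200))
        with pytest.raises(ValueError, match="L_lateral"):
            roispec.window_frames(gated, 1)
        (w,) = roispec.window_frames(gated, 1, pad_lateral=True)
        assert w.values.shape == (768, 256)

    def test_random_pairs_emit_exactly_n_in_bounds_windows(self, rng):
        for _ in range(50):
            L = int(rng.integers(256, 2000))
            n_aug = int(rng.integers(1, 9))
            gated = rng.random((768, L))
            out = roispec.window_frames(gated, n_aug)
            assert len(out) == n_aug
            step = max(1, (L - 256) // n_aug)
            for i, w in enumerate(out):
                start = min(i * step, L - 256)
                np.testing.assert_array_equal(w.values,
                                              gated[:, start:start + 256])


class TestBalanceAndAssemble:
    def test_cohort_ratio_gives_n_aug_2(self):
        # 76 early-stage vs 161 advanced frames -> round(161/76) = 2
        labels = [0] * 76 + [1] * 161
        assert roispec.augmentation_factor(labels) == 2

    def test_balanced_classes_give_n_aug_1(self):
        assert roispec.augmentation_factor([0, 1] * 10) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roispec.augmentation_factor([1, 1, 1])

    @pytest.fixture(scope="class")
    @staticmethod
    def toy_frames():
        frames = []
        for i in range(20):
            stage = 0 if i < 10 else 4
            # 1100-sample run -> 17 gate segments x 16 lines = 272 >= 256
            mask = np.zeros((1247, 16), np.uint8)
            mask[50:1150] = 1
            rng = np.random.default_rng(i)
            frames.append(make_roi(rng.random((1247, 16)) * mask, mask,
                                   label=stage, fid=f"t{i:02d}",
                                   normalized=True))
        return frames

    def test_assembly_shapes_labels_and_purity(self, toy_frames):
        tsk = roispec.task("geF2")
        train, val, test = roispec.balance_and_assemble(
            toy_frames, tsk, ratios=(0.6, 0.2, 0.2), seed=3)
        parts = [train, val, test]
        ids = [set(s.source_frame_id for s in p) for p in parts]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) \
            and not (ids[1] & ids[2])
        for p in parts:
            assert {s.label for s in p} == {0, 1}
            for s in p:
                assert s.values.shape == (768, 256)
        # balanced toy cohort: one window per frame everywhere
        assert len(train) + len(val) + len(test) == 20

    def test_minority_training_frames_are_augmented(self, toy_frames):
        # drop early-stage frames to a 1:2 minority within this cohort
        frames = toy_frames[:5] + toy_frames[10:]
        tsk = roispec.task("geF2")
        train, val, test = roispec.balance_and_assemble(
            frames, tsk, ratios=(0.6, 0.2, 0.2), seed=1)
        by_frame = {}
        for s in train:
            by_frame.setdefault(s.source_frame_id, []).append(s)
        tr_labels = [v[0].label for v in by_frame.values()]
        n_aug = roispec.augmentation_factor(tr_labels)
        minority = 0 if tr_labels.count(0) < tr_labels.count(1) else 1
        for fid, ws in by_frame.items():
            assert len(ws) == (n_aug if ws[0].label == minority else 1)
        # validation/test frames never augmented
        for part in (val, test):
            counts = {}
            for s in part:
                counts[s.source_frame_id] = counts.get(s.source_frame_id, 0) + 1
            assert set(counts.values()) == {1}

    def test_shard_roundtrip(self, toy_frames, tmp_path):
        tsk = roispec.task("geF1")
        train, _, _ = roispec.balance_and_assemble(
            toy_frames, tsk, ratios=(0.6, 0.2, 0.2), seed=0)
        path = roispec.save_samples(train, tmp_path / "train.npz", tsk.name)
        loaded = roispec.load_samples(path)
        assert len(loaded) == len(train)
        np.testing.assert_allclose(loaded[0].values, train[0].values,
                                   rtol=1e-6)


class TestBinaryTask:
    def test_partitions(self):
        t2 = roispec.task("geF2")
        assert t2.positive_stages == frozenset({2, 3, 4})
        assert t2.negative_stages == frozenset({0, 1})
        assert roispec.task(">=F4").positive_stages == frozenset({4})

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            roispec.task("geF5")
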