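"""Detection, kymograph construction, edge extraction, and summaries."""

import numpy as np
import pytest

from nanokymo import kymo, synthdata
from nanokymo.kymo import (EdgeTrack, ImageStack, Kymograph, SegmentBox,
                           build_kymograph, detect_molecules, extract_edges,
                           summarize_molecule)


def test_blank_stack_detects_nothing():
    rng = np.random.default_rng(0)
    frames = 100.0 + np.abs(rng.normal(0, 2, size=(5, 60, 80)))
    stack = ImageStack(frames=frames, pixel_size=110.0, frame_interval=0.1)
    assert detect_molecules(stack) == []


def test_empty_stack_rejected():
    with pytest.raises(ValueError):
        ImageStack(frames=np.zeros((0, 10, 10)), pixel_size=110, frame_interval=0.1)


def test_detection_recovers_ground_truth_positions():
    cfg = synthdata.SimConfig(seed=21)
    stack, truths = synthdata.simulate_kymograph_stack(cfg, 5)
    boxes = detect_molecules(stack)
    assert len(boxes) == 5
    rows = sorted(b.row for b in boxes)
    assert rows == sorted(t.channel_row for t in truths)
    by_row = {b.row: b for b in boxes}
    for t in truths:
        b = by_row[t.channel_row]
        assert b.col_start <= t.center_px <= b.col_stop


def test_close_molecules_merge_into_flagged_box():
    """Two molecules closer than the detection gap produce one flagged box."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(1)
    frames = np.full((4, 30, 200), 0.0)
    row = 10
    frames[:, row, 20:60] += 300.0     # normal-length molecule
    frames[:, 19, 30:70] += 300.0      # another normal molecule
    frames[:, 24, 100:140] += 300.0    # molecule A
    frames[:, 24, 142:182] += 300.0    # molecule B, 2-px gap: PSF bridges it
    frames = gaussian_filter(frames, (0, 1.0, 1.0)) + 100.0
    frames += rng.normal(0, 1, frames.shape)
    stack = ImageStack(frames=np.clip(frames, 0, None), pixel_size=110.0,
                       frame_interval=0.1)
    boxes = detect_molecules(stack, max_length_px=60)
    merged = [b for b in boxes if "suspect_merge" in b.flags]
    assert len(merged) == 1
    assert merged[0].row == 24


def test_single_frame_kymograph_is_transverse_sum():
    frames = np.arange(2 * 9 * 12, dtype=float).reshape(2, 9, 12)[:1]
    stack = ImageStack(frames=frames, pixel_size=110, frame_interval=0.1)
    box = SegmentBox(row=4, col_start=2, col_stop=10)
    km = build_kymograph(stack, box, transverse_half_width=1)
    assert km.matrix.shape == (8, 1)
    expected = frames[0, 3:6, 2:10].sum(axis=0)
    np.testing.assert_allclose(km.matrix[:, 0], expected)


def test_static_molecule_gives_identical_columns():
    cfg = synthdata.SimConfig(seed=2, extension_sd=0.0, bleach_rate=0.0,
                              read_noise_sd=0.0, frame_count=5)
    stack, _ = synthdata.simulate_kymograph_stack(cfg, 1, shot_noise=False)
    box = detect_molecules(stack)[0]
    km = build_kymograph(stack, box)
    first = np.repeat(km.matrix[:, :1], km.matrix.shape[1], axis=1)
    np.testing.assert_allclose(km.matrix, first)


def test_box_outside_bounds_rejected():
    stack = ImageStack(frames=np.ones((2, 10, 10)), pixel_size=110,
                       frame_interval=0.1)
    with pytest.raises(ValueError):
        build_kymograph(stack, SegmentBox(row=5, col_start=0, col_stop=20))


def test_bleaching_kymograph_sums_decay_at_ground_truth_rate():
    cfg = synthdata.SimConfig(seed=8, bleach_rate=0.8, frame_count=25,
                              nick_rate=0.0)
    stack, _ = synthdata.simulate_kymograph_stack(cfg, 10)
    boxes = detect_molecules(stack)
    sums = []
    for b in boxes:
        km = build_kymograph(stack, b)
        col = km.matrix - np.median(km.matrix[:6], axis=0)  # flank background
        sums.append(col.sum(axis=0))
    mean = np.mean(sums, axis=0)
    t = np.arange(25) * cfg.exposure
    slope = np.polyfit(t, np.log(np.clip(mean, 1, None)), 1)[0]
    assert -slope == pytest.approx(0.8, rel=0.15)


class TestExtractEdges:
    def test_noiseless_boxcar_width(self, boxcar_kymo):
        edges = extract_edges(boxcar_kymo, threshold_fraction=0.5)
        ext_px = edges.extension_um / (boxcar_kymo.pixel_size / 1000.0)
        np.testing.assert_allclose(ext_px, 50.0, atol=0.01)
        assert not edges.missing.any()
        assert not edges.split.any()

    def test_two_segments_report_union_and_split_flag(self):
        mat = np.full((80, 3), 10.0)
        mat[10:30, :] = 210.0
        mat[45:70, :] = 210.0
        km = Kymograph(matrix=mat, channel_index=0, origin=(0, 0),
                       pixel_size=100.0, frame_interval=0.1)
        edges = extract_edges(km)
        assert edges.split.all()
        ext_px = edges.extension_um[0] / 0.1
        np.testing.assert_allclose(ext_px, 60.0, atol=0.01)  # union 9.5..69.5

    def test_all_frames_missing_raises(self):
        km = Kymograph(matrix=np.full((40, 4), 7.0), channel_index=0,
                       origin=(3, 0), pixel_size=100.0, frame_interval=0.1)
        with pytest.raises(ValueError, match="origin"):
            extract_edges(km)

    def test_mean_edge_error_below_one_pixel(self, imaging_stack,
                                             imaging_summaries):
        cfg, _stack, truths = imaging_stack
        px = cfg.pixel_size / 1000.0
        errs = [abs(imaging_summaries[t.channel_row].extension_um
                    - t.mean_extension_um) / px
                for t in truths if t.channel_row in imaging_summaries]
        assert len(errs) == len(truths)
        assert np.mean(errs) <= 1.0


class TestSummarize:
    def _kymo(self, n_frames=6):
        mat = np.full((120, n_frames), 10.0)
        mat[10:110, :] = 110.0
        return Kymograph(matrix=mat, channel_index=0, origin=(0, 0),
                         pixel_size=100.0, frame_interval=0.1)

    def test_constant_edges(self):
        km = self._kymo()
        T = km.n_frames
        edges = EdgeTrack(left_um=np.zeros(T), right_um=np.full(T, 10.0),
                          missing=np.zeros(T, bool), split=np.zeros(T, bool))
        s = summarize_molecule(km, edges)
        assert s.extension_um == pytest.approx(10.0)
        assert s.extension_sd_um == 0.0
        assert s.n_frames_used == T

    def test_alternating_edges_population_sd(self):
        km = self._kymo(6)
        right = np.array([10.0, 12.0] * 3)
        edges = EdgeTrack(left_um=np.zeros(6), right_um=right,
                          missing=np.zeros(6, bool), split=np.zeros(6, bool))
        s = summarize_molecule(km, edges)
        assert s.extension_um == pytest.approx(11.0)
        assert s.extension_sd_um == pytest.approx(1.0)   # population SD

    def test_too_few_frames_dropped(self):
        km = self._kymo(4)
        missing = np.array([True, True, False, False])
        edges = EdgeTrack(left_um=np.zeros(4), right_um=np.full(4, 5.0),
                          missing=missing, split=np.zeros(4, bool))
        with pytest.raises(ValueError, match="usable frames"):
            summarize_molecule(km, edges)

    def test_extension_recovery_on_synthetic_set(self, imaging_stack,
                                                 imaging_summaries):
        """Extension and its SD recover the generating values within 3%."""
        cfg, _stack, truths = imaging_stack
        est = np.array([imaging_summaries[t.channel_row].extension_um
                        for t in truths])
        gt = np.array([t.mean_extension_um for t in truths])
        assert abs(est.mean() - gt.mean()) / gt.mean() <= 0.03
        est_sd = np.mean([imaging_summaries[t.channel_row].extension_sd_um
                          for t in truths])
        gt_sd = np.mean([np.std(t.true_extension_um) for t in truths])
        assert abs(est_sd - gt_sd) / gt_sd <= 0.10


class TestInvariances:
    def test_constant_offset_leaves_extension_unchanged(self, imaging_stack):
        _cfg, stack, _ = imaging_stack
        shifted = ImageStack(frames=stack.frames + 250.0,
                             pixel_size=stack.pixel_size,
                             frame_interval=stack.frame_interval)
        b0 = detect_molecules(stack)[0]
        e0 = extract_edges(build_kymograph(stack, b0))
        e1 = extract_edges(build_kymograph(shifted, b0))
        np.testing.assert_allclose(e0.extension_um, e1.extension_um, atol=1e-9)

    def test_doubling_illumination_doubles_intensity_only(self, imaging_stack):
        _cfg, stack, _ = imaging_stack
        doubled = ImageStack(frames=stack.frames * 2.0,
                             pixel_size=stack.pixel_size,
                             frame_interval=stack.frame_interval)
        box = detect_molecules(stack)[0]
        km0 = build_kymograph(stack, box)
        km1 = build_kymograph(doubled, box)
        e0, e1 = extract_edges(km0), extract_edges(km1)
        s0 = summarize_molecule(km0, e0)
        s1 = summarize_molecule(km1, e1)
        assert s1.mean_intensity == pytest.approx(2 * s0.mean_intensity, rel=1e-6)
        assert s1.extension_um == pytest.approx(s0.extension_um, abs=1e-9)
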