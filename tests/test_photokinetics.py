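"""Bleach decay, fragmentation detection/kinetics, and gel densitometry."""

import numpy as np
import pytest

from nanokymo import kymo, photokinetics as pk, synthdata
from nanokymo.photokinetics import (BleachTrace, FragSeries, GelLaneProfile,
                                    detect_fragmentation_event,
                                    fit_bleach_decay,
                                    fit_fragmentation_power_law, quantify_lane)


def _trace(t, a, alpha, b):
    return BleachTrace(time_s=t, intensity=a * np.exp(-alpha * t) + b)


class TestBleachDecay:
    def test_noiseless_exact_recovery(self):
        t = np.linspace(0, 30, 40)
        fit = fit_bleach_decay(_trace(t, 100.0, 0.2, 10.0))
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.alpha == pytest.approx(0.2, rel=1e-6)
        assert fit.offset == pytest.approx(10.0, rel=1e-6)

    def test_constant_trace_degenerate(self):
        t = np.linspace(0, 10, 20)
        fit = fit_bleach_decay(BleachTrace(time_s=t, intensity=np.full(20, 55.0)))
        assert fit.degenerate
        assert fit.alpha == 0.0
        assert fit.offset == pytest.approx(55.0)  # A folded into B

    def test_scaling_equivariance(self):
        """Scaling intensity by c scales A and B by c, alpha unchanged."""
        t = np.linspace(0, 25, 30)
        rng = np.random.default_rng(0)
        y = 80 * np.exp(-0.3 * t) + 5 + rng.normal(0, 0.5, t.size)
        f1 = fit_bleach_decay(BleachTrace(time_s=t, intensity=y))
        f2 = fit_bleach_decay(BleachTrace(time_s=t, intensity=3.0 * y))
        assert f2.alpha == pytest.approx(f1.alpha, rel=1e-6)
        assert f2.amplitude == pytest.approx(3 * f1.amplitude, rel=1e-6)
        assert f2.offset == pytest.approx(3 * f1.offset, rel=1e-6)

    def test_shot_noise_ensemble_recovery(self):
        """500 Poisson-noised traces: mean-trace alpha within 10%."""
        rng = np.random.default_rng(1)
        t = np.arange(0, 30, 0.5)
        traces = [BleachTrace(time_s=t,
                              intensity=rng.poisson(1000 * np.exp(-0.1 * t)
                                                    + 50).astype(float))
                  for _ in range(500)]
        fit = fit_bleach_decay(traces, average_first=True)
        assert fit.alpha == pytest.approx(0.1, rel=0.10)

    def test_per_trace_mode_returns_list(self):
        t = np.linspace(0, 20, 25)
        fits = fit_bleach_decay([_trace(t, 50, 0.2, 2), _trace(t, 70, 0.4, 3)],
                                average_first=False)
        assert [round(f.alpha, 6) for f in fits] == [0.2, 0.4]

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="time grid"):
            fit_bleach_decay([_trace(np.linspace(0, 9, 10), 1, 0.1, 0),
                              _trace(np.linspace(0, 8, 10), 1, 0.1, 0)])


class TestFragmentationDetection:
    def test_never_splitting_molecule_returns_none(self, boxcar_kymo):
        assert detect_fragmentation_event(boxcar_kymo) is None

    def test_single_frame_flicker_ignored(self):
        """A 1-frame split does not survive the persistence filter."""
        mat = np.full((80, 10), 10.0)
        mat[20:60, :] = 210.0
        mat[35:45, 4] = 10.0          # flicker: split in one column only
        km = kymo.Kymograph(matrix=mat, channel_index=0, origin=(0, 0),
                            pixel_size=100.0, frame_interval=0.1)
        assert detect_fragmentation_event(km, persist_frames=3) is None

    def test_persistent_split_detected_at_onset(self):
        mat = np.full((80, 12), 10.0)
        mat[20:60, :] = 210.0
        mat[38:44, 7:] = 10.0          # split persists from frame 7
        km = kymo.Kymograph(matrix=mat, channel_index=0, origin=(0, 0),
                            pixel_size=100.0, frame_interval=0.5)
        assert detect_fragmentation_event(km) == pytest.approx(7 * 0.5)

    def test_synthetic_dsb_detected_within_persistence_window(
            self, photodamage_stack):
        cfg, stack, truths = photodamage_stack
        gt = {t.channel_row: t for t in truths}
        frame_errs, missed = [], 0
        for box in kymo.detect_molecules(stack):
            t = gt.get(box.row)
            if t is None or t.fragmentation_time is None:
                continue
            if t.fragmentation_time > (cfg.frame_count - 8) * cfg.exposure:
                continue   # too close to the end of the movie to persist
            det = detect_fragmentation_event(kymo.build_kymograph(stack, box))
            if det is None:
                missed += 1
            else:
                frame_errs.append(abs(det - t.fragmentation_time) / cfg.exposure)
        assert len(frame_errs) >= 5
        assert missed <= 0.3 * (missed + len(frame_errs))
        assert np.mean(frame_errs) <= 3.0


class TestPowerLaw:
    def test_linear_kinetics_closed_form(self):
        t = np.linspace(0.2, 1.8, 9)
        fit = fit_fragmentation_power_law(FragSeries(t, 1 - 0.5 * t),
                                          isotonic_cleanup=False)
        assert fit.r == pytest.approx(0.5, rel=1e-6)
        assert fit.n_exp == pytest.approx(1.0, rel=1e-6)
        assert fit.t50 == pytest.approx(1.0, rel=1e-6)

    def test_quadratic_kinetics_closed_form(self):
        t = np.linspace(0.3, 3.0, 10)
        fit = fit_fragmentation_power_law(FragSeries(t, 1 - 0.05 * t**2),
                                          isotonic_cleanup=False)
        assert fit.t50 == pytest.approx(np.sqrt(10.0), rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.4, 4.0, 12)
        y = np.clip(0.05 * t**2 * (1 + rng.normal(0, 0.03, t.size)), 0, 1)
        fit = fit_fragmentation_power_law(FragSeries(t, 1 - y))
        assert fit.r == pytest.approx(0.05, rel=0.15)
        assert fit.n_exp == pytest.approx(2.0, rel=0.15)

    def test_t50_time_unit_consistency(self):
        """Rescaling the time grid by c rescales t50 by c (r -> r*c^-n)."""
        t = np.linspace(0.2, 1.8, 9)
        y = 0.3 * t**1.4
        f1 = fit_fragmentation_power_law(FragSeries(t, 1 - y),
                                         isotonic_cleanup=False)
        c = 60.0   # minutes -> seconds
        f2 = fit_fragmentation_power_law(FragSeries(t * c, 1 - y),
                                         isotonic_cleanup=False)
        assert f2.t50 == pytest.approx(c * f1.t50, rel=1e-6)
        assert f2.r == pytest.approx(f1.r * c**-f1.n_exp, rel=1e-4)

    def test_no_fragmentation_raises(self):
        with pytest.raises(ValueError, match="no fragmentation"):
            fit_fragmentation_power_law(
                FragSeries(np.arange(1.0, 6.0), np.ones(5)))


class TestQuantifyLane:
    def test_fully_intact_lane(self):
        lane = synthdata.simulate_gel_lanes([1.0])[0]
        intact, frag = quantify_lane(lane)
        assert intact == pytest.approx(1.0, abs=0.01)
        assert frag == pytest.approx(0.0, abs=0.01)

    def test_half_fragmented_round_trip(self):
        lane = synthdata.simulate_gel_lanes([0.5])[0]
        intact, frag = quantify_lane(lane)
        assert intact == pytest.approx(0.5, abs=0.02)
        assert frag == pytest.approx(0.5, abs=0.02)
        assert intact + frag == pytest.approx(1.0)

    def test_exposure_scale_invariance(self):
        lane = synthdata.simulate_gel_lanes([0.7])[0]
        scaled = GelLaneProfile(position=lane.position,
                                intensity=lane.intensity * 37.0,
                                band_window=lane.band_window)
        assert quantify_lane(lane) == pytest.approx(quantify_lane(scaled))

    def test_baseline_offset_invariance(self):
        lane = synthdata.simulate_gel_lanes([0.6])[0]
        shifted = GelLaneProfile(position=lane.position,
                                 intensity=lane.intensity + 42.0,
                                 band_window=lane.band_window)
        i0, _ = quantify_lane(lane)
        i1, _ = quantify_lane(shifted)
        assert i1 == pytest.approx(i0, abs=0.01)

    def test_band_window_autolocated_from_dominant_peak(self):
        lane = synthdata.simulate_gel_lanes([0.5])[0]
        blind = GelLaneProfile(position=lane.position, intensity=lane.intensity)
        intact, _ = quantify_lane(blind)
        assert intact == pytest.approx(0.5, abs=0.05)

    def test_zero_signal_raises(self):
        lane = GelLaneProfile(position=np.arange(100.0),
                              intensity=np.zeros(100), band_window=(10, 30))
        with pytest.raises(ValueError, match="zero total signal"):
            quantify_lane(lane)
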