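import numpy as np
import pytest

from polkin import changepoint as cp
from polkin import synthgen
from polkin.polarimetry import Calibration


def make_trace(counts, bg=0.0, dt=0.01):
    return cp.PolarizedTrace(np.asarray(counts),
                             frame_interval=dt,
                             calibration=Calibration(backgrounds=(bg,) * 4))


class TestSegmentLLR:
    def test_exactly_zero_for_identical_halves(self):
        seg = np.tile([5, 7, 3, 9], (40, 1))
        assert cp.segment_llr(seg, 20) == pytest.approx(0.0, abs=1e-9)

    def test_additive_over_channels(self):
        rng = np.random.default_rng(0)
        seg = rng.poisson(6, size=(60, 4))
        seg[30:, 2] += 15                      # only one channel changes
        total = cp.segment_llr(seg, 30)
        single = cp._llr_profile_1d(seg[:, 2])[29]
        others = sum(cp._llr_profile_1d(seg[:, c])[29] for c in (0, 1, 3))
        assert np.isclose(total, single + others)

    def test_maximized_near_true_split(self):
        rng = np.random.default_rng(1)
        seg = np.concatenate([rng.poisson(20, size=(100, 4)),
                              rng.poisson(40, size=(100, 4))])
        prof = cp.llr_profile(seg)
        # grid-evaluation oracle: the profile peak sits at the rate change
        assert abs(int(np.argmax(prof)) + 1 - 100) <= 2
        assert prof.max() > 50

    def test_split_bounds(self):
        with pytest.raises(ValueError):
            cp.segment_llr(np.ones((10, 4)), 0)
        with pytest.raises(ValueError):
            cp.segment_llr(np.ones((10, 4)), 10)


class TestThresholdCalibration:
    def test_confidence_monotone(self):
        t95 = cp.calibrate_threshold(200, 80, 0.95, n_null=300, seed=4)
        t99 = cp.calibrate_threshold(200, 80, 0.99, n_null=300, seed=4)
        assert t99 > t95

    def test_grows_with_trace_length(self):
        t_short = cp.calibrate_threshold(100, 80, 0.95, n_null=300, seed=5)
        t_long = cp.calibrate_threshold(1600, 80, 0.95, n_null=300, seed=5)
        assert t_long > t_short

    def test_self_consistent_false_positive_rate(self):
        thr = cp.calibrate_threshold(300, 100, 0.95, n_null=600, seed=6)
        rng = np.random.default_rng(7)
        exceed = 0
        n = 400
        for _ in range(n):
            counts = rng.poisson(25, size=(300, 4))
            exceed += cp.llr_profile(counts).max() > thr
        # 99% binomial interval around 5%
        assert abs(exceed / n - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / n) + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cp.calibrate_threshold(100, 50, confidence=0.4)
        with pytest.raises(ValueError):
            cp.calibrate_threshold(100, 50, n_null=50)


class TestDetection:
    def test_single_large_step_located(self, thresholds):
        rng = np.random.default_rng(8)
        counts = np.concatenate([rng.poisson([40, 20, 10, 30], size=(500, 4)),
                                 rng.poisson([10, 30, 40, 20], size=(500, 4))])
        res = cp.detect_changepoints(make_trace(counts), thresholds=thresholds)
        assert len(res.changepoints) == 1
        assert abs(res.changepoints[0] - 500) <= 1
        assert res.llr_ratio[0] >= 1.0

    def test_two_steps_recovered_in_order(self, thresholds):
        rng = np.random.default_rng(9)
        counts = np.concatenate([rng.poisson([40, 20, 10, 30], size=(300, 4)),
                                 rng.poisson([10, 30, 40, 20], size=(300, 4)),
                                 rng.poisson([40, 20, 10, 30], size=(300, 4))])
        res = cp.detect_changepoints(make_trace(counts), thresholds=thresholds)
        assert len(res.changepoints) == 2
        assert abs(res.changepoints[0] - 300) <= 2
        assert abs(res.changepoints[1] - 600) <= 2

    def test_channel_relabeling_invariance(self, thresholds):
        rng = np.random.default_rng(10)
        counts = np.concatenate([rng.poisson([40, 20, 10, 30], size=(200, 4)),
                                 rng.poisson([15, 35, 30, 10], size=(200, 4))])
        a = cp.detect_changepoints(make_trace(counts), thresholds=thresholds)
        b = cp.detect_changepoints(make_trace(counts[:, [2, 0, 3, 1]]),
                                   thresholds=thresholds)
        assert np.array_equal(a.changepoints, b.changepoints)

    def test_too_short_trace(self, thresholds):
        with pytest.raises(ValueError):
            cp.PolarizedTrace(np.ones((1, 4)))


class TestEvents:
    def test_no_changepoints_single_event(self, thresholds):
        counts = np.random.default_rng(0).poisson(10, size=(50, 4))
        trace = make_trace(counts)
        res = cp.ChangePointResult(np.array([], dtype=int), np.array([]))
        events = cp.build_events(trace, res)
        assert len(events) == 1
        assert events.loc[0, "start"] == 0 and events.loc[0, "end"] == 50

    def test_short_event_means_are_segment_means(self):
        counts = np.arange(8 * 4).reshape(8, 4)
        trace = make_trace(counts)
        res = cp.ChangePointResult(np.array([2]), np.array([2.0]))
        events = cp.build_events(trace, res)
        # 2-frame event: plain mean; longer events average interior frames
        assert np.allclose(events.loc[0, ["I0", "I45", "I90", "I135"]],
                           counts[:2].mean(axis=0))
        assert np.allclose(events.loc[1, ["I0", "I45", "I90", "I135"]],
                           counts[3:7].mean(axis=0))

    def test_orientation_se_shrinks_with_dwell_length(self, truth):
        rng = np.random.default_rng(2)
        spec = synthgen.TraceSpec(n_frames=64, bleach_time=None)
        expect = np.array(
            [synthgen.polarimetry.forward_intensities(truth.orientations[2],
                                                      truth.delta_deg, spec.photon_rate)])
        sds = {}
        for frames in (2, 32):
            phis = []
            for _ in range(200):
                counts = rng.poisson(np.repeat(expect, frames, axis=0))
                o = synthgen.polarimetry.estimate_angles(
                    *counts.mean(axis=0),
                    cal=Calibration(delta_deg=truth.delta_deg))
                phis.append(o.phi_deg)
            sds[frames] = np.std(phis)
        # SE scales roughly as 1/sqrt(frames): 16x frames -> ~4x smaller
        assert sds[32] < sds[2] / 2.5


class TestParticleQC:
    def test_too_few_events_rejected(self, truth, thresholds):
        spec = synthgen.TraceSpec(n_frames=120, bleach_time=None)
        rng = np.random.default_rng(0)
        times = np.array([0.0, spec.n_frames * spec.frame_interval + 1])
        counts = synthgen.render_trace(times, np.array([0]), truth, spec, seed=3)
        trace = cp.PolarizedTrace(counts, calibration=Calibration(
            delta_deg=truth.delta_deg, backgrounds=(spec.background_rate,) * 4))
        kept, rejected = cp.filter_particles([trace], thresholds=thresholds)
        assert not kept
        assert rejected[0][1] == "too few events"

    def test_two_bleach_steps_rejected(self, truth, thresholds):
        spec = synthgen.TraceSpec(n_frames=400, bleach_time=2.5)
        times = np.array([0.0, 5.0])
        counts = synthgen.render_trace(times, np.array([0]), truth, spec, seed=4,
                                       second_fluor_bleach_time=1.2)
        trace = cp.PolarizedTrace(counts, calibration=Calibration(
            delta_deg=truth.delta_deg, backgrounds=(spec.background_rate,) * 4))
        kept, rejected = cp.filter_particles([trace], thresholds=thresholds)
        assert not kept
        assert rejected[0][1] == "multiple bleach steps"

    def test_low_snr_rejected(self, thresholds):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5.5, size=(300, 4))   # signal barely above background
        trace = cp.PolarizedTrace(counts, calibration=Calibration(backgrounds=(5,) * 4))
        kept, rejected = cp.filter_particles([trace], thresholds=thresholds)
        assert not kept
        assert rejected[0][1] == "low SNR"

    def test_compliant_particle_kept(self, truth, small_spec, small_traces, thresholds):
        kept, rejected = cp.filter_particles(small_traces[:3], thresholds=thresholds)
        assert len(kept) >= 2
        for k in kept:
            assert len(k["events"]) >= 15
            assert k["snr"] > 5
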