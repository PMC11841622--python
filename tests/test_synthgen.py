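import numpy as np
import pytest
from scipy import stats

from polkin import dwellkin, polarimetry, synthgen
from polkin.polarimetry import SphericalOrientation


class TestGroundTruth:
    def test_adic_like_serial_rates_markedly_slower(self):
        t = synthgen.make_ground_truth("adic-like", 1)
        for lig in (None, "arg", "agm"):
            b = t.rates.branch(lig)
            serial_fwd = [b[(i, i + 4)] for i in range(1, 5)]
            others = [v for k, v in b.items()
                      if k not in [(i, i + 4) for i in range(1, 5)]]
            assert max(serial_fwd) * 5 <= np.median(others)

    def test_deterministic_given_seed(self):
        a = synthgen.make_ground_truth("random", 7)
        b = synthgen.make_ground_truth("random", 7)
        assert a.rates.apo == b.rates.apo
        assert a.kd == b.kd

    def test_seed_sensitivity(self):
        a = synthgen.make_ground_truth("random", 7)
        c = synthgen.make_ground_truth("random", 8)
        assert a.rates.apo != c.rates.apo

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            synthgen.make_ground_truth("nope", 0)

    def test_invariants_hold(self):
        t = synthgen.make_ground_truth("adic-like", 3)
        assert all(v > 0 for v in t.rates.apo.values())
        assert all(0 <= o.theta_deg <= 90 and -90 < o.phi_deg <= 90
                   for o in t.orientations)
        assert 0 <= t.delta_deg < polarimetry.MAX_DELTA_DEG

    def test_eq3_structure_of_apparent_rates(self, truth):
        # apparent rates interpolate apo -> bound with midpoint K_D(start)
        pair = (2, 6)
        kd = truth.kd["arg"][2]
        mid = truth.apparent_rates("arg", kd)[pair]
        assert mid == pytest.approx(
            (truth.rates.apo[pair] + truth.rates.arg[pair]) / 2)


class TestRenderTrace:
    def test_expected_channels_at_reference_orientation(self):
        t = synthgen.make_ground_truth("adic-like", 1)
        spec = synthgen.TraceSpec(n_frames=20000, photon_rate=100,
                                  background_rate=0.0, bleach_time=None)
        times = np.array([0.0, spec.n_frames * spec.frame_interval + 1])
        path = np.array([0])
        orients = [SphericalOrientation(90, 0)] * 4
        tweaked = synthgen.GroundTruth(rates=t.rates, kd=t.kd,
                                       orientations=tuple(orients),
                                       delta_deg=0.0, seed=0)
        counts = synthgen.render_trace(times, path, tweaked, spec, seed=2)
        means = counts.mean(axis=0)
        n = spec.n_frames
        se = np.sqrt(np.array([50, 25, 1e-9, 25]) / n)
        assert abs(means[0] - 50.0) < 4 * se[0]    # I0 = Itot/2
        assert means[2] == 0                       # I90 = 0
        assert abs(means[1] - 25.0) < 4 * se[1]
        assert abs(means[3] - 25.0) < 4 * se[3]

    def test_total_intensity_conserved_in_expectation(self, truth):
        spec = synthgen.TraceSpec(n_frames=40000, bleach_time=None)
        q = truth.generator8(None, 0)
        times, st = synthgen.simulate_ctmc(q, spec.n_frames * spec.frame_interval + 1,
                                           seed=5)
        t2, confs = synthgen.conformation_path(times, st)
        counts = synthgen.render_trace(t2, confs, truth, spec, seed=6)
        expected = spec.photon_rate + 4 * spec.background_rate
        tot = counts.sum(axis=1)
        assert tot.mean() == pytest.approx(expected, rel=4 * np.sqrt(expected)
                                           / np.sqrt(len(tot)) / expected)

    def test_single_step_bleach(self, truth):
        spec = synthgen.TraceSpec(n_frames=300, bleach_time=1.5)
        times = np.array([0.0, 3.1])
        counts = synthgen.render_trace(times, np.array([0]), truth, spec, seed=7)
        pre = counts[:140].sum(axis=1).mean()
        post = counts[160:].sum(axis=1).mean()
        assert pre > 300
        assert post == pytest.approx(4 * spec.background_rate, rel=0.2)

    def test_empty_path_rejected(self, truth):
        with pytest.raises(ValueError):
            synthgen.render_trace(np.array([0.0]), np.array([]), truth,
                                  synthgen.TraceSpec(), seed=0)

    def test_path_must_cover_duration(self, truth):
        with pytest.raises(ValueError):
            synthgen.render_trace(np.array([0.0, 1.0]), np.array([0]), truth,
                                  synthgen.TraceSpec(n_frames=500), seed=0)

    def test_noiseless_intensities_invert_to_ground_truth(self, truth):
        # polarimetry round trip at infinite photon rate: use the expected
        # intensities directly
        for o in truth.orientations:
            i = polarimetry.forward_intensities(o, truth.delta_deg, 1e6)
            e = polarimetry.estimate_angles(
                *i, cal=polarimetry.Calibration(delta_deg=truth.delta_deg))
            assert abs(e.theta_deg - o.theta_deg) < 1e-5
            assert abs(e.phi_deg - o.phi_deg) < 1e-7


class TestDwellStatistics:
    def test_simulated_dwells_match_analytic_mixture(self, truth):
        q = truth.generator8(None, 0)
        times, st = synthgen.simulate_ctmc(q, 12000.0, seed=8)
        t2, confs = synthgen.conformation_path(times, st)
        dwells = np.diff(t2)[confs == 0]
        assert dwells.size > 8000
        l1, l2, f = truth.analytic_dwell_params(None, 0, 1)

        def mixture_cdf(x):
            return f * (1 - np.exp(-l1 * x)) + (1 - f) * (1 - np.exp(-l2 * x))

        d, p = stats.kstest(dwells, mixture_cdf)
        assert p > 0.01


class TestFluxDataset:
    def test_zero_noise_is_deterministic_model_curve(self, truth):
        proto = synthgen.make_flux_protocol(5e-5, 5e-3, rv=50, t_max=200,
                                            n_points=8, volume_int=2e2)
        a = synthgen.make_flux_dataset(truth, proto, noise_cv=0.0, seed=1)
        b = synthgen.make_flux_dataset(truth, proto, noise_cv=0.0, seed=99)
        assert np.allclose(a.fractional_uptake, b.fractional_uptake)

    def test_seeded_noise_reproducible(self, truth):
        proto = synthgen.make_flux_protocol(5e-5, 5e-3, rv=50, t_max=200,
                                            n_points=8, volume_int=2e2)
        a = synthgen.make_flux_dataset(truth, proto, noise_cv=0.1, seed=5)
        b = synthgen.make_flux_dataset(truth, proto, noise_cv=0.1, seed=5)
        c = synthgen.make_flux_dataset(truth, proto, noise_cv=0.1, seed=6)
        assert np.allclose(a.fractional_uptake, b.fractional_uptake)
        assert not np.allclose(a.fractional_uptake, c.fractional_uptake)

    def test_negative_noise_rejected(self, truth):
        proto = synthgen.make_flux_protocol(5e-5, 5e-3, rv=50, t_max=10)
        with pytest.raises(ValueError):
            synthgen.make_flux_dataset(truth, proto, noise_cv=-0.1)

    def test_symmetric_long_time_partition(self, truth):
        # same substrate at the same concentration on both sides: the tracer
        # ends up distributed by volume, F -> 1/(1+rv)
        proto = synthgen.make_flux_protocol(1e-4, 1e-4, rv=4, t_max=12000,
                                            n_points=10, volume_int=1e5)
        df = synthgen.make_flux_dataset(truth, proto, noise_cv=0.0, seed=0)
        assert df.fractional_uptake.iloc[-1] == pytest.approx(0.2, rel=0.03)
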