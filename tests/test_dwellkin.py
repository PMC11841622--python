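import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polkin import dwellkin as dk

DT = 0.01


def sample_span(lam, n, rng, dt=DT):
    """Monte Carlo oracle for the frame-span law."""
    u = rng.uniform(0, dt, n)
    t = rng.exponential(1 / lam, n)
    return np.floor((u + t) / dt).astype(int) + 1


class TestDwellPmf:
    @pytest.mark.parametrize("lam", [0.7, 12.0, 90.0])
    def test_normalization(self, lam):
        k = np.arange(1, 5000)
        assert dk.dwell_pmf(lam, DT, k).sum() == pytest.approx(1.0, abs=1e-9)

    def test_small_rate_limit_is_geometric(self):
        lam = 0.5                       # lam*dt = 0.005
        k = np.arange(1, 2000)
        pmf = dk.dwell_pmf(lam, DT, k)
        mean = (k * pmf).sum()
        assert mean == pytest.approx(1 / (lam * DT) + 0.5, rel=0.01)
        ratio = pmf[10:100] / pmf[9:99]
        assert np.allclose(ratio, np.exp(-lam * DT), rtol=1e-6)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(0)
        lam, n = 17.0, 10 ** 6
        spans = sample_span(lam, n, rng)
        kmax = 40
        emp = np.bincount(spans, minlength=kmax + 1)[1:kmax] / n
        pred = dk.dwell_pmf(lam, DT, np.arange(1, kmax))
        z = np.abs(emp - pred) / np.sqrt(pred * (1 - pred) / n)
        assert z.max() < 3.5

    def test_boundary_convention_is_shifted_span_law(self):
        rng = np.random.default_rng(1)
        lam, n = 17.0, 10 ** 6
        u = rng.uniform(0, DT, n)
        t = rng.exponential(1 / lam, n)
        det = np.floor((u + t) / DT + 0.5).astype(int) - np.floor(u / DT + 0.5).astype(int)
        det = det[det >= 1]
        kmax = 40
        emp = np.bincount(det, minlength=kmax + 1)[1:kmax] / det.size
        pred = dk.dwell_mixture_pmf(lam, lam, 1.0, DT, np.arange(1, kmax),
                                    1, "boundary")
        z = np.abs(emp - pred) / np.sqrt(pred * (1 - pred) / det.size)
        assert z.max() < 3.5

    def test_truncation_renormalizes(self):
        k = np.arange(3, 4000)
        assert dk.dwell_pmf(8.0, DT, k, k_min=3).sum() == pytest.approx(1.0, abs=1e-9)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            dk.dwell_pmf(5.0, DT, np.array([0, 1]))

    def test_missed_merge_pmf_reduces_to_plain_at_mu_zero(self):
        k = np.arange(1, 200)
        a = dk.serial_missed_pmf(7.0, 0.4, 1.0, 0.0, 50.0, DT, k)
        l1, l2, f = dk.forward_serial(7.0, 0.4, 1.0)
        b = dk.dwell_mixture_pmf(l1, l2, f, DT, k)
        assert np.allclose(a, b)

    def test_missed_merge_pmf_normalized(self):
        k = np.arange(1, 6000)
        p = dk.serial_missed_pmf(7.0, 0.4, 1.0, 0.12, 50.0, DT, k)
        assert p.sum() == pytest.approx(1.0, abs=1e-7)
        assert (p > 0).all()


class TestFitDwell:
    def test_single_exponential_recovery(self):
        rng = np.random.default_rng(2)
        k = sample_span(10.0, 10 ** 4, rng)
        fit = dk.fit_dwell(k, DT, ncomp=1)
        assert fit.lambda1 == pytest.approx(10.0, rel=0.05)

    def test_mixture_recovery(self):
        rng = np.random.default_rng(3)
        n = 10 ** 4
        comp = rng.random(n) < 0.6
        t = np.where(comp, rng.exponential(1 / 50, n), rng.exponential(1 / 2, n))
        k = np.floor((rng.uniform(0, DT, n) + t) / DT).astype(int) + 1
        fit = dk.fit_dwell(k, DT, ncomp=2)
        assert fit.lambda1 == pytest.approx(50.0, rel=0.10)
        assert fit.lambda2 == pytest.approx(2.0, rel=0.10)
        assert fit.f == pytest.approx(0.6, abs=0.06)

    def test_censored_dwells_restore_slow_component(self):
        # exclude every dwell above a cutoff, then hand them back censored
        rng = np.random.default_rng(4)
        n = 6000
        comp = rng.random(n) < 0.9
        t = np.where(comp, rng.exponential(1 / 10, n), rng.exponential(1 / 0.8, n))
        k = np.floor((rng.uniform(0, DT, n) + t) / DT).astype(int) + 1
        cutoff = 150
        observed, censored = k[k <= cutoff], np.full((k > cutoff).sum(), cutoff)
        biased = dk.fit_dwell(observed, DT, ncomp=2, seed=1)
        fixed = dk.fit_dwell(observed, DT, ncomp=2, seed=1, censored=censored)
        truth = 0.8
        assert abs(np.log(fixed.lambda2 / truth)) < abs(np.log(biased.lambda2 / truth))

    def test_requires_enough_dwells(self):
        with pytest.raises(ValueError):
            dk.fit_dwell(np.arange(1, 20), DT, ncomp=2)


class TestFTest:
    def test_equal_fits_give_p_one(self):
        fit = dk.DwellFitResult(10, 10, 1.0, -100.0, 500, ncomp=1)
        fit2 = dk.DwellFitResult(11, 9, 0.5, -100.0, 500, ncomp=2)
        assert dk.ftest_components(fit, fit2, 500) == 1.0

    def test_strong_mixture_rejected_overwhelmingly(self):
        rng = np.random.default_rng(5)
        n = 3000
        comp = rng.random(n) < 0.55
        t = np.where(comp, rng.exponential(1 / 60, n), rng.exponential(1 / 1.5, n))
        k = np.floor((rng.uniform(0, DT, n) + t) / DT).astype(int) + 1
        f1 = dk.fit_dwell(k, DT, ncomp=1)
        f2 = dk.fit_dwell(k, DT, ncomp=2)
        assert dk.ftest_components(f1, f2, n) < 1e-15

    def test_single_exponential_usually_accepted(self):
        rng = np.random.default_rng(6)
        k = sample_span(8.0, 2000, rng)
        f1 = dk.fit_dwell(k, DT, ncomp=1)
        f2 = dk.fit_dwell(k, DT, ncomp=2, n_restarts=4)
        assert dk.ftest_components(f1, f2, 2000) > 0.01


class TestSerialScheme:
    def test_reference_eigen_solution(self):
        l1, l2, f = dk.forward_serial(10.0, 2.0, 1.0)
        assert l1 == pytest.approx(12.178908, rel=1e-6)
        assert l2 == pytest.approx(0.821092, rel=1e-6)
        assert f == pytest.approx(0.808158, rel=1e-6)
        k_inter, k_ab, k_ba = dk.invert_serial_scheme(l1, l2, f, [0.2, 0.3, 0.5])
        assert k_inter.sum() == pytest.approx(10.0)
        assert k_ab == pytest.approx(2.0)
        assert k_ba == pytest.approx(1.0)

    @given(st.floats(np.log(0.05), np.log(200)), st.floats(np.log(0.05), np.log(200)),
           st.floats(np.log(0.05), np.log(200)))
    @settings(max_examples=300, deadline=None)
    def test_round_trip_identity(self, lko, lka, lkb):
        ko, ka, kb = np.exp([lko, lka, lkb])
        l1, l2, f = dk.forward_serial(ko, ka, kb)
        k_inter, k_ab, k_ba = dk.invert_serial_scheme(l1, l2, f, [1 / 3] * 3)
        assert np.isclose(k_inter.sum(), ko, rtol=1e-8)
        assert np.isclose(k_ab, ka, rtol=1e-8)
        assert np.isclose(k_ba, kb, rtol=1e-8)
        # spectral invariants of the scheme
        assert np.isclose(l1 + l2, ko + ka + kb, rtol=1e-12)
        assert np.isclose(l1 * l2, ko * kb, rtol=1e-12)

    def test_boundary_f_flagged(self):
        with pytest.raises(dk.NonPhysicalRatesError):
            dk.invert_serial_scheme(10.0, 1.0, 1.0, [1 / 3] * 3)

    def test_probability_row_must_normalize(self):
        l1, l2, f = dk.forward_serial(10.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            dk.invert_serial_scheme(l1, l2, f, [0.2, 0.2, 0.2])


class TestConcentrationFits:
    def test_isotherm_endpoints(self):
        assert dk.isotherm(2.0, 8.0, 0.0, 1e-4) == 2.0
        assert dk.isotherm(2.0, 8.0, 1e2, 1e-4) == pytest.approx(8.0, rel=1e-4)
        assert dk.isotherm(2.0, 8.0, 1e-4, 1e-4) == pytest.approx(5.0)

    def test_fit_eq3_recovers_exact_isotherms(self, truth):
        concs = [0.0] + list(np.geomspace(1e-5, 2e-3, 7))
        appk = {}
        for lig in ("arg", "agm"):
            for c in concs:
                key = ("apo", 0.0) if c == 0 else (lig, c)
                appk[key] = truth.apparent_rates(None if c == 0 else lig, c)
        rates = dk.fit_eq3(appk)
        for pair in dk.TRANSITIONS:
            assert rates.apo[pair] == pytest.approx(truth.rates.apo[pair], rel=0.02)
            assert rates.arg[pair] == pytest.approx(truth.rates.arg[pair], rel=0.05)

    def test_stationary_two_state(self):
        rates = {p: 1e-12 for p in dk.TRANSITIONS}
        rates[(1, 2)], rates[(2, 1)] = 1.0, 3.0
        p = dk.energetic_state_probabilities(rates)
        assert p[0] / p[1] == pytest.approx(3.0, rel=1e-6)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()

    def test_stationary_matches_gillespie_occupancy(self, truth):
        from polkin import synthgen
        q = truth.generator8("arg", 1e-4)
        p = dk.stationary_distribution(q)
        times, states = synthgen.simulate_ctmc(q, 3000.0, seed=9)
        occ = np.zeros(8)
        np.add.at(occ, states, np.diff(times))
        occ /= occ.sum()
        assert np.abs(occ - p).max() < 0.02

    def test_fit_equilibrium_recovers_constants(self, truth):
        concs = [0.0] + list(np.geomspace(1e-5, 2e-3, 7))
        p_by = {}
        for lig in ("arg", "agm"):
            for c in concs:
                key = ("apo", 0.0) if c == 0 else (lig, c)
                p_by[key] = dk.energetic_state_probabilities(
                    truth.apparent_rates(None if c == 0 else lig, c))
        eq = dk.fit_equilibrium(p_by)
        assert eq.k_i1[0] == 1.0
        for lig in ("arg", "agm"):
            # detailed-balance ground truth: the cycle K_D's are exact
            kd_true = np.array([truth.kd[lig][i] for i in range(1, 9)])
            assert eq.kd1[lig] == pytest.approx(kd_true[0], rel=0.15)
            kd_fit = eq.kd(lig)
            for s in (6, 7):      # the consequential open-state constants
                assert kd_fit[s - 1] == pytest.approx(kd_true[s - 1], rel=0.15)

    def test_global_fit_serial_recovers_curves(self, truth):
        rng = np.random.default_rng(11)
        concs = [0.0] + list(np.geomspace(2e-5, 1e-3, 4))
        dwell_sets = {}
        for c in concs:
            key = ("apo", 0.0) if c == 0 else ("arg", c)
            ko = sum(truth.apparent_rates(None if c == 0 else "arg", c)[(1, j)]
                     for j in (2, 3, 4))
            appk = truth.apparent_rates(None if c == 0 else "arg", c)
            l1, l2, f = dk.forward_serial(ko, appk[(1, 5)], appk[(5, 1)])
            n = 3000
            comp = rng.random(n) < f
            t = np.where(comp, rng.exponential(1 / l1, n), rng.exponential(1 / l2, n))
            dwell_sets[key] = np.floor((rng.uniform(0, DT, n) + t) / DT).astype(int) + 1
        gf = dk.global_fit_serial(dwell_sets, DT, seed=0)
        appk0 = truth.apparent_rates(None, 0)
        assert gf["params"]["k_ab"][None] == pytest.approx(appk0[(1, 5)], rel=0.2)
        assert gf["params"]["k_ba"][None] == pytest.approx(appk0[(5, 1)], rel=0.2)


class TestGlobalFitSingleLigand:
    def test_lambda_level_global_fit_recovers_apo_and_khalf(self, truth):
        rng = np.random.default_rng(21)
        concs = [0.0, 3e-5, 1e-4, 3e-4, 1e-3]
        dwell_sets = {}
        for c in concs:
            l1, l2, f = truth.analytic_dwell_params(None if c == 0 else "arg", c, 2)
            n = 4000
            comp = rng.random(n) < f
            t = np.where(comp, rng.exponential(1 / l1, n), rng.exponential(1 / l2, n))
            dwell_sets[c] = np.floor((rng.uniform(0, DT, n) + t) / DT).astype(int) + 1
        res = dk.global_fit(dwell_sets, DT, seed=0)
        l1_apo, l2_apo, f_apo = truth.analytic_dwell_params(None, 0, 2)
        assert res["lambda1_apo"] == pytest.approx(l1_apo, rel=0.1)
        assert res["lambda2_apo"] == pytest.approx(l2_apo, rel=0.2)
        assert res["f_apo"] == pytest.approx(f_apo, abs=0.03)
        assert res["khalf_bracketed"]
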