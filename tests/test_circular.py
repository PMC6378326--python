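"""Circular statistics: estimators, tests, PLF, synchrony scan."""

import numpy as np
import pytest
from scipy import stats as ss

from ripplelock.core import TimeSeries
from ripplelock.circular import (
    CircularSample,
    circ_mean_kappa,
    equal_kappa_test,
    event_phase_locking,
    kappa_from_r,
    phase_locking_factor,
    phase_synchrony_scan,
    rayleigh_test,
    watson_williams_test,
)
from ripplelock.signals import analytic_phase_amplitude


class TestEstimators:
    def test_constant_angles(self):
        mu, R, kappa = circ_mean_kappa(np.full(20, 0.56))
        assert mu == pytest.approx(0.56)
        assert R == pytest.approx(1.0)
        assert kappa > 1e6

    def test_uniform_grid_zero_resultant(self):
        th = np.linspace(-np.pi, np.pi, 1001)[:-1]
        _, R, kappa = circ_mean_kappa(th)
        assert R < 1e-10
        assert kappa < 1e-9

    def test_kappa_recovery_within_bootstrap_ci(self, rng):
        for true_kappa in (0.32, 1.08):
            th = rng.vonmises(0.2, true_kappa, 10_000)
            boots = [
                circ_mean_kappa(rng.choice(th, th.size, replace=True))[2]
                for _ in range(200)
            ]
            lo, hi = np.percentile(boots, [2.5, 97.5])
            assert lo <= true_kappa <= hi

    def test_kappa_monotone_in_r(self):
        r = np.linspace(0, 0.999, 200)
        k = kappa_from_r(r)
        assert k[0] == 0.0
        assert np.all(np.diff(k) >= -1e-9)


class TestRayleigh:
    def test_identical_angles_tiny_p(self):
        res = rayleigh_test(np.full(50, 1.0))
        assert res.pvalue < 1e-10

    def test_statistic_matches_brute_force(self):
        th = np.array([0.1, 0.5, -0.3, 2.0, 1.1])
        res = rayleigh_test(th)
        R = np.abs(np.exp(1j * th).mean())
        assert res.statistic == pytest.approx(5 * R**2)

    def test_type_one_error_calibrated(self, rng):
        n, reps = 100, 2000
        th = rng.uniform(-np.pi, np.pi, (reps, n))
        R = np.abs(np.exp(1j * th).mean(axis=1)) * n
        p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
        assert 0.04 <= np.mean(p < 0.05) <= 0.06
        # implementation agrees with the vectorized oracle
        assert rayleigh_test(th[0]).pvalue == pytest.approx(p[0])

    def test_small_sample_flagged(self):
        assert not rayleigh_test(np.array([0.0, 1.0, 2.0])).valid


class TestWatsonWilliams:
    def test_identical_samples_f_near_zero(self, rng):
        th = rng.vonmises(0.5, 2.0, 200)
        res = watson_williams_test(th, th.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.pvalue > 0.99

    def test_power_on_separated_means(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.vonmises(0.56, 1.0, 500)
            b = rng.vonmises(0.18, 1.0, 500)
            hits += watson_williams_test(a, b).pvalue < 0.05
        assert hits / 200 >= 0.90

    def test_type_one_error_calibrated(self, rng):
        rej = sum(
            watson_williams_test(
                rng.vonmises(0.5, 2.0, 100), rng.vonmises(0.5, 2.0, 100)
            ).pvalue < 0.05
            for _ in range(2000)
        )
        assert 0.04 <= rej / 2000 <= 0.06

    def test_low_concentration_flagged(self, rng):
        res = watson_williams_test(
            rng.vonmises(0, 0.2, 100), rng.vonmises(0, 0.2, 100)
        )
        assert not res.valid


class TestEqualKappa:
    def test_identical_samples_not_significant(self, rng):
        th = rng.vonmises(0.0, 1.0, 300)
        assert equal_kappa_test(th, th.copy()).pvalue > 0.5

    def test_power_on_study_concentrations(self, rng):
        hits = 0
        for _ in range(200):
            a = rng.vonmises(0.56, 1.08, 1000)
            b = rng.vonmises(0.18, 0.32, 1000)
            hits += equal_kappa_test(a, b).pvalue < 0.05
        assert hits / 200 >= 0.90

    def test_rank_statistic_matches_scipy(self, rng):
        # dual implementation: hand-coded U statistic vs scipy oracle
        a = CircularSample(rng.vonmises(0.5, 1.0, 80))
        b = CircularSample(rng.vonmises(0.1, 0.4, 60))
        res = equal_kappa_test(a, b, method="rank")
        from ripplelock.circular import _angular_deviations

        da, db = _angular_deviations(a), _angular_deviations(b)
        ref = ss.mannwhitneyu(da, db, alternative="two-sided", method="asymptotic",
                              use_continuity=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_type_one_error_calibrated(self, rng):
        rej = sum(
            equal_kappa_test(
                rng.vonmises(0, 2.0, 100), rng.vonmises(0, 2.0, 100)
            ).pvalue < 0.05
            for _ in range(2000)
        )
        assert 0.04 <= rej / 2000 <= 0.06

    def test_concentrated_method_flag(self, rng):
        res = equal_kappa_test(
            rng.vonmises(0, 8.0, 200), rng.vonmises(0, 8.0, 200),
            method="concentrated",
        )
        assert res.valid


class TestEventLocking:
    def test_events_at_cosine_peaks(self):
        fs = 1000.0
        t = np.arange(0, 10, 1 / fs)
        ts = TimeSeries(np.cos(2 * np.pi * 4 * t), fs)
        phase = analytic_phase_amplitude(ts, (3, 5))
        events = np.arange(1.0, 9.0, 0.25)  # every cosine peak
        rep = event_phase_locking(phase, events)
        assert abs(rep.mu) < 0.05
        assert rep.R > 0.999

    def test_uniform_events_not_locked(self, rng):
        fs = 1000.0
        ts = TimeSeries(np.cos(2 * np.pi * 4 * np.arange(0, 60, 1 / fs)), fs)
        phase = analytic_phase_amplitude(ts, (3, 5))
        ps = []
        for _ in range(100):
            events = rng.uniform(1, 59, 40)
            ps.append(event_phase_locking(phase, events).rayleigh_p)
        assert np.median(ps) > 0.05

    def test_generator_fr_locking_recovered(self, rng):
        # FRs placed at slow-oscillation phase 1.57 by construction
        from ripplelock.simulate import SynthConfig, generate_complex, generate_background
        from ripplelock.signals import decimate_timeseries

        cfg = SynthConfig.desk(seed=6)
        angles = []
        for _ in range(100):
            frag, truth = generate_complex(cfg, rng)
            bg = generate_background(cfg, 1, rng, n_samples=frag.n_samples)
            noisy = decimate_timeseries(
                TimeSeries(frag.data[0] + bg.data[0], cfg.fs), 1000.0
            )
            phase = analytic_phase_amplitude(noisy, (3, 6))
            angles.append(phase.phase_at(truth["fr_onset"]))
        mu, R, _ = circ_mean_kappa(np.array(angles))
        assert abs(mu - 1.57) < 0.15

    def test_empty_events_rejected(self):
        ts = TimeSeries(np.cos(np.arange(1000) * 0.01), 100.0)
        phase = analytic_phase_amplitude(ts, (0.1, 0.3))
        with pytest.raises(ValueError):
            event_phase_locking(phase, [])


class TestPhaseLockingFactor:
    def test_identical_epochs_plf_one(self, rng):
        ep = TimeSeries(rng.standard_normal(500), 500.0)
        plf = phase_locking_factor([ep] * 12, freqs=np.linspace(5, 50, 8),
                                   time_decim=10, rng=0)
        assert plf.plf.min() > 1 - 1e-9

    def test_null_level_scales_as_inverse_sqrt_n(self, rng):
        n = 100
        eps = [TimeSeries(rng.standard_normal(800), 1000.0) for _ in range(n)]
        plf = phase_locking_factor(eps, freqs=np.linspace(5, 50, 8),
                                   time_decim=40, rng=0)
        # E[R] for uniform phases = sqrt(pi)/2 / sqrt(n)
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
        assert abs(plf.plf.mean() / expected - 1) < 0.2

    def test_generator_complexes_significant_in_slow_band(self, rng):
        from ripplelock.simulate import SynthConfig, generate_complex, generate_background
        from ripplelock.signals import decimate_timeseries

        cfg = SynthConfig.desk(seed=7)
        eps = []
        for _ in range(30):
            frag, _ = generate_complex(cfg, rng)
            bg = generate_background(cfg, 1, rng, n_samples=frag.n_samples)
            eps.append(
                decimate_timeseries(TimeSeries(frag.data[0] + bg.data[0], cfg.fs), 1000.0)
            )
        plf = phase_locking_factor(eps, freqs=np.linspace(1, 100, 50),
                                   time_decim=10, rng=1)
        rows = (plf.freqs >= 3) & (plf.freqs <= 5.5)
        mid = (plf.times > -0.25) & (plf.times < 0.25)
        frac = plf.mask[np.ix_(rows, mid)].mean()
        assert frac > 0.5

    def test_few_epochs_flagged(self, rng):
        eps = [TimeSeries(rng.standard_normal(300), 300.0) for _ in range(5)]
        plf = phase_locking_factor(eps, freqs=[10.0], time_decim=30, rng=0)
        assert not plf.valid


class TestSynchronyScan:
    def _bipolar(self, x, fs, region):
        from ripplelock.core import Channel

        ch = Channel(id=f"{region}0-{region}1", region=region, montage="bipolar",
                     sources=(f"{region}0", f"{region}1"))
        return TimeSeries(x, fs, channels=[ch])

    def test_monopolar_refused(self, rng):
        a = TimeSeries(rng.standard_normal(4000), 1000.0)
        with pytest.raises(ValueError, match="bipolar"):
            phase_synchrony_scan(a, a, [(0.5, 1.5)], [(2.0, 3.0)],
                                 freqs=[4.0])

    def test_constant_delay_gives_huge_kappa(self, rng):
        fs = 1000.0
        x = rng.standard_normal(20_000)
        a = self._bipolar(x, fs, "LH")
        b = self._bipolar(np.roll(x, 30), fs, "FC")
        scan = phase_synchrony_scan(
            a, b, [(2.0, 8.0)], [(10.0, 16.0)], freqs=np.arange(4.0, 10.0)
        )
        assert np.all(scan.kappa_poi > 5.0)
        # both pools are extremely concentrated, so the ratio of two huge
        # kappas stays of order one
        assert np.all(scan.kappa_baseline > 5.0)
        assert np.all((scan.ratio > 0.1) & (scan.ratio < 10.0))

    def test_shared_component_peak_recovered(self, rng):
        fs = 1000.0
        n = 40_000
        shared = np.sin(2 * np.pi * 4 * np.arange(n) / fs)
        poi_mask = np.zeros(n, bool)
        poi_mask[5_000:15_000] = True
        xa = rng.standard_normal(n)
        xb = rng.standard_normal(n)
        xa[poi_mask] += 3 * shared[poi_mask]
        xb[poi_mask] += 3 * shared[poi_mask]
        a = self._bipolar(xa, fs, "LH")
        b = self._bipolar(xb, fs, "FC")
        scan = phase_synchrony_scan(
            a, b, [(5.0, 15.0)], [(20.0, 30.0)], freqs=np.arange(1.0, 16.0)
        )
        assert abs(scan.peak_freq - 4.0) <= 1.0

    def test_independent_signals_ratio_near_one(self, rng):
        fs = 500.0
        sig = 0
        for _ in range(20):
            xa = rng.standard_normal(10_000)
            xb = rng.standard_normal(10_000)
            a = self._bipolar(xa, fs, "LH")
            b = self._bipolar(xb, fs, "FC")
            scan = phase_synchrony_scan(
                a, b, [(2.0, 8.0)], [(12.0, 18.0)], freqs=np.arange(2.0, 12.0, 2.0)
            )
            sig += np.any(scan.pvalues < 0.05 / scan.freqs.size)
        assert sig <= 3
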