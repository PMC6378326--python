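"""Kalman-TVAR, adaptive PDC, band integration, lags, comparisons."""

import numpy as np
import pytest

from ripplelock.core import TimeSeries
from ripplelock.connectivity import (
    DirectedConnectivityResult,
    apdc_spectrum,
    bandlimited_crosscorr_lag,
    directed_comparison,
    fit_tvar_kalman,
    iapdc_band,
)


def simulate_var1(A, T, seed, sd=1.0):
    rng = np.random.default_rng(seed)
    K = A.shape[0]
    X = np.zeros((K, T))
    for t in range(1, T):
        X[:, t] = A @ X[:, t - 1] + sd * rng.standard_normal(K)
    return X


def resonant_pair(seed, T=3000, fs=100.0, f0=4.0, r=0.9, c=0.5):
    """x drives y; x is an AR(2) resonator at f0."""
    rng = np.random.default_rng(seed)
    a1, a2 = 2 * r * np.cos(2 * np.pi * f0 / fs), -(r**2)
    X = np.zeros((2, T))
    for t in range(2, T):
        X[0, t] = a1 * X[0, t - 1] + a2 * X[0, t - 2] + rng.standard_normal()
        X[1, t] = (
            0.8 * X[1, t - 1] - 0.2 * X[1, t - 2] + c * X[0, t - 1]
            + rng.standard_normal()
        )
    return TimeSeries(X, fs)


class TestKalmanTvar:
    def test_stationary_var1_matches_ols(self):
        A = np.array([[0.5, 0.2], [0.0, 0.4]])
        X = simulate_var1(A, 10_000, seed=0)
        model = fit_tvar_kalman(TimeSeries(X, 100.0), order=1, rate=0.002)
        est = model.time_averaged(burn_frac=0.3)[0]
        Y, Z = X[:, 1:].T, X[:, :-1].T
        ols = np.linalg.lstsq(Z, Y, rcond=None)[0].T
        assert np.abs(est - ols).max() < 0.05

    def test_independent_channels_no_coupling(self, rng):
        X = rng.standard_normal((2, 10_000))
        model = fit_tvar_kalman(TimeSeries(X, 100.0), order=1, rate=0.02)
        est = model.time_averaged()[0]
        assert abs(est[0, 1]) < 0.02 and abs(est[1, 0]) < 0.02

    def test_tracks_coefficient_switch_faster_with_rate(self):
        rng = np.random.default_rng(4)
        T = 6000
        X = np.zeros((2, T))
        for t in range(1, T):
            a = 0.1 if t < T // 2 else 0.7
            X[0, t] = a * X[0, t - 1] + rng.standard_normal()
            X[1, t] = 0.3 * X[1, t - 1] + rng.standard_normal()
        settle = []
        for rate in (0.002, 0.01, 0.05):
            m = fit_tvar_kalman(TimeSeries(X, 100.0), order=1, rate=rate)
            a_self = m.coeffs[:, 0, 0, 0]
            after = np.flatnonzero((np.arange(T) > T // 2) & (a_self > 0.5))
            settle.append(after[0] - T // 2 if after.size else T)
        assert settle[0] > settle[1] > settle[2]

    def test_convergence_to_ols_as_rate_shrinks(self):
        A = np.array([[0.5, 0.2], [0.0, 0.4]])
        X = simulate_var1(A, 10_000, seed=1)
        Y, Z = X[:, 1:].T, X[:, :-1].T
        ols = np.linalg.lstsq(Z, Y, rcond=None)[0].T
        diffs = []
        for rate in (0.02, 0.005, 0.001):
            m = fit_tvar_kalman(TimeSeries(X, 100.0), order=1, rate=rate)
            diffs.append(np.abs(m.time_averaged(burn_frac=0.3)[0] - ols).max())
        assert diffs[0] > diffs[1] > diffs[2]


class TestApdc:
    def test_diagonal_model_no_offdiagonal_flow(self):
        X = np.vstack(
            [simulate_var1(np.array([[0.6]]), 5000, seed=s)[0] for s in (0, 1)]
        )
        model = fit_tvar_kalman(TimeSeries(X, 100.0), order=1, rate=0.01)
        model.coeffs[:, :, 0, 1] = 0.0
        model.coeffs[:, :, 1, 0] = 0.0
        res = apdc_spectrum(model, np.arange(1.0, 20.0))
        assert np.allclose(res.apdc_sq[0, 1], 0.0)
        assert np.allclose(res.apdc_sq[1, 0], 0.0)

    def test_row_normalization_sums_to_one(self):
        ts = resonant_pair(seed=2)
        model = fit_tvar_kalman(ts, order=2, rate=0.02)
        res = apdc_spectrum(model, np.arange(1.0, 30.0),
                            times_idx=np.arange(500, 3000, 100))
        sums = res.apdc_sq.sum(axis=1)  # over sources for each sink
        assert np.abs(sums - 1.0).max() < 1e-12

    def test_column_normalization_variant(self):
        ts = resonant_pair(seed=3)
        model = fit_tvar_kalman(ts, order=2, rate=0.02)
        res = apdc_spectrum(model, np.arange(1.0, 30.0), normalization="column",
                            times_idx=np.arange(500, 3000, 100))
        sums = res.apdc_sq.sum(axis=0)  # over sinks for each source
        assert np.abs(sums - 1.0).max() < 1e-12

    def test_unidirectional_flow_dominates(self):
        wins = 0
        for seed in range(30):
            ts = resonant_pair(seed=seed)
            model = fit_tvar_kalman(ts, order=2, rate=0.02)
            res = apdc_spectrum(model, np.arange(2.0, 10.0))
            band = iapdc_band(res, 3.0, 5.0)
            xy = np.median(band[1, 0, 500:])  # x -> y (sink 1, source 0)
            yx = np.median(band[0, 1, 500:])
            wins += xy > yx
        assert wins >= 29


class TestIapdcBand:
    def _result(self, q):
        n_f = q.shape[2]
        return DirectedConnectivityResult(
            apdc_sq=q, freqs=np.arange(1.0, n_f + 1.0), times=np.arange(q.shape[3]) / 100.0,
        )

    def test_flat_in_frequency_identity(self):
        q = np.full((2, 2, 10, 5), 0.37)
        out = iapdc_band(self._result(q), 2.0, 8.0)
        assert np.allclose(out, 0.37)

    def test_single_bin_band(self):
        q = np.random.default_rng(0).uniform(0, 1, (2, 2, 10, 5))
        out = iapdc_band(self._result(q), 3.0, 3.0 + 1e-9)
        np.testing.assert_allclose(out, q[:, :, 2, :])

    def test_empty_band_rejected(self):
        q = np.zeros((2, 2, 10, 5))
        with pytest.raises(ValueError):
            iapdc_band(self._result(q), 8.0, 2.0)

    def test_generator_drive_increases_forward_flow(self):
        # raising drive_gain raises hippocampus->FC iAPDC on average and
        # does not raise FC->hippocampus
        from ripplelock.signals import decimate_timeseries
        from ripplelock.simulate import SynthConfig, generate_recording

        fwd, rev = {0.0: [], 1.0: []}, {0.0: [], 1.0: []}
        for seed in range(6):
            for gain in (0.0, 1.0):
                cfg = SynthConfig.desk(
                    seed=seed, duration=45.0, n_complexes=6, drive_gain=gain,
                )
                rec, _ = generate_recording(cfg)
                rows = []
                for region in ("LH", "RH", "FC"):
                    sub = rec.by_region(region)
                    lfp = sub.select(
                        [i for i, c in enumerate(sub.channels) if c.kind == "lfp"]
                    )
                    rows.append(lfp.data.mean(axis=0))
                sig = decimate_timeseries(
                    TimeSeries(np.array(rows), rec.fs), 100.0
                )
                model = fit_tvar_kalman(sig, order=8, rate=0.02)
                res = apdc_spectrum(model, np.arange(2.0, 10.0),
                                    times_idx=np.arange(200, sig.n_samples, 5))
                band = iapdc_band(res, 3.0, 5.0)
                fwd[gain].append(np.median(band[2, 0]))  # LH -> FC
                rev[gain].append(np.median(band[0, 2]))  # FC -> LH
        assert np.mean(fwd[1.0]) > np.mean(fwd[0.0])
        assert np.mean(rev[1.0]) <= np.mean(rev[0.0]) + 0.02


class TestCrossCorrLag:
    def test_identical_signals_zero_lag(self, rng):
        ts = TimeSeries(rng.standard_normal(8000), 1000.0)
        lag, _, _ = bandlimited_crosscorr_lag(ts, ts, band=(3, 5), max_lag=0.2)
        assert lag == 0.0

    def test_sign_convention_delayed_second_signal(self, rng):
        # second signal delayed by 64 ms -> lag exactly -64 ms at 1 kHz
        fs = 1000.0
        x = rng.standard_normal(10_000)
        a = TimeSeries(x, fs)
        b = TimeSeries(np.concatenate([np.zeros(64), x[:-64]]), fs)
        lag, lags_s, prof = bandlimited_crosscorr_lag(a, b, band=(3, 5), max_lag=0.25)
        assert lag == pytest.approx(-0.064, abs=1e-9)
        # brute-force correlation oracle at the peak
        xa = a.data[0] - a.data[0].mean()
        assert prof[np.argmax(prof)] <= 1.0 + 1e-9

    def test_antisymmetry(self, rng):
        fs = 500.0
        x = rng.standard_normal(6000)
        y = np.roll(x, 17) + 0.1 * rng.standard_normal(6000)
        a, b = TimeSeries(x, fs), TimeSeries(y, fs)
        l_ab = bandlimited_crosscorr_lag(a, b, band=(3, 5), max_lag=0.2)[0]
        l_ba = bandlimited_crosscorr_lag(b, a, band=(3, 5), max_lag=0.2)[0]
        assert l_ab == pytest.approx(-l_ba)

    def test_excessive_max_lag_rejected(self, rng):
        ts = TimeSeries(rng.standard_normal(1000), 1000.0)
        with pytest.raises(ValueError):
            bandlimited_crosscorr_lag(ts, ts, max_lag=0.6)

    def test_independent_noise_lower_peak_correlation(self, rng):
        fs = 1000.0
        coupled_peaks, indep_peaks = [], []
        for _ in range(10):
            x = rng.standard_normal(8000)
            a = TimeSeries(x, fs)
            b = TimeSeries(np.roll(x, 50), fs)
            c = TimeSeries(rng.standard_normal(8000), fs)
            _, _, p1 = bandlimited_crosscorr_lag(a, b, band=(3, 5), max_lag=0.2)
            _, _, p2 = bandlimited_crosscorr_lag(a, c, band=(3, 5), max_lag=0.2)
            coupled_peaks.append(p1.max())
            indep_peaks.append(p2.max())
        assert np.median(indep_peaks) < np.median(coupled_peaks)


class TestDirectedComparison:
    def test_identical_conditions(self, rng):
        vals = {("LH", "FC"): rng.uniform(0, 1, 200)}
        table = directed_comparison(vals, {k: v.copy() for k, v in vals.items()})
        assert table["diff_percent"].iloc[0] == 0.0
        assert table["p"].iloc[0] > 0.99

    def test_location_shift_detected(self, rng):
        base = {("LH", "FC"): rng.uniform(0, 1, 500)}
        poi = {("LH", "FC"): base[("LH", "FC")] + 0.3}
        table = directed_comparison(poi, base)
        assert table["diff_percent"].iloc[0] > 0
        assert table["p"].iloc[0] < 0.01

    def test_unmatched_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            directed_comparison(
                {("LH", "FC"): rng.uniform(0, 1, 10)},
                {("RH", "FC"): rng.uniform(0, 1, 10)},
            )
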