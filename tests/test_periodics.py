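import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import repsync as rs
from repsync.periodics import (
    PeriodEstimate,
    autocorrelation,
    autocorrelation_of,
    detect_period,
    delta_p,
    measure_sync,
    phase_lag,
    power_spectrum,
    spectral_peaks,
    write_sync_report,
)
from conftest import brute_force_autocorrelation


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.standard_normal(200)
            assert autocorrelation(x).values[0] == 1.0

    def test_matches_direct_truncated_sum(self, cosine_series, two_tone_series):
        # FFT path against the direct O(N^2) oracle on assorted signals
        rng = np.random.default_rng(1)
        _, cos_x, _ = cosine_series
        _, tt_x, _ = two_tone_series
        signals = [cos_x[:1500], tt_x[:2000], rng.standard_normal(999),
                   np.exp(-np.arange(500) / 90.0)]
        for x in signals:
            max_lag = len(x) // 2
            got = autocorrelation(x, max_lag=max_lag).values
            want = brute_force_autocorrelation(x, max_lag)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_cosine_over_whole_periods(self, cosine_series):
        # truncating the product sum to the overlap scales the exact cosine
        # autocorrelation by (1 - k/N), up to a boundary term bounded by
        # ~1/(N sin(2*pi*dt/T))
        t, x, dt = cosine_series
        n = len(x)
        res = autocorrelation(x, max_lag=200)
        expected = (1 - res.lags / n) * np.cos(2 * np.pi * res.lags * dt / 10.0)
        np.testing.assert_allclose(res.values, expected, atol=5e-3)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            autocorrelation(np.full(100, 3.7))

    def test_values_bounded_by_one(self, short_coupled_traj):
        for i in range(3):
            r = autocorrelation(short_coupled_traj.mrna(i, 0)).values
            assert np.max(np.abs(r)) <= 1 + 1e-9


class TestDetectPeriod:
    def test_recovers_cosine_period(self, cosine_series):
        _, x, dt = cosine_series
        est = detect_period(autocorrelation_of(x, dt))
        assert est.detected
        assert est.lag_index == 100
        assert est.period == pytest.approx(10.0, abs=dt)

    @pytest.mark.parametrize("period", [1.0, 2.5, 7.0, 25.0])
    def test_recovers_any_period_within_one_lag(self, period):
        dt = 0.1
        t = np.arange(0, 40 * period, dt)
        est = detect_period(autocorrelation_of(np.cos(2 * np.pi * t / period), dt))
        assert est.detected
        assert abs(est.period - period) <= dt + 1e-12

    def test_aperiodic_decay_is_undetected(self):
        x = np.exp(-np.arange(1000) / 50.0)
        est = detect_period(autocorrelation(x))
        assert not est.detected

    def test_two_tone_matches_exhaustive_scan(self, two_tone_series):
        _, x, dt = two_tone_series
        ac = autocorrelation_of(x, dt)
        est = detect_period(ac, threshold=0.7)
        r = ac.values
        # brute-force scan over all lags for the first strict local max > 0.7
        expected = None
        for k in range(1, len(r) - 1):
            if r[k] > r[k - 1] and r[k] > r[k + 1] and r[k] > 0.7:
                expected = k
                break
        assert est.lag_index == expected

    def test_threshold_is_configurable(self, cosine_series):
        _, x, dt = cosine_series
        ac = autocorrelation_of(x, dt)
        assert not detect_period(ac, threshold=0.999).detected
        assert detect_period(ac, threshold=0.5).detected


class TestDeltaP:
    def test_identical_periods_give_zero(self):
        assert delta_p((5.0, 5.0, 5.0)) == 0.0

    def test_hand_case(self):
        assert delta_p((1.0, 2.0, 3.0)) == 6.0

    @given(st.permutations([1.0, 2.0, 3.0]))
    @settings(deadline=None, derandomize=True)
    def test_permutation_invariance_hand_case(self, perm):
        assert delta_p(perm) == 6.0

    @given(
        st.lists(st.floats(min_value=0.1, max_value=100.0), min_size=3, max_size=3),
        st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_nonnegative_and_quadratic_scaling(self, taus, c):
        base = delta_p(taus)
        assert base >= 0
        assert delta_p([c * t for t in taus]) == pytest.approx(c**2 * base, rel=1e-9)

    def test_zero_iff_all_equal(self):
        assert delta_p((7.0, 7.0, 7.0)) == 0.0
        assert delta_p((7.0, 7.0, 7.05)) > 0.0

    def test_undetected_period_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            delta_p((1.0, None, 3.0))
        with pytest.raises(ValueError, match="undefined"):
            delta_p((1.0, PeriodEstimate.undetected(), 3.0))

    def test_accepts_period_estimates(self):
        ests = [PeriodEstimate(period=p, lag_index=1, peak_value=0.9)
                for p in (1.0, 2.0, 3.0)]
        assert delta_p(ests) == 6.0


class TestMeasureSync:
    def test_symmetric_run_gives_zero_delta_p(self, quick_sim_config):
        p = rs.build_params(0.0, 1.0, 1.0)
        rng = np.random.default_rng(9)
        y0 = np.concatenate([np.tile(rng.uniform(0, 1, 3), 3),
                             np.tile(rng.uniform(0, 1, 3), 3)])
        traj = rs.integrate(p, quick_sim_config, initial=y0)
        traj = rs.discard_transient(traj, quick_sim_config.t_burn)
        res = measure_sync(traj)
        assert res.n_undetected == 0
        periods = [e.period for e in res.periods]
        assert periods[0] == periods[1] == periods[2]
        assert res.delta_p == 0.0

    def test_report_roundtrip(self, tmp_path, short_coupled_traj):
        import json
        res = measure_sync(short_coupled_traj)
        path = tmp_path / "report.json"
        write_sync_report(res, path)
        data = json.loads(path.read_text())
        assert len(data["periods"]) == 3
        assert data["delta_p"] == res.delta_p

    def test_curve_csv_exports(self, tmp_path, cosine_series):
        import pandas as pd
        from repsync.periodics import write_autocorrelation_csv, write_spectrum_csv
        _, x, dt = cosine_series
        ac = autocorrelation_of(x, dt, max_lag=50)
        ac_path = tmp_path / "acorr.csv"
        write_autocorrelation_csv(ac, ac_path)
        df = pd.read_csv(ac_path)
        assert list(df.columns) == ["lag", "lag_time", "autocorrelation"]
        np.testing.assert_allclose(df.autocorrelation.to_numpy(), ac.values)
        freqs, power = power_spectrum(x, dt)
        sp_path = tmp_path / "spectrum.csv"
        write_spectrum_csv(freqs, power, sp_path)
        df2 = pd.read_csv(sp_path)
        assert df2.power.idxmax() == int(np.argmax(power))


class TestPhaseLag:
    def test_self_alignment(self, cosine_series):
        _, x, dt = cosine_series
        assert phase_lag(x, x, dt) == 0.0

    def test_quarter_period_shift(self):
        dt = 0.1
        t = np.arange(0, 400, dt)
        a = np.cos(2 * np.pi * t / 10.0)
        b = np.cos(2 * np.pi * (t - 2.5) / 10.0)  # b delayed by T/4
        assert phase_lag(a, b, dt) == pytest.approx(2.5, abs=dt)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            phase_lag(np.ones(100), np.ones(100), 0.1)

    def test_coupled_regime_has_in_phase_pair(self):
        # in a strongly coupled regime some species pair from distinct
        # repressilators locks nearly in phase
        params = rs.build_params(2.0, 1.0, 1.0)
        cfg = rs.SimConfig(t_end=400.0, dt=0.05, t_burn=100.0, seed=14)
        traj = rs.discard_transient(rs.integrate(params, cfg), 100.0)
        ref = traj.mrna(0, 0)
        from repsync.periodics import autocorrelation_of as _ac
        est = detect_period(_ac(ref, traj.dt))
        assert est.detected
        best = np.inf
        for i in (1, 2):
            for j in range(3):
                lag = phase_lag(ref, traj.mrna(i, j), traj.dt)
                best = min(best, abs(lag))
        assert best < 0.05 * est.period


class TestPowerSpectrum:
    def test_single_tone_peak(self, cosine_series):
        _, x, dt = cosine_series
        freqs, power = power_spectrum(x, dt)
        df = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(power)] - 0.1) <= df

    def test_two_tone_peaks(self, two_tone_series):
        _, x, dt = two_tone_series
        freqs, power = power_spectrum(x, dt)
        df = freqs[1] - freqs[0]
        peaks = sorted(f for f, _ in spectral_peaks(freqs, power, q=2))
        assert abs(peaks[0] - 0.1) <= df
        assert abs(peaks[1] - 0.25) <= df

    def test_enzyme_coupling_adds_spectral_content(self):
        # moderate saturation deforms the waveform relative to the
        # weak-coupling (large-K) limit: more relative power off the
        # dominant line
        def rel_power_off_peak(km):
            params = rs.build_params(1.5, km, km)
            cfg = rs.SimConfig(t_end=400.0, dt=0.05, t_burn=100.0, seed=5)
            traj = rs.discard_transient(rs.integrate(params, cfg), 100.0)
            freqs, power = power_spectrum(traj.mrna(1, 0), traj.dt)
            return 1.0 - power.max() / power.sum()

        assert rel_power_off_peak(1.0) > rel_power_off_peak(10.0)
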