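"""Synchrony measures: windowed correlation, Fisher-z ISC, phase
clustering, coherence, and the group-lag procedure."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cardiosync.series import PhaseSeries, RateSeries
from cardiosync.sync import (
    estimate_group_lag,
    fisher_mean,
    isc,
    isc_per_participant,
    ispc,
    phase_cluster,
    src,
    srpc,
    windowed_correlation,
)


def rate(x):
    return RateSeries(bpm=np.asarray(x, float))


class TestWindowedCorrelation:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(0).normal(60, 2, 1200)
        s = windowed_correlation(x, x)
        assert np.allclose(s.values, 1.0)

    def test_affine_invariance(self):
        x = np.random.default_rng(1).normal(60, 2, 1200)
        s = windowed_correlation(x, 2 * x + 1)
        assert np.allclose(s.values, 1.0)

    def test_window_count_for_60s_series(self):
        s = windowed_correlation(np.arange(1200.0), np.random.default_rng(0).normal(size=1200))
        assert s.values.size == 51  # (1200 - 200)/20 + 1

    def test_zero_variance_window_masked(self):
        x = np.ones(400)
        y = np.random.default_rng(0).normal(size=400)
        s = windowed_correlation(x, y)
        assert np.isnan(s.values).all()

    def test_short_series_errors(self):
        with pytest.raises(ValueError, match="window"):
            windowed_correlation(np.zeros(100), np.zeros(100))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(float, 400, elements=st.floats(-100, 100)),
        arrays(float, 400, elements=st.floats(-100, 100)),
    )
    def test_values_stay_in_unit_interval(self, x, y):
        vals = windowed_correlation(x, y).values
        finite = vals[np.isfinite(vals)]
        assert np.all(finite >= -1.0) and np.all(finite <= 1.0)


class TestGroupLag:
    def test_zero_lag_recovered(self):
        x = np.random.default_rng(0).normal(size=600)
        est = estimate_group_lag([x], x, [0.99])
        assert est.group_ms == 0.0

    def test_600ms_delay_recovered(self):
        from scipy.ndimage import gaussian_filter1d

        stim = gaussian_filter1d(np.random.default_rng(3).normal(size=1200), 3)
        resp = np.concatenate([np.zeros(12), stim])[:1200]
        est = estimate_group_lag([resp], stim, [0.99])
        assert abs(est.group_ms - 600.0) <= 50.0

    def test_anticorrelated_participant_excluded(self):
        stim = np.sin(np.arange(600) / 5)
        with pytest.warns(UserWarning, match="excluded"):
            est = estimate_group_lag([-stim[:400]], stim, [0.1])
        assert est.excluded == [0]
        assert est.group_ms == 0.0


class TestSRC:
    def test_affine_rate_of_flux_gives_unit_correlation(self):
        flux = np.abs(np.random.default_rng(0).normal(size=1200)) + 0.1
        r = rate(60 + 2 * flux)
        s = src(r, flux, lag_ms=0.0)
        assert np.allclose(s.values, 1.0)

    def test_independent_noise_averages_to_zero(self):
        rng = np.random.default_rng(7)
        flux = rng.normal(size=4000)
        r = rate(60 + rng.normal(size=4000))
        s = src(r, flux, lag_ms=0.0)
        assert s.values.size >= 150
        assert abs(np.nanmean(s.values)) < 0.05

    def test_half_period_lag_flips_sign(self):
        # cosine drive: shifting the response by half a period negates r
        t = np.arange(2400) / 20.0
        flux = np.cos(2 * np.pi * 0.5 * t)  # 2 s period
        r = rate(60 + np.cos(2 * np.pi * 0.5 * t))
        aligned = src(r, flux, lag_ms=0.0)
        flipped = src(r, flux, lag_ms=1000.0)
        n = flipped.values.size
        assert np.allclose(aligned.values[:n], 1.0, atol=1e-6)
        assert np.allclose(flipped.values, -1.0, atol=1e-6)


class TestISC:
    def test_identical_signals_give_unity(self):
        x = np.random.default_rng(0).normal(60, 3, 600)
        s = isc([rate(x), rate(x.copy()), rate(x.copy())])
        assert np.all(s.values > 1 - 1e-6)

    def test_fisher_combination_oracle(self):
        # oracle: tanh(mean(atanh(.))) evaluated directly
        assert fisher_mean(np.array([0.6, 0.0])) == pytest.approx(
            np.tanh(np.mean(np.arctanh([0.6, 0.0])))
        )
        assert fisher_mean(np.array([0.6, 0.0])) == pytest.approx(1 / 3, abs=0.02)

    def test_equal_pair_correlations_are_fixed_point(self):
        assert fisher_mean(np.array([0.42, 0.42, 0.42])) == pytest.approx(0.42)

    def test_participant_order_invariance(self):
        rng = np.random.default_rng(5)
        rates = [rate(rng.normal(60, 2, 600)) for _ in range(4)]
        a = isc(rates).values
        b = isc(rates[::-1]).values
        assert np.allclose(a, b, equal_nan=True)

    def test_single_participant_errors(self):
        with pytest.raises(ValueError, match="two participants"):
            isc([rate(np.zeros(400))])

    def test_per_participant_variant_matches_pool_on_shared_signal(self):
        x = np.random.default_rng(0).normal(60, 3, 600)
        per = isc_per_participant([rate(x), rate(x.copy()), rate(x.copy())])
        assert len(per) == 3
        for s in per:
            assert np.all(s.values > 1 - 1e-6)


class TestPhaseCluster:
    def test_identical_angles(self):
        assert phase_cluster(np.array([1.2, 1.2, 1.2])) == pytest.approx(1.0)

    def test_antiphase_pair(self):
        assert phase_cluster(np.array([0.0, np.pi])) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_triplet(self):
        angles = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        assert phase_cluster(angles) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_complex_mean(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            angles = rng.uniform(-np.pi, np.pi, rng.integers(2, 12))
            brute = abs(sum(np.exp(1j * a) for a in angles) / len(angles))
            assert abs(phase_cluster(angles) - brute) < 1e-12

    def test_nan_angle_masks_output(self):
        out = phase_cluster(np.array([[0.0], [np.nan]]))
        assert np.isnan(out[0])


class TestSRPC:
    def _ramp(self, freq, duration=120.0, fs=20.0):
        from cardiosync.features import wrap_angle

        t = np.arange(0, duration, 1 / fs)
        return PhaseSeries(wrap_angle(2 * np.pi * freq * t))

    def test_identical_ramps_fully_coherent_in_both_modes(self):
        a, b = self._ramp(1.0), self._ramp(1.0)
        for mode in ("pointwise", "plv"):
            s = srpc(a, b, mode=mode)
            assert np.allclose(s.values, 1.0, atol=1e-9)

    def test_constant_offset_closed_form(self):
        from cardiosync.features import wrap_angle

        delta = 1.1
        t = np.arange(0, 120, 1 / 20.0)
        a = PhaseSeries(wrap_angle(2 * np.pi * 1.0 * t))
        b = PhaseSeries(wrap_angle(2 * np.pi * 1.0 * t + delta))
        point = srpc(a, b, mode="pointwise").values
        plv = srpc(a, b, mode="plv").values
        assert np.allclose(point, abs(np.cos(delta / 2)), atol=1e-9)
        assert np.allclose(plv, 1.0, atol=1e-9)

    def test_incommensurate_ramps_have_low_plv(self):
        # |(1/T) integral exp(i 2 pi df t) dt| = |sinc(df T)| ~ 0.2 for
        # df = 0.13 Hz over T = 10 s
        a, b = self._ramp(1.0), self._ramp(1.13)
        s = srpc(a, b, mode="plv")
        assert np.nanmax(s.values) < 0.3


class TestISPC:
    def test_identical_participants(self):
        t = np.arange(0, 60, 1 / 20.0)
        from cardiosync.features import wrap_angle

        phases = [PhaseSeries(wrap_angle(2 * np.pi * t)) for _ in range(3)]
        s = ispc(phases)
        assert np.allclose(s.values, 1.0, atol=1e-9)

    def test_pair_mean_contract(self):
        # three signals: two identical, one in antiphase to both ->
        # pair coherences {1, 0, 0}, mean 1/3
        n = 1200
        base = np.zeros(n)
        anti = np.full(n, np.pi)
        phases = [PhaseSeries(base), PhaseSeries(base.copy()), PhaseSeries(anti)]
        s = ispc(phases, mode="pointwise")
        assert np.allclose(s.values, 1 / 3, atol=1e-9)

    def test_coherence_stays_in_unit_interval(self):
        rng = np.random.default_rng(4)
        from cardiosync.features import wrap_angle

        phases = [
            PhaseSeries(wrap_angle(np.cumsum(rng.normal(0.3, 0.1, 800))))
            for _ in range(3)
        ]
        vals = ispc(phases).values
        finite = vals[np.isfinite(vals)]
        assert np.all((finite >= 0) & (finite <= 1))
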