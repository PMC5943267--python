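"""Correlator and FCS model/fit behaviour."""

import numpy as np
import pytest
from dataclasses import replace

from fpfa.errors import FitError, ValidationError
from fpfa.fcs import (GAMMA_2P, CorrelationCurve, cross_correlate, fcs_model,
                      fcs_flicker_model, fit_fcs, molecular_brightness)
from fpfa.photons import AcquisitionMeta, PhotonStream, count_rate


class TestFcsModel:
    def test_short_lag_limit_is_gamma_over_n(self):
        assert fcs_model(1e-12, 50.0, 380e-6, 0.049) == pytest.approx(0.35 / 50, rel=1e-5)

    def test_hand_evaluated_point(self):
        # tau = tau_D, omega/z = 0.049, N = 1: 0.35/(2*sqrt(1.0024))
        expected = 0.35 / (2.0 * np.sqrt(1.0 + 0.049**2))
        assert fcs_model(380e-6, 1.0, 380e-6, 0.049) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.17479, abs=5e-6)

    def test_monotone_decay_to_zero(self):
        lags = np.logspace(-7, 1, 200)
        g = fcs_model(lags, 10.0, 380e-6, 0.049)
        assert np.all(np.diff(g) < 0)
        assert g[-1] < 1e-5 * g[0]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            fcs_model(1e-6, -1.0, 380e-6, 0.049)


class TestFlickerModel:
    def test_reduces_to_plain_at_zero_dark_fraction(self):
        lags = np.logspace(-7, 0, 100)
        plain = fcs_model(lags, 7.0, 380e-6, 0.049)
        flick = fcs_flicker_model(lags, 7.0, 380e-6, 0.049, T=0.0, tau_t_s=25e-6)
        np.testing.assert_allclose(flick, plain, rtol=1e-15)

    def test_amplitude_inflated_by_dark_fraction(self):
        g0 = fcs_flicker_model(1e-12, 4.0, 380e-6, 0.049, T=0.3, tau_t_s=25e-6)
        assert g0 == pytest.approx((0.35 / 4.0) / 0.7, rel=1e-6)

    def test_hand_evaluated_point_at_tau_equals_tau_t(self):
        tau_t = 5e-6
        base = fcs_model(tau_t, 1.0, 380e-6, 0.049)
        expected = base * (0.7 + 0.3 * np.exp(-1.0)) / 0.7
        got = fcs_flicker_model(tau_t, 1.0, 380e-6, 0.049, T=0.3, tau_t_s=tau_t)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_dark_fraction_domain_enforced(self):
        with pytest.raises(ValidationError):
            fcs_flicker_model(1e-6, 1.0, 380e-6, 0.049, T=1.0, tau_t_s=25e-6)


def _direct_multi_tau_oracle(a, b, dt, m, max_lag):
    """Naive direct-product correlator on the same coarsened binning."""
    a = a.astype(float).copy()
    b = b.astype(float).copy()
    lags, gs = [], []
    level = 0
    while True:
        width = dt * 2**level
        ks = list(range(1, m + 1)) if level == 0 else list(range(m // 2 + 1, m + 1))
        for k in ks:
            lag = k * width
            n = a.size - k
            if lag > max_lag or n < 2 * m:
                return np.array(lags), np.array(gs)
            prods = [a[i] * b[i + k] for i in range(n)]
            num = sum(prods) / n
            ma = sum(a[:n]) / n
            mb = sum(b[k:k + n]) / n
            lags.append(lag)
            gs.append(num / (ma * mb) - 1.0)
        half = 2 * (a.size // 2)
        a = np.array([a[2 * i] + a[2 * i + 1] for i in range(half // 2)])
        b = np.array([b[2 * i] + b[2 * i + 1] for i in range(half // 2)])
        level += 1


class TestCorrelator:
    def test_multi_tau_matches_direct_oracle(self, venus_stream):
        """Multi-tau equals an O(B^2)-style direct correlator to 1e-12."""
        sub = _first_seconds(venus_stream, 1.0)
        curve = cross_correlate(sub, base_bin_s=1e-4, n_segments=1, max_lag_s=0.05)
        t = sub.seconds()
        n_bins = int(round(1.0 / 1e-4))
        a = np.bincount(np.minimum((t[sub.channel == 0] / 1e-4).astype(int), n_bins - 1),
                        minlength=n_bins)
        b = np.bincount(np.minimum((t[sub.channel == 1] / 1e-4).astype(int), n_bins - 1),
                        minlength=n_bins)
        lags, gs = _direct_multi_tau_oracle(a, b, 1e-4, 16, 0.05)
        np.testing.assert_allclose(curve.lag_s, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.G, gs, rtol=1e-9, atol=1e-12)

    def test_independent_poisson_streams_have_zero_correlation(self):
        rng = np.random.default_rng(5)
        meta = AcquisitionMeta(sync_rate_hz=80e6, macro_tick_s=12.5e-9,
                               micro_bin_ns=12.5 / 1024, duration_s=10.0)
        n = 100_000
        macro = np.sort(np.concatenate([
            rng.integers(0, int(10 / 12.5e-9), n),
            rng.integers(0, int(10 / 12.5e-9), n)]))
        order = np.argsort(macro, kind="stable")
        channel = np.r_[np.zeros(n, dtype=int), np.ones(n, dtype=int)]
        rng.shuffle(channel)
        stream = PhotonStream(macro_time=macro,
                              micro_time=np.zeros(2 * n, dtype=int),
                              channel=channel, meta=meta)
        curve = cross_correlate(stream, base_bin_s=1e-4)
        assert np.all(np.abs(curve.G) < 4.5 * np.where(curve.G_err > 0, curve.G_err, np.inf))

    def test_amplitude_matches_gamma_over_n(self, venus_stream, venus_config):
        """G at the shortest lags ~ gamma/N (e.g. 0.35/57.3 = 6.1e-3 at N=57.3)."""
        curve = cross_correlate(venus_stream)
        g_short = curve.G[:8].mean()
        expected = GAMMA_2P / venus_config.n_molecules_mean
        err = curve.G_err[:8].mean() / np.sqrt(8) * 3 + 0.1 * expected
        assert g_short == pytest.approx(expected, abs=3 * err)

    def test_empty_channel_is_an_error(self, meta):
        stream = PhotonStream(macro_time=np.arange(100), micro_time=np.zeros(100, dtype=int),
                              channel=np.zeros(100, dtype=int), meta=meta)
        with pytest.raises(FitError):
            cross_correlate(stream)

    def test_overlong_max_lag_warns_and_truncates(self, venus_stream):
        with pytest.warns(UserWarning, match="truncating"):
            curve = cross_correlate(venus_stream, max_lag_s=10.0)
        assert curve.lag_s[-1] <= venus_stream.meta.duration_s / 8 / 10


class TestFitFcs:
    def _noiseless_curve(self, n=50.0, tau_d=380e-6, woz=0.049):
        lags = np.logspace(np.log10(2e-6), np.log10(2e-2), 60)
        return CorrelationCurve(lag_s=lags, G=fcs_model(lags, n, tau_d, woz),
                                G_err=None, n_photons_used=(0, 0), duration_s=60.0,
                                base_bin_s=2e-6)

    def test_noiseless_curve_recovered_exactly(self):
        fit = fit_fcs(self._noiseless_curve(), omega_over_z=0.049)
        assert fit.n_mean == pytest.approx(50.0, rel=1e-6)
        assert fit.tau_d_us == pytest.approx(380.0, rel=1e-6)
        assert fit.success

    def test_noiseless_flicker_curve_recovered(self):
        lags = np.logspace(np.log10(2e-6), np.log10(2e-2), 80)
        g = fcs_flicker_model(lags, 10.0, 94e-6, 0.049, T=0.5, tau_t_s=25e-6)
        curve = CorrelationCurve(lag_s=lags, G=g, G_err=None, n_photons_used=(0, 0),
                                 duration_s=30.0, base_bin_s=2e-6)
        fit = fit_fcs(curve, model="flicker", omega_over_z=0.049)
        assert fit.n_mean == pytest.approx(10.0, rel=1e-4)
        assert fit.T == pytest.approx(0.5, abs=1e-3)
        assert fit.tau_t_us == pytest.approx(25.0, rel=1e-3)

    def test_flicker_t0_fit_matches_plain(self):
        curve = self._noiseless_curve()
        plain = fit_fcs(curve, omega_over_z=0.049)
        flick = fit_fcs(curve, model="flicker", omega_over_z=0.049)
        assert flick.n_mean == pytest.approx(plain.n_mean, rel=1e-3)
        assert flick.T < 0.02

    def test_too_few_points_rejected(self):
        lags = np.logspace(-6, -2, 5)
        curve = CorrelationCurve(lag_s=lags, G=fcs_model(lags, 5, 380e-6, 0.049),
                                 G_err=None, n_photons_used=(0, 0), duration_s=1.0,
                                 base_bin_s=2e-6)
        with pytest.raises(FitError):
            fit_fcs(curve)


class TestBrightness:
    def test_simple_ratio(self):
        assert molecular_brightness(10_000, 10) == pytest.approx(1000.0)

    def test_hetero_fret_plateau_values(self):
        # <k> = 96 kHz at <N> = 57.3 -> 1675.4 cpms
        assert molecular_brightness(96_000, 57.3) == pytest.approx(1675.4, abs=0.1)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValidationError):
            molecular_brightness(1000, 0)


def test_thinning_leaves_correlation_unchanged_and_halves_rate(venus_stream):
    """Uniform 50% photon thinning: G(τ) invariant within noise, rate halves.

    The normalized correlation does not see uniform detection losses — only
    the count rate (hence apparent brightness) drops.  At desk-scale photon
    counts the check lives at the curve level: the thinned curve must agree
    with the full curve within the added shot noise at essentially every
    point.
    """
    rng = np.random.default_rng(123)
    keep = rng.random(len(venus_stream)) < 0.5
    thinned = replace(venus_stream, macro_time=venus_stream.macro_time[keep],
                      micro_time=venus_stream.micro_time[keep],
                      channel=venus_stream.channel[keep])
    assert count_rate(thinned) / count_rate(venus_stream) == pytest.approx(0.5, abs=0.01)
    full = cross_correlate(venus_stream)
    thin = cross_correlate(thinned)
    np.testing.assert_allclose(thin.lag_s, full.lag_s)
    sigma = np.sqrt(full.G_err**2 + thin.G_err**2)
    n_outliers = int(np.sum(np.abs(thin.G - full.G) > 5 * sigma))
    assert n_outliers <= max(1, len(full.G) // 50)


def _first_seconds(stream, seconds):
    t = stream.seconds()
    sel = t < seconds
    meta = replace(stream.meta, duration_s=seconds)
    return PhotonStream(macro_time=stream.macro_time[sel],
                        micro_time=stream.micro_time[sel],
                        channel=stream.channel[sel], meta=meta)
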