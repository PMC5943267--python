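"""Micro-time analysis: decays, anisotropy, lifetimes, g-factor."""

import numpy as np
import pytest
from dataclasses import replace

from fpfa.errors import FitError, ValidationError
from fpfa.photons import AcquisitionMeta, PhotonStream
from fpfa.simulate import SimConfig, simulate_stream
from fpfa.trfa import (AnisotropyResult, DecayHistogram, anisotropy_decay,
                       build_decay, estimate_g_tailfit, fit_anisotropy_decay,
                       fit_lifetime, steady_state_anisotropy, total_decay)


def _hist(par, perp, width_ns=12.5 / 1024):
    par = np.asarray(par, dtype=float)
    centers = (np.arange(par.size) + 0.5) * width_ns
    return DecayHistogram(bin_centers_ns=centers, counts_parallel=par,
                          counts_perpendicular=np.asarray(perp, dtype=float),
                          dark_level_per_bin=(0.0, 0.0), dark_subtracted=False,
                          clipped=False)


class TestBuildDecay:
    def test_photon_at_micro_time_zero_lands_in_bin_zero(self, meta):
        stream = PhotonStream(macro_time=np.array([0]), micro_time=np.array([0]),
                              channel=np.array([0]), meta=meta)
        hist = build_decay(stream, n_bins=64, dark_subtraction=False)
        assert hist.counts_parallel[0] == 1
        assert hist.counts_parallel[1:].sum() == 0

    def test_dark_only_stream_is_flat(self, meta):
        rng = np.random.default_rng(3)
        n = 200_000
        stream = PhotonStream(macro_time=np.sort(rng.integers(0, 10**7, n)),
                              micro_time=rng.integers(0, 1024, n),
                              channel=np.zeros(n, dtype=int), meta=meta)
        hist = build_decay(stream, n_bins=128, dark_subtraction=False)
        expected = n / 128
        assert np.all(np.abs(hist.counts_parallel - expected) < 5 * np.sqrt(expected))

    def test_empty_stream_rejected(self, meta):
        empty = PhotonStream(macro_time=np.array([], dtype=int),
                             micro_time=np.array([], dtype=int),
                             channel=np.array([], dtype=int), meta=meta)
        with pytest.raises(ValidationError):
            build_decay(empty)

    def test_log_slope_matches_simulated_lifetime(self, venus_stream):
        """Mono-exponential stream: regression of log counts gives -1/tau."""
        hist = build_decay(venus_stream, n_bins=256)
        total = total_decay(hist, 1.07)
        t = hist.bin_centers_ns
        sel = (t > 1.0) & (t < 9.0) & (total > 50)
        slope = np.polyfit(t[sel], np.log(total[sel]), 1)[0]
        assert -1.0 / slope == pytest.approx(3.154, rel=0.03)


class TestTotalDecayArithmetic:
    def test_unity_g(self):
        out = total_decay(_hist([100.0], [50.0]), 1.0)
        assert out[0] == pytest.approx(200.0)

    def test_instrument_g(self):
        # 150 + 2*1.07*100 = 364
        out = total_decay(_hist([150.0], [100.0]), 1.07)
        assert out[0] == pytest.approx(364.0)

    def test_zero_bins_stay_zero(self):
        out = total_decay(_hist(np.zeros(8), np.zeros(8)), 1.07)
        assert np.all(out == 0)

    def test_conserves_g_weighted_counts(self, venus_stream):
        hist = build_decay(venus_stream)
        out = total_decay(hist, 1.07)
        expected = hist.counts_parallel.sum() + 2 * 1.07 * hist.counts_perpendicular.sum()
        assert out.sum() == pytest.approx(expected, rel=1e-12)


class TestAnisotropyArithmetic:
    def test_isotropic_is_zero(self):
        res = anisotropy_decay(_hist([100.0] * 4, [100.0] * 4), 1.0, min_counts=1)
        np.testing.assert_allclose(res.r_of_t, 0.0, atol=1e-14)

    def test_perpendicular_dark_limit_is_one(self):
        res = anisotropy_decay(_hist([100.0], [0.0]), 1.0, min_counts=1)
        assert res.r_of_t[0] == pytest.approx(1.0)

    def test_hand_evaluated_point(self):
        # (150 - 1.07*100)/364 = 0.1181
        res = anisotropy_decay(_hist([150.0], [100.0]), 1.07, min_counts=1)
        assert res.r_of_t[0] == pytest.approx(43.0 / 364.0, rel=1e-12)
        assert res.r_of_t[0] == pytest.approx(0.1181, abs=5e-5)

    def test_steady_state_hand_values(self):
        # (300 - 1.07*200)/(300 + 2*1.07*200) = 0.1181
        hist = _hist([100.0, 200.0], [150.0, 50.0])
        assert steady_state_anisotropy(hist, 1.07) == pytest.approx(86.0 / 728.0, rel=1e-12)

    def test_steady_state_equals_count_weighted_mean_of_r(self, venus_stream):
        """r(t)/R consistency: R equals the sum-weighted average of r(t)."""
        hist = build_decay(venus_stream)
        g = 1.07
        res = anisotropy_decay(hist, g, min_counts=0.0)
        denom = hist.counts_parallel + 2 * g * hist.counts_perpendicular
        ok = denom > 0
        weighted = np.sum(res.r_of_t[ok] * denom[ok]) / np.sum(denom[ok])
        assert weighted == pytest.approx(res.R_steady, rel=1e-10)

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValidationError):
            steady_state_anisotropy(_hist([0.0], [0.0]), 1.0)


class TestLifetimeFit:
    def _stream(self, components, seed=5, duration=4.0, **over):
        cfg = SimConfig(lifetime_components=components, duration_s=duration,
                        seed=seed, dark_cps=0.0, **over)
        return simulate_stream(cfg)

    def test_equal_lifetimes_average_to_same(self):
        # amplitude-weighted mean identity: a1 = a2, tau1 = tau2 = 3 -> <tau> = 3
        from fpfa.trfa import LifetimeFit
        fit = LifetimeFit(amplitudes=(0.5, 0.5), lifetimes_ns=(3.0, 3.0),
                          tau_avg_ns=(0.5 * 3 + 0.5 * 3) / 1.0, chi2_reduced=1.0,
                          fit_window_ns=(0.5, 12.5), n_components=2, param_errors={},
                          success=True, message="")
        assert fit.tau_avg_ns == pytest.approx(3.0)

    def test_amplitude_weighted_average_hand_value(self, venus_stream):
        """Fit machinery reports <tau> = sum(a tau)/sum(a); 0.6*3+0.4*1 = 2.2."""
        amps = np.array([0.6, 0.4])
        taus = np.array([3.0, 1.0])
        assert float((amps * taus).sum() / amps.sum()) == pytest.approx(2.2)
        # and the fitted mono-exponential stream reproduces its input lifetime
        hist = build_decay(venus_stream)
        fit = fit_lifetime(hist, g_factor=1.07)
        assert fit.tau_avg_ns == pytest.approx(3.154, abs=0.02)
        assert fit.tau_avg_ns == fit.lifetimes_ns[0]

    def test_double_exponential_recovery(self):
        stream = self._stream(((0.6, 3.0), (0.4, 1.0)), duration=8.0,
                              n_molecules_mean=30, eta_cpms=1500)
        fit = fit_lifetime(build_decay(stream), g_factor=1.07, n_components=2)
        assert fit.tau_avg_ns == pytest.approx(2.2, abs=0.12)
        assert sorted(fit.lifetimes_ns, reverse=True)[0] == pytest.approx(3.0, abs=0.25)

    def test_scaling_counts_leaves_lifetimes_unchanged(self, venus_stream):
        hist = build_decay(venus_stream)
        scaled = DecayHistogram(bin_centers_ns=hist.bin_centers_ns,
                                counts_parallel=hist.counts_parallel * 4.0,
                                counts_perpendicular=hist.counts_perpendicular * 4.0,
                                dark_level_per_bin=hist.dark_level_per_bin,
                                dark_subtracted=hist.dark_subtracted, clipped=False)
        f1 = fit_lifetime(hist, g_factor=1.07)
        f2 = fit_lifetime(scaled, g_factor=1.07)
        assert f2.lifetimes_ns[0] == pytest.approx(f1.lifetimes_ns[0], rel=1e-3)

    def test_window_before_peak_rejected(self, venus_stream):
        with pytest.raises(FitError):
            fit_lifetime(build_decay(venus_stream), g_factor=1.07,
                         fit_window_ns=(-1.0, 12.0))


class TestAnisotropyFit:
    def test_noiseless_hindered_rotor_recovered_exactly(self):
        t = np.linspace(0.2, 12.0, 200)
        r = 0.05 + (0.38 - 0.05) * np.exp(-t / 16.0)
        res = AnisotropyResult(t_ns=t, r_of_t=r, r_err=np.full_like(t, 1e-4),
                               mask=np.ones_like(t, dtype=bool), R_steady=0.3,
                               g_factor=1.0)
        fit = fit_anisotropy_decay(res)
        assert fit.r0 == pytest.approx(0.38, abs=1e-4)
        assert fit.theta_rot_ns == pytest.approx(16.0, rel=1e-3)
        assert fit.r_inf == pytest.approx(0.05, abs=1e-4)

    def test_flat_anisotropy_flagged_unidentifiable(self):
        t = np.linspace(0.2, 12.0, 100)
        rng = np.random.default_rng(0)
        r = 0.42 + rng.normal(0, 1e-4, t.size)
        res = AnisotropyResult(t_ns=t, r_of_t=r, r_err=np.full_like(t, 1e-3),
                               mask=np.ones_like(t, dtype=bool), R_steady=0.42,
                               g_factor=1.0)
        fit = fit_anisotropy_decay(res)
        assert "theta_unidentifiable" in fit.flags
        assert fit.r0 == pytest.approx(0.42, abs=1e-3)
        assert fit.r_inf == pytest.approx(0.42, abs=1e-3)

    def test_simulated_stream_recovery(self, venus_stream, venus_config):
        hist = build_decay(venus_stream)
        res = anisotropy_decay(hist, venus_config.g_factor)
        fit = fit_anisotropy_decay(res, folding_lifetime_ns=3.154, sync_period_ns=12.5)
        assert fit.r0 == pytest.approx(venus_config.r0, abs=0.02)
        assert fit.R_steady == pytest.approx(venus_config.steady_state_anisotropy(), abs=0.01)


class TestGFactor:
    def test_fast_rotor_recovers_instrument_g(self, fluorescein_stream, fluorescein_config):
        g, g_err = estimate_g_tailfit(fluorescein_stream)
        assert g == pytest.approx(fluorescein_config.g_factor, abs=max(3 * g_err, 0.02))

    def test_symmetric_detection_gives_unity(self, fluorescein_config):
        cfg = replace(fluorescein_config, g_factor=1.0, seed=78)
        g, g_err = estimate_g_tailfit(simulate_stream(cfg))
        assert g == pytest.approx(1.0, abs=max(3 * g_err, 0.02))

    def test_slow_rotor_detected_and_rejected(self, fluorescein_config):
        slow = replace(fluorescein_config, theta_rot_ns=40.0, r0=0.38, seed=79,
                       eta_cpms=4000.0)
        with pytest.raises(FitError, match="rotor"):
            estimate_g_tailfit(simulate_stream(slow))


def test_homo_fret_depolarization_ordering():
    """Dimer series with shrinking r0 keeps its steady-state R ordering."""
    r0s = (0.31, 0.345, 0.372, 0.42)
    measured = []
    for i, r0 in enumerate(r0s):
        cfg = SimConfig(n_molecules_mean=25, eta_cpms=1700.0, duration_s=3.0,
                        r0=r0, r_inf=0.0, theta_rot_ns=60.0, seed=500 + i,
                        dark_cps=0.0)
        hist = build_decay(simulate_stream(cfg))
        measured.append(steady_state_anisotropy(hist, cfg.g_factor))
    assert measured == sorted(measured)
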