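"""Fluorescence correlation spectroscopy on dual-polarization photon streams.

The parallel and perpendicular channels are cross-correlated (which cancels
detector afterpulsing, the reason dual-detector FCS cross-correlates) with a
multi-tau scheme: a quasi-logarithmic lag grid with 16 linear lags per
octave and bin width doubling per octave, using symmetric (Schätzel)
normalization.  The curve is fit to a single-component 3D-Gaussian two-photon
diffusion model

    G(τ) = γ/⟨N⟩ · 1/(1 + τ/τ_D) · 1/sqrt(1 + (ω/z)²·τ/τ_D),  γ = 0.35,

optionally extended with a bright/dark flicker factor

    × (1 - T + T·exp(-τ/τ_T)) / (1 - T).

Statistical errors per lag come from block averaging: the stream is split
into segments, each correlated independently, and the segment scatter gives
the per-point standard error used as fit weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import FitError, ValidationError
from .photons import PhotonStream

__all__ = [
    "GAMMA_2P",
    "CorrelationCurve",
    "FcsFit",
    "cross_correlate",
    "fcs_model",
    "fcs_flicker_model",
    "fit_fcs",
    "molecular_brightness",
]

#: shape factor of a two-photon 3D-Gaussian observation volume
GAMMA_2P = 0.35


@dataclass(frozen=True)
class CorrelationCurve:
    """Cross-correlation amplitudes on a quasi-logarithmic lag grid."""

    lag_s: np.ndarray
    G: np.ndarray
    G_err: np.ndarray | None
    n_photons_used: tuple
    duration_s: float
    base_bin_s: float
    n_segments: int = 1

    def __post_init__(self) -> None:
        lag = np.asarray(self.lag_s, dtype=float)
        g = np.asarray(self.G, dtype=float)
        object.__setattr__(self, "lag_s", lag)
        object.__setattr__(self, "G", g)
        if lag.shape != g.shape:
            raise ValidationError("lag and G must have matching shapes")
        if lag.size and (np.any(lag <= 0) or np.any(np.diff(lag) <= 0)):
            raise ValidationError("lags must be positive and strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ValidationError("G contains non-finite values")

    def to_text(self, path) -> None:
        err = self.G_err if self.G_err is not None else np.full_like(self.G, np.nan)
        header = (f"fpfa cross-correlation\nduration_s = {self.duration_s}\n"
                  f"base_bin_s = {self.base_bin_s}\nn_segments = {self.n_segments}\n"
                  f"n_photons_used = {self.n_photons_used[0]} {self.n_photons_used[1]}\n"
                  "lag_s G G_err")
        np.savetxt(path, np.column_stack([self.lag_s, self.G, err]), header=header)


def _multi_tau_pair(a: np.ndarray, b: np.ndarray, dt: float, m: int,
                    max_lag: float) -> tuple[np.ndarray, np.ndarray]:
    """Multi-tau cross-correlation of two binned count arrays.

    Level 0 evaluates lags 1..m in units of the base bin; every further level
    doubles the bin width and evaluates lags m/2+1..m, so the lag grid is
    strictly increasing.  Symmetric normalization: numerator and the two
    channel means are all taken over the overlapping window.
    """
    lags: list[float] = []
    g: list[float] = []
    a = a.astype(np.float64, copy=True)
    b = b.astype(np.float64, copy=True)
    level = 0
    while True:
        width = dt * (1 << level)
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        for k in ks:
            lag = k * width
            n = a.size - k
            if lag > max_lag or n < 2 * m:
                return np.asarray(lags), np.asarray(g)
            num = float(a[:n] @ b[k:k + n]) / n
            mean_a = float(a[:n].mean())
            mean_b = float(b[k:k + n].mean())
            if mean_a <= 0 or mean_b <= 0:
                raise FitError("a correlator segment contains an empty channel")
            lags.append(lag)
            g.append(num / (mean_a * mean_b) - 1.0)
        half = 2 * (a.size // 2)
        a = a[:half].reshape(-1, 2).sum(axis=1)
        b = b[:half].reshape(-1, 2).sum(axis=1)
        level += 1


#: default longest lag evaluated.  Diffusion times in this workflow are
#: 70–600 µs, so 20 ms already covers >30 diffusion times; far longer lags
#: add no information about τ_D but are the first to pick up slow drifts
#: (and, for simulated streams, finite-reservoir recurrence).
DEFAULT_MAX_LAG_S = 20e-3


def cross_correlate(stream: PhotonStream, base_bin_s: float = 2e-6, m: int = 16,
                    n_segments: int = 8, max_lag_s: float | None = None) -> CorrelationCurve:
    """Cross-correlate the parallel and perpendicular channels.

    The stream is cut into ``n_segments`` equal blocks; the mean over blocks
    is the curve and the block scatter the per-point standard error.
    ``max_lag_s`` defaults to :data:`DEFAULT_MAX_LAG_S` (capped at a tenth
    of the segment length); explicit values beyond that cap are truncated
    with a warning.
    """
    if base_bin_s <= 0 or m < 2 or n_segments < 1:
        raise ValidationError("need base_bin_s > 0, m >= 2, n_segments >= 1")
    t = stream.seconds()
    par_t = t[stream.channel == 0]
    perp_t = t[stream.channel == 1]
    if par_t.size == 0 or perp_t.size == 0:
        raise FitError("cross-correlation requires photons in both channels")
    duration = stream.meta.duration_s
    seg_dur = duration / n_segments
    lag_cap = seg_dur / 10.0
    if max_lag_s is None:
        max_lag_s = min(lag_cap, DEFAULT_MAX_LAG_S)
    elif max_lag_s > lag_cap:
        warnings.warn(f"max lag {max_lag_s:g}s exceeds segment duration/10; truncating to {lag_cap:g}s")
        max_lag_s = lag_cap

    n_bins = int(round(seg_dur / base_bin_s))
    if n_bins < 4 * m:
        raise FitError("segments too short for the requested lag schedule")
    g_segments = []
    lags = None
    for i in range(n_segments):
        t0 = i * seg_dur
        sel_a = (par_t >= t0) & (par_t < t0 + seg_dur)
        sel_b = (perp_t >= t0) & (perp_t < t0 + seg_dur)
        a = np.bincount(np.minimum(((par_t[sel_a] - t0) / base_bin_s).astype(np.int64),
                                   n_bins - 1), minlength=n_bins)
        b = np.bincount(np.minimum(((perp_t[sel_b] - t0) / base_bin_s).astype(np.int64),
                                   n_bins - 1), minlength=n_bins)
        lag_i, g_i = _multi_tau_pair(a, b, base_bin_s, m, max_lag_s)
        if lags is None:
            lags = lag_i
        g_segments.append(g_i)
    g_arr = np.vstack(g_segments)
    g_mean = g_arr.mean(axis=0)
    if n_segments > 1:
        g_err = g_arr.std(axis=0, ddof=1) / math.sqrt(n_segments)
    else:
        g_err = None
    return CorrelationCurve(lag_s=lags, G=g_mean, G_err=g_err,
                            n_photons_used=(int(par_t.size), int(perp_t.size)),
                            duration_s=duration, base_bin_s=base_bin_s,
                            n_segments=n_segments)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def fcs_model(lag_s, n_mean: float, tau_d_s: float, omega_over_z: float,
              gamma: float = GAMMA_2P):
    """Single-component 3D-Gaussian two-photon diffusion model G(τ)."""
    if n_mean <= 0 or tau_d_s <= 0 or omega_over_z <= 0:
        raise ValidationError("fcs_model parameters must be > 0")
    x = np.asarray(lag_s, dtype=float) / tau_d_s
    return gamma / n_mean / (1.0 + x) / np.sqrt(1.0 + omega_over_z**2 * x)


def fcs_flicker_model(lag_s, n_mean: float, tau_d_s: float, omega_over_z: float,
                      T: float, tau_t_s: float, gamma: float = GAMMA_2P):
    """Diffusion model with a bright/dark flicker factor.

    The flicker term is (1 - T + T·e^{-τ/τ_T})/(1 - T): a decaying
    exponential whose τ→0 limit inflates the amplitude by 1/(1-T).
    """
    if not 0.0 <= T < 1.0:
        raise ValidationError("dark fraction T must lie in [0, 1)")
    if tau_t_s <= 0:
        raise ValidationError("tau_T must be > 0")
    base = fcs_model(lag_s, n_mean, tau_d_s, omega_over_z, gamma)
    lag = np.asarray(lag_s, dtype=float)
    return base * (1.0 - T + T * np.exp(-lag / tau_t_s)) / (1.0 - T)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FcsFit:
    """Result of fitting a correlation curve."""

    model: str                       # "plain" or "flicker"
    n_mean: float
    tau_d_us: float
    omega_over_z: float
    T: float | None
    tau_t_us: float | None
    gamma: float
    chi2_reduced: float
    residuals: np.ndarray            # weighted residuals on the curve's lag grid
    param_errors: dict
    success: bool
    message: str
    n_points: int

    @property
    def flagged(self) -> bool:
        return not self.success

    def predict(self, lag_s) -> np.ndarray:
        if self.model == "flicker":
            return fcs_flicker_model(lag_s, self.n_mean, self.tau_d_us * 1e-6,
                                     self.omega_over_z, self.T, self.tau_t_us * 1e-6,
                                     self.gamma)
        return fcs_model(lag_s, self.n_mean, self.tau_d_us * 1e-6,
                         self.omega_over_z, self.gamma)


def _expit(x: float) -> float:
    """Logistic transform clipped away from the {0, 1} boundaries."""
    x = min(max(x, -500.0), 500.0)
    return min(max(1.0 / (1.0 + math.exp(-x)), 1e-12), 1.0 - 1e-12)


def _initial_guess(curve: CorrelationCurve, gamma: float) -> tuple[float, float]:
    g0 = float(curve.G[0])
    if g0 <= 0:
        g0 = max(float(np.max(curve.G)), 1e-6)
    n0 = gamma / g0
    half = g0 / 2.0
    below = np.flatnonzero(curve.G < half)
    tau0 = float(curve.lag_s[below[0]]) if below.size else float(curve.lag_s[-1] / 4)
    return max(n0, 1e-3), tau0


def fit_fcs(curve: CorrelationCurve, model: str = "plain",
            omega_over_z: float = 0.049, vary_omega_over_z: bool = False,
            gamma: float = GAMMA_2P, init: dict | None = None,
            window_tau_d: float | None = None) -> FcsFit:
    """Weighted nonlinear least-squares fit of a correlation curve.

    Positive parameters are fit in log space, the dark fraction through a
    logistic transform, so no parameter can leave its domain.  ω/z is fixed
    by default (it comes from calibration and is barely identifiable from a
    single curve).  Non-convergence is reported through ``success`` /
    ``message``, never raised.

    ``window_tau_d``, when set, truncates the fit to lags below
    ``window_tau_d · τ_D`` (τ_D from a first full-range pass and one
    refinement): the correlation decay carries all its τ_D information
    within a few diffusion times, and far-tail points are the most exposed
    to slow drifts — and, for simulated streams, finite-reservoir artifacts.
    """
    if window_tau_d is not None:
        fit = fit_fcs(curve, model=model, omega_over_z=omega_over_z,
                      vary_omega_over_z=vary_omega_over_z, gamma=gamma, init=init)
        for _ in range(2):
            cap = window_tau_d * fit.tau_d_us * 1e-6
            sel = curve.lag_s <= cap
            if sel.sum() < max(16, int(0.2 * curve.lag_s.size)):
                sel = curve.lag_s <= curve.lag_s[max(16, int(0.2 * curve.lag_s.size)) - 1]
            sub = CorrelationCurve(
                lag_s=curve.lag_s[sel], G=curve.G[sel],
                G_err=None if curve.G_err is None else curve.G_err[sel],
                n_photons_used=curve.n_photons_used, duration_s=curve.duration_s,
                base_bin_s=curve.base_bin_s, n_segments=curve.n_segments)
            fit = fit_fcs(sub, model=model, omega_over_z=omega_over_z,
                          vary_omega_over_z=vary_omega_over_z, gamma=gamma, init=init)
        return fit
    if model not in ("plain", "flicker"):
        raise ValidationError(f"unknown FCS model {model!r}")
    if curve.lag_s.size < 10:
        raise FitError("need at least 10 correlation points to fit")
    span = curve.lag_s[-1] / curve.lag_s[0]
    if span < 100:
        raise FitError("lag grid must span at least 2 decades")

    n0, tau0 = _initial_guess(curve, gamma)
    init = init or {}
    n0 = float(init.get("n_mean", n0))
    tau0 = float(init.get("tau_d_s", tau0))

    # deterministic multi-start for the flicker parameters: the (T, tau_T)
    # surface has a degenerate plain-model valley at T->1, tau_T->0
    if model == "flicker":
        if "T" in init or "tau_t_s" in init:
            starts = [(float(init.get("T", 0.3)),
                       float(init.get("tau_t_s", max(curve.lag_s[0] * 4, tau0 / 20))))]
        else:
            t_starts = (0.15, 0.5)
            tau_t_starts = (max(curve.lag_s[0] * 4, tau0 / 100), tau0 / 10, tau0 / 3)
            starts = [(t, tt) for t in t_starts for tt in tau_t_starts]
    else:
        starts = [(None, None)]

    def make_params(t0, tau_t0):
        params = lmfit.Parameters()
        amp_boost = 1.0 / (1.0 - t0) if t0 is not None else 1.0
        params.add("ln_n", value=math.log(n0 * amp_boost))
        params.add("ln_tau_d", value=math.log(tau0))
        params.add("ln_woz", value=math.log(omega_over_z), vary=vary_omega_over_z)
        if t0 is not None:
            # T capped at 0.85 and tau_T confined to the measured lag range:
            # without bounds the flicker factor can absorb the whole decay
            # (T -> 1 with a huge tau_T), a degenerate re-parameterization of
            # diffusion rather than a dark-state fraction
            params.add("logit_T", value=math.log(t0 / (1 - t0)),
                       max=math.log(0.85 / 0.15))
            params.add("ln_tau_t", value=math.log(tau_t0),
                       min=math.log(curve.lag_s[0] / 2.0),
                       max=math.log(curve.lag_s[-1]))
        return params

    if curve.G_err is not None:
        err = np.where(curve.G_err > 0, curve.G_err, np.nan)
        fallback = np.nanmedian(err) if np.isfinite(err).any() else 1.0
        err = np.where(np.isfinite(err), err, fallback)
        # block-averaged SEs are themselves noisy (few segments); smooth them
        # on the log scale so no single point dominates the fit
        log_err = np.log(err)
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(np.pad(log_err, 2, mode="edge"), kernel, mode="valid")
        weights = 1.0 / np.exp(smooth)
    else:
        weights = np.ones_like(curve.G)

    lag = curve.lag_s

    def _exp(value: float) -> float:
        return math.exp(min(max(value, -250.0), 250.0))

    def residual(p):
        n = _exp(p["ln_n"].value)
        tau_d = _exp(p["ln_tau_d"].value)
        woz = _exp(p["ln_woz"].value)
        if model == "flicker":
            t_frac = _expit(p["logit_T"].value)
            tau_t = _exp(p["ln_tau_t"].value)
            model_g = fcs_flicker_model(lag, n, tau_d, woz, t_frac, tau_t, gamma)
        else:
            model_g = fcs_model(lag, n, tau_d, woz, gamma)
        return (curve.G - model_g) * weights

    result = None
    for t0, tau_t0 in starts:
        candidate = lmfit.minimize(residual, make_params(t0, tau_t0),
                                   method="leastsq", nan_policy="raise")
        if result is None or candidate.chisqr < result.chisqr:
            result = candidate

    p = result.params
    n_fit = math.exp(p["ln_n"].value)
    tau_d_fit = math.exp(p["ln_tau_d"].value)
    woz_fit = math.exp(p["ln_woz"].value)
    errors: dict[str, float] = {}

    def _delta(name: str, scale: float) -> float | None:
        stderr = p[name].stderr
        return scale * stderr if stderr is not None else None

    errors["n_mean"] = _delta("ln_n", n_fit)
    errors["tau_d_us"] = _delta("ln_tau_d", tau_d_fit * 1e6)
    if vary_omega_over_z:
        errors["omega_over_z"] = _delta("ln_woz", woz_fit)
    t_fit = tau_t_fit = None
    if model == "flicker":
        t_fit = _expit(p["logit_T"].value)
        tau_t_fit = math.exp(p["ln_tau_t"].value)
        errors["T"] = _delta("logit_T", t_fit * (1 - t_fit))
        errors["tau_t_us"] = _delta("ln_tau_t", tau_t_fit * 1e6)

    success = bool(result.success) and np.isfinite(result.redchi)
    message = result.message if isinstance(result.message, str) else str(result.message)
    return FcsFit(model=model, n_mean=n_fit, tau_d_us=tau_d_fit * 1e6,
                  omega_over_z=woz_fit, T=t_fit,
                  tau_t_us=tau_t_fit * 1e6 if tau_t_fit is not None else None,
                  gamma=gamma, chi2_reduced=float(result.redchi),
                  residuals=np.asarray(result.residual),
                  param_errors=errors, success=success, message=message,
                  n_points=int(lag.size))


def molecular_brightness(count_rate_cps: float, n_mean: float) -> float:
    """Molecular brightness η = ⟨k⟩/⟨N⟩ in counts per molecule per second."""
    if n_mean <= 0:
        raise ValidationError("n_mean must be > 0")
    return float(count_rate_cps) / float(n_mean)
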