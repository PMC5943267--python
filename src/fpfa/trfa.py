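"""Time-resolved fluorescence analysis from TCSPC micro-times.

From the per-channel micro-time histograms this module derives:

* the total intensity decay ``I(t) = I_∥(t) + 2·g·I_⊥(t)``,
* the time-resolved anisotropy
  ``r(t) = (I_∥(t) − g·I_⊥(t)) / (I_∥(t) + 2·g·I_⊥(t))``,
* the steady-state anisotropy ``R`` (same expression on channel sums),
* tail fits of the decay to one- or two-exponential models with the
  amplitude-weighted mean lifetime ``⟨τ⟩ = Σaᵢτᵢ/Σaᵢ``,
* a hindered-rotor fit ``r(t) = r_∞ + (r0 − r_∞)·exp(−t/θ)``, and
* the polarization g-factor from tail fitting of a fast-rotor standard.

``g`` corrects the detection-efficiency imbalance between the two
polarization detectors: the perpendicular counts are multiplied by ``g``
wherever the equations above use them.

No instrument-response deconvolution is attempted: fits are tail fits
starting (by default 0.5 ns) after the decay peak, appropriate for an IRF of
order 100 ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import lmfit
import numpy as np

from .errors import FitError, ValidationError
from .photons import PhotonStream

__all__ = [
    "DecayHistogram",
    "AnisotropyResult",
    "LifetimeFit",
    "build_decay",
    "total_decay",
    "anisotropy_decay",
    "steady_state_anisotropy",
    "fit_anisotropy_decay",
    "fit_lifetime",
    "estimate_g_tailfit",
]


@dataclass(frozen=True)
class DecayHistogram:
    """Per-channel micro-time histograms over one sync period."""

    bin_centers_ns: np.ndarray
    counts_parallel: np.ndarray
    counts_perpendicular: np.ndarray
    dark_level_per_bin: tuple   # expected dark counts per bin (par, perp)
    dark_subtracted: bool
    clipped: bool               # True if dark subtraction hit zero anywhere

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers_ns.size)

    @property
    def bin_width_ns(self) -> float:
        return float(self.bin_centers_ns[1] - self.bin_centers_ns[0])

    def to_text(self, path) -> None:
        """3-column text export: t_ns, parallel counts, perpendicular counts."""
        header = (f"fpfa decay histogram\nn_bins = {self.n_bins}\n"
                  f"dark_subtracted = {self.dark_subtracted}\n"
                  "t_ns counts_parallel counts_perpendicular")
        np.savetxt(path, np.column_stack([self.bin_centers_ns,
                                          self.counts_parallel,
                                          self.counts_perpendicular]),
                   header=header)


@dataclass(frozen=True)
class AnisotropyResult:
    """Time-resolved and steady-state anisotropy derived from a decay."""

    t_ns: np.ndarray
    r_of_t: np.ndarray
    r_err: np.ndarray
    mask: np.ndarray              # True where r is statistically usable
    R_steady: float
    g_factor: float
    r0: float | None = None
    theta_rot_ns: float | None = None
    r_inf: float | None = None
    fit_window_ns: tuple | None = None
    chi2_reduced: float | None = None
    param_errors: dict | None = None
    flags: tuple = ()


@dataclass(frozen=True)
class LifetimeFit:
    """Exponential tail fit of the total intensity decay."""

    amplitudes: tuple
    lifetimes_ns: tuple
    tau_avg_ns: float
    chi2_reduced: float
    fit_window_ns: tuple
    n_components: int
    param_errors: dict
    success: bool
    message: str
    flags: tuple = ()


def build_decay(stream: PhotonStream, n_bins: int = 1024,
                dark_subtraction: bool = True) -> DecayHistogram:
    """Micro-time histograms per channel, optionally dark-subtracted.

    The uniform dark (and ambient) background expected in each bin is
    ``dark_cps · duration / n_bins`` per channel; subtraction clips at zero
    and sets ``clipped`` when it does.
    """
    if n_bins < 64:
        raise ValidationError("need n_bins >= 64")
    if len(stream) == 0:
        raise ValidationError("cannot build a decay from an empty stream")
    meta = stream.meta
    n_native = meta.n_micro_bins
    if n_native % n_bins == 0:
        factor = n_native // n_bins
        idx = stream.micro_time // factor
    else:
        idx = (stream.micro_time * n_bins) // n_native
    par = np.bincount(idx[stream.channel == 0], minlength=n_bins).astype(float)
    perp = np.bincount(idx[stream.channel == 1], minlength=n_bins).astype(float)
    width = meta.sync_period_ns / n_bins
    centers = (np.arange(n_bins) + 0.5) * width
    dark_per_bin = meta.dark_cps * meta.duration_s / n_bins
    clipped = False
    if dark_subtraction and dark_per_bin > 0:
        clipped = bool((par < dark_per_bin).any() or (perp < dark_per_bin).any())
        par = np.clip(par - dark_per_bin, 0.0, None)
        perp = np.clip(perp - dark_per_bin, 0.0, None)
    return DecayHistogram(bin_centers_ns=centers, counts_parallel=par,
                          counts_perpendicular=perp,
                          dark_level_per_bin=(dark_per_bin, dark_per_bin),
                          dark_subtracted=bool(dark_subtraction and dark_per_bin > 0),
                          clipped=clipped)


def total_decay(hist: DecayHistogram, g_factor: float) -> np.ndarray:
    """Polarization-corrected total intensity I(t) = I_∥ + 2·g·I_⊥ per bin."""
    if g_factor <= 0:
        raise ValidationError("g_factor must be > 0")
    par = np.asarray(hist.counts_parallel, dtype=float)
    perp = np.asarray(hist.counts_perpendicular, dtype=float)
    if par.shape != perp.shape:
        raise ValidationError("channel histograms have mismatched shapes")
    return par + 2.0 * g_factor * perp


def anisotropy_decay(hist: DecayHistogram, g_factor: float,
                     min_counts: float = 25.0) -> AnisotropyResult:
    """Per-bin anisotropy r(t); bins with denominator < min_counts masked.

    Per-bin errors come from Poisson propagation through
    r = (p − g·q)/(p + 2·g·q).
    """
    if g_factor <= 0:
        raise ValidationError("g_factor must be > 0")
    p = np.asarray(hist.counts_parallel, dtype=float)
    q = np.asarray(hist.counts_perpendicular, dtype=float)
    denom = p + 2.0 * g_factor * q
    mask = denom >= min_counts
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mask, (p - g_factor * q) / denom, np.nan)
        dr_dp = 3.0 * g_factor * q / denom**2
        dr_dq = -3.0 * g_factor * p / denom**2
        var = dr_dp**2 * np.maximum(p, 1.0) + dr_dq**2 * np.maximum(q, 1.0)
        r_err = np.where(mask, np.sqrt(var), np.nan)
    return AnisotropyResult(t_ns=hist.bin_centers_ns, r_of_t=r, r_err=r_err,
                            mask=mask, R_steady=steady_state_anisotropy(hist, g_factor),
                            g_factor=g_factor)


def steady_state_anisotropy(hist: DecayHistogram, g_factor: float) -> float:
    """Steady-state anisotropy R = (ΣI_∥ − g·ΣI_⊥)/(ΣI_∥ + 2·g·ΣI_⊥)."""
    if g_factor <= 0:
        raise ValidationError("g_factor must be > 0")
    s_par = float(np.sum(hist.counts_parallel))
    s_perp = float(np.sum(hist.counts_perpendicular))
    denom = s_par + 2.0 * g_factor * s_perp
    if denom <= 0:
        raise ValidationError("zero total intensity; cannot form anisotropy")
    return (s_par - g_factor * s_perp) / denom


def _smoothed_peak_bin(intensity: np.ndarray) -> int:
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(intensity, kernel, mode="same")
    return int(np.argmax(smooth))


def fit_anisotropy_decay(result: AnisotropyResult,
                         fit_window_ns: tuple | None = None,
                         folding_lifetime_ns: float | None = None,
                         sync_period_ns: float | None = None) -> AnisotropyResult:
    """Weighted hindered-rotor fit r(t) = r_∞ + (r0 − r_∞)·e^(−t/θ).

    When ``folding_lifetime_ns`` and ``sync_period_ns`` are given, the model
    accounts for pulse wrap-around: photons excited by earlier pulses fold
    into the observation window and attenuate the apparent decaying
    amplitude by the constant factor
    ``(1 − e^{−P/τ}) / (1 − e^{−P/τ − P/θ})``.
    """
    sel = result.mask & np.isfinite(result.r_of_t) & (result.r_err > 0)
    if fit_window_ns is not None:
        sel &= (result.t_ns >= fit_window_ns[0]) & (result.t_ns <= fit_window_ns[1])
    t = result.t_ns[sel]
    r = result.r_of_t[sel]
    w = 1.0 / result.r_err[sel]
    if t.size < 10:
        raise FitError("need at least 10 usable bins to fit an anisotropy decay")

    flags: list[str] = []
    span = r.max() - r.min()
    noise = float(np.median(result.r_err[sel]))
    if span < 4 * noise:
        # flat within noise: theta unidentifiable
        r_flat = float(np.average(r, weights=w**2))
        return _with_fit(result, r0=r_flat, theta=None, r_inf=r_flat,
                         window=(float(t[0]), float(t[-1])), chi2=None,
                         errors={}, flags=("theta_unidentifiable",))

    def attenuation(theta: float) -> float:
        if folding_lifetime_ns is None or sync_period_ns is None:
            return 1.0
        p_over = sync_period_ns / folding_lifetime_ns
        return -math.expm1(-p_over) / -math.expm1(-p_over - sync_period_ns / theta)

    params = lmfit.Parameters()
    r0_guess = float(np.clip(r[: max(3, t.size // 20)].mean(), 0.01, 0.57))
    params.add("r0", value=r0_guess, min=-0.2, max=0.57)
    params.add("r_inf", value=float(np.clip(r[-max(3, t.size // 10):].mean(), -0.19, 0.56)),
               min=-0.2, max=0.57)
    params.add("ln_theta", value=math.log(max((t[-1] - t[0]) / 4.0, 0.1)))

    def residual(p):
        theta = math.exp(p["ln_theta"].value)
        model = p["r_inf"].value + (p["r0"].value - p["r_inf"].value) \
            * attenuation(theta) * np.exp(-t / theta)
        return (r - model) * w

    fit = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
    if not fit.success:
        flags.append("non_convergence")
    theta = math.exp(fit.params["ln_theta"].value)
    errors = {}
    for name, scale in (("r0", 1.0), ("r_inf", 1.0)):
        stderr = fit.params[name].stderr
        errors[name] = stderr * scale if stderr is not None else None
    stderr = fit.params["ln_theta"].stderr
    errors["theta_rot_ns"] = stderr * theta if stderr is not None else None
    return _with_fit(result, r0=float(fit.params["r0"].value), theta=float(theta),
                     r_inf=float(fit.params["r_inf"].value),
                     window=(float(t[0]), float(t[-1])),
                     chi2=float(fit.redchi), errors=errors, flags=tuple(flags))


def _with_fit(base: AnisotropyResult, r0, theta, r_inf, window, chi2, errors, flags):
    return AnisotropyResult(t_ns=base.t_ns, r_of_t=base.r_of_t, r_err=base.r_err,
                            mask=base.mask, R_steady=base.R_steady,
                            g_factor=base.g_factor, r0=r0, theta_rot_ns=theta,
                            r_inf=r_inf, fit_window_ns=window, chi2_reduced=chi2,
                            param_errors=errors, flags=flags)


def fit_lifetime(hist: DecayHistogram, g_factor: float = 1.0, n_components: int = 1,
                 fit_window_ns: tuple | None = None,
                 tail_offset_ns: float = 0.5) -> LifetimeFit:
    """Tail fit of the total decay to a 1- or 2-exponential model.

    Weighted least squares with Poisson weights, iterated once with weights
    from the fitted model (removes the small-count weighting bias).  The fit
    window must start after the decay peak; the default starts
    ``tail_offset_ns`` after it.  ``tau_avg_ns`` is the amplitude-weighted
    mean lifetime Σaᵢτᵢ/Σaᵢ.
    """
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    intensity = total_decay(hist, g_factor)
    t = hist.bin_centers_ns
    peak = _smoothed_peak_bin(intensity)
    if fit_window_ns is None:
        fit_window_ns = (t[peak] + tail_offset_ns, float(t[-1]))
    if fit_window_ns[0] <= t[peak] - hist.bin_width_ns / 2:
        raise FitError(f"tail fit window must start after the decay peak at {t[peak]:.3f} ns")
    sel = (t >= fit_window_ns[0]) & (t <= fit_window_ns[1]) & (intensity > 0)
    ts = t[sel]
    ys = intensity[sel]
    if ts.size < 10 or ys.sum() < 100:
        raise FitError("too few counts in the tail window for a lifetime fit")

    # variance of I = p + 2gq is p + 4g^2 q; approximate from the data
    p_counts = np.asarray(hist.counts_parallel, dtype=float)[sel]
    q_counts = np.asarray(hist.counts_perpendicular, dtype=float)[sel]
    var = np.maximum(p_counts + 4.0 * g_factor**2 * q_counts, 1.0)

    # crude slope-based initial lifetime
    tau0 = _log_slope_lifetime(ts, ys)

    params = lmfit.Parameters()
    if n_components == 1:
        params.add("ln_a1", value=math.log(ys[0]))
        params.add("ln_tau1", value=math.log(tau0))
    else:
        params.add("ln_a1", value=math.log(ys[0] * 0.6))
        params.add("ln_a2", value=math.log(ys[0] * 0.4))
        params.add("ln_tau1", value=math.log(tau0 * 1.4))
        params.add("ln_tau2", value=math.log(tau0 * 0.6))

    t_rel = ts - ts[0]

    def model_of(p):
        out = np.zeros_like(t_rel)
        for i in range(1, n_components + 1):
            out = out + math.exp(p[f"ln_a{i}"].value) \
                * np.exp(-t_rel / math.exp(p[f"ln_tau{i}"].value))
        return out

    # var(I)/I is nearly constant across the tail; reuse it to set
    # model-based weights on the second pass (removes small-count bias)
    phi = float((p_counts.sum() + 4.0 * g_factor**2 * q_counts.sum())
                / max(p_counts.sum() + 2.0 * g_factor * q_counts.sum(), 1.0))
    weights = 1.0 / np.sqrt(var)
    fit = None
    for _ in range(2):
        def residual(p):
            return (ys - model_of(p)) * weights
        fit = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
        params = fit.params
        weights = 1.0 / np.sqrt(np.maximum(model_of(fit.params) * phi, 1.0))

    amps = np.array([math.exp(fit.params[f"ln_a{i}"].value) for i in range(1, n_components + 1)])
    taus = np.array([math.exp(fit.params[f"ln_tau{i}"].value) for i in range(1, n_components + 1)])
    amps = amps * np.exp(ts[0] / taus)  # refer amplitudes back to t = 0
    order = np.argsort(taus)[::-1]  # report slow component first
    amps, taus = amps[order], taus[order]
    flags: list[str] = []
    if not fit.success:
        flags.append("non_convergence")
    errors: dict[str, float | None] = {}
    for j, i in enumerate(order, start=1):
        stderr = fit.params[f"ln_tau{i + 1}"].stderr
        errors[f"tau{j}_ns"] = stderr * taus[j - 1] if stderr is not None else None
    if n_components == 2:
        err1 = errors.get("tau1_ns") or 0.0
        err2 = errors.get("tau2_ns") or 0.0
        if abs(taus[0] - taus[1]) < math.hypot(err1, err2):
            flags.append("overparameterized")
    tau_avg = float(np.sum(amps * taus) / np.sum(amps))
    return LifetimeFit(amplitudes=tuple(amps / amps.sum()), lifetimes_ns=tuple(taus),
                       tau_avg_ns=tau_avg, chi2_reduced=float(fit.redchi),
                       fit_window_ns=(float(fit_window_ns[0]), float(fit_window_ns[1])),
                       n_components=n_components, param_errors=errors,
                       success=bool(fit.success), message=str(fit.message),
                       flags=tuple(flags))


def _log_slope_lifetime(t: np.ndarray, y: np.ndarray) -> float:
    n = max(t.size // 2, 2)
    slope = np.polyfit(t[:n], np.log(np.maximum(y[:n], 0.5)), 1)[0]
    if slope >= 0:
        return float(t[-1] - t[0]) / 4.0
    return float(-1.0 / slope)


def estimate_g_tailfit(stream: PhotonStream, tail_start_ns: float | None = None,
                       n_bins: int = 256, min_counts_per_bin: float = 10.0,
                       flatness_z: float = 5.0) -> tuple:
    """g-factor from the decay tail of a fast-rotor standard (fluorescein).

    Once the anisotropy has fully decayed, both channels follow the same
    decay and their ratio is the detection imbalance g.  Returns
    ``(g, standard_error)``.  A weighted trend test on the per-bin log ratio
    guards against slow rotors (residual anisotropy makes the ratio drift):
    a trend with |z| above ``flatness_z`` raises :class:`FitError`.
    """
    hist = build_decay(stream, n_bins=n_bins)
    t = hist.bin_centers_ns
    total = total_decay(hist, 1.0)
    peak = _smoothed_peak_bin(total)
    if tail_start_ns is None:
        tail_start_ns = t[peak] + 2.0
    sel = (t >= tail_start_ns) & (hist.counts_perpendicular > min_counts_per_bin) \
        & (hist.counts_parallel > min_counts_per_bin)
    p = hist.counts_parallel[sel]
    q = hist.counts_perpendicular[sel]
    if p.size < 10 or p.sum() < 1000:
        raise FitError("insufficient tail counts for a g-factor estimate")
    g = float(p.sum() / q.sum())
    g_err = g * math.sqrt(1.0 / p.sum() + 1.0 / q.sum())

    # flatness check: weighted regression of log(p/q) on t
    logratio = np.log(p / q)
    var = 1.0 / p + 1.0 / q
    w = 1.0 / var
    x = t[sel]
    xm = np.average(x, weights=w)
    ym = np.average(logratio, weights=w)
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (logratio - ym)) / sxx
    slope_err = math.sqrt(1.0 / sxx)
    z = slope / slope_err
    if abs(z) > flatness_z:
        raise FitError(
            f"channel ratio trends across the tail (z = {z:.1f}); the rotor is "
            "not fast enough for tail-fit g estimation")
    return g, g_err
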