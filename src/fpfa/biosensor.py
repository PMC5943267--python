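"""Sample-level biosensor analysis.

Stoichiometry from normalized molecular brightness (ρ = η_c/η_m, optionally
corrected for a lifetime change of the complex by the factor ⟨τ_m⟩/⟨τ_c⟩),
FRET efficiency from amplitude-weighted lifetimes (E = 1 − τ/τ_donor), and
calcium dose-response fitting with a four-parameter variable-slope Hill
model or a biphasic (two-site, shared plateau) variant.

Dose-response fits operate on log10 of molar ligand concentration.  pCa here
means −log10([Ca²⁺]/M).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .errors import FitError, ValidationError

__all__ = [
    "StoichiometryResult",
    "DoseResponseFit",
    "normalized_brightness",
    "normalized_brightness_lifetime_corrected",
    "stoichiometry_regression",
    "fret_efficiency_from_lifetime",
    "delta_fret_efficiency",
    "hill4",
    "biphasic",
    "fit_dose_response",
    "plateau_change",
]


def normalized_brightness(eta_complex: float, eta_monomer: float) -> float:
    """Normalized brightness ρ = η_c/η_m (≈ number of fluorophores/complex)."""
    if eta_monomer <= 0:
        raise ValidationError("monomer brightness must be > 0")
    return float(eta_complex) / float(eta_monomer)


def normalized_brightness_lifetime_corrected(eta_complex: float, eta_monomer: float,
                                             tau_monomer_ns: float,
                                             tau_complex_ns: float) -> float:
    """ρ = η_c·(⟨τ_m⟩/⟨τ_c⟩)/η_m — compensates brightness for quenching.

    Reduces to the plain ratio when the lifetimes are equal.
    """
    if tau_monomer_ns <= 0 or tau_complex_ns <= 0:
        raise ValidationError("lifetimes must be > 0")
    return normalized_brightness(eta_complex, eta_monomer) * tau_monomer_ns / tau_complex_ns


@dataclass(frozen=True)
class StoichiometryResult:
    """Brightness-based subunit count for one complex vs a monomer control."""

    eta_complex: float
    eta_monomer: float
    tau_monomer_ns: float | None
    tau_complex_ns: float | None

    @property
    def rho(self) -> float:
        return normalized_brightness(self.eta_complex, self.eta_monomer)

    @property
    def rho_lifetime_corrected(self) -> float:
        if self.tau_monomer_ns is None or self.tau_complex_ns is None:
            raise ValidationError("lifetimes required for the corrected ratio")
        return normalized_brightness_lifetime_corrected(
            self.eta_complex, self.eta_monomer, self.tau_monomer_ns, self.tau_complex_ns)


def stoichiometry_regression(points) -> tuple:
    """OLS of ρ against fluorophore count; returns (slope, intercept, ci95).

    ``points`` is an iterable of (n_fluorophores, rho); ``ci95`` is the 95%
    confidence interval on the slope, (lo, hi).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.shape[0] < 3:
        raise FitError("stoichiometry regression needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    fit = stats.linregress(x, y)
    dof = pts.shape[0] - 2
    tcrit = stats.t.ppf(0.975, dof)
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return float(fit.slope), float(fit.intercept), (float(ci[0]), float(ci[1]))


def fret_efficiency_from_lifetime(tau_sample_ns: float, tau_donor_ns: float) -> float:
    """FRET efficiency E = 1 − τ_sample/τ_donor (fraction, not percent)."""
    if tau_sample_ns <= 0 or tau_donor_ns <= 0:
        raise ValidationError("lifetimes must be > 0")
    if tau_sample_ns > tau_donor_ns:
        warnings.warn("sample lifetime exceeds donor-only lifetime; E < 0")
    return 1.0 - tau_sample_ns / tau_donor_ns


def delta_fret_efficiency(tau_low_ns: float, tau_high_ns: float,
                          tau_donor_ns: float) -> float:
    """Change in FRET efficiency between two states, (τ_high − τ_low)/τ_donor."""
    if min(tau_low_ns, tau_high_ns, tau_donor_ns) <= 0:
        raise ValidationError("lifetimes must be > 0")
    return (tau_high_ns - tau_low_ns) / tau_donor_ns


# ---------------------------------------------------------------------------
# dose-response models
# ---------------------------------------------------------------------------

def hill4(x, bottom: float, top: float, log_kd: float, hill: float):
    """Four-parameter variable-slope dose response on a log10 axis."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_kd - x) * hill))


def biphasic(x, bottom: float, top: float, log_kd_1: float, hill_1: float,
             log_kd_2: float, hill_2: float, fraction_1: float):
    """Two-transition dose response sharing bottom/top, GraphPad style."""
    x = np.asarray(x, dtype=float)
    phase1 = fraction_1 / (1.0 + 10.0 ** ((log_kd_1 - x) * hill_1))
    phase2 = (1.0 - fraction_1) / (1.0 + 10.0 ** ((log_kd_2 - x) * hill_2))
    return bottom + (top - bottom) * (phase1 + phase2)


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted dose-response parameters (concentration axis: log10 molar)."""

    model: str                      # "hill4" or "biphasic"
    bottom: float
    top: float
    log_kd: float | None = None
    hill: float | None = None
    log_kd_1: float | None = None
    hill_1: float | None = None
    log_kd_2: float | None = None
    hill_2: float | None = None
    fraction_phase1: float | None = None
    chi2_reduced: float = math.nan
    param_errors: dict = None
    success: bool = True
    message: str = ""
    flags: tuple = ()

    @property
    def kd_molar(self) -> float | None:
        return 10.0 ** self.log_kd if self.log_kd is not None else None

    @property
    def kd_1_molar(self) -> float | None:
        return 10.0 ** self.log_kd_1 if self.log_kd_1 is not None else None

    @property
    def kd_2_molar(self) -> float | None:
        return 10.0 ** self.log_kd_2 if self.log_kd_2 is not None else None

    def predict(self, x) -> np.ndarray:
        if self.model == "hill4":
            return hill4(x, self.bottom, self.top, self.log_kd, self.hill)
        return biphasic(x, self.bottom, self.top, self.log_kd_1, self.hill_1,
                        self.log_kd_2, self.hill_2, self.fraction_phase1)


def fit_dose_response(log10_conc, y, y_err=None, model: str = "hill4") -> DoseResponseFit:
    """Weighted dose-response fit with a deterministic multi-start grid.

    ``log10_conc`` is log10 of molar concentration.  The log-Kd axis is
    multi-started on a fixed grid across the data range (6 points for
    hill4, a small Kd₁ × gap grid for biphasic) and the best χ² wins, making
    the fit deterministic.  Flat data and boundary-saturating biphasic
    fractions are flagged rather than raised.
    """
    x = np.asarray(log10_conc, dtype=float)
    yv = np.asarray(y, dtype=float)
    if model not in ("hill4", "biphasic"):
        raise ValidationError(f"unknown dose-response model {model!r}")
    min_pts = 5 if model == "hill4" else 7
    if x.size < min_pts:
        raise FitError(f"{model} fit needs at least {min_pts} points")
    if x.size != yv.size:
        raise ValidationError("x and y must have equal length")
    if y_err is not None:
        err = np.asarray(y_err, dtype=float)
        w = np.where(err > 0, 1.0 / np.where(err > 0, err, 1.0), 0.0)
        if not np.any(w > 0):
            w = np.ones_like(yv)
        else:
            w = np.where(w > 0, w, np.median(w[w > 0]))
    else:
        w = np.ones_like(yv)

    span = float(yv.max() - yv.min())
    flags: list[str] = []
    noise = float(np.median(np.abs(np.diff(yv)))) if yv.size > 1 else 0.0
    if span == 0 or (y_err is not None and span < 2 * float(np.median(np.asarray(y_err)))):
        flags.append("flat_response_kd_unidentifiable")

    increasing = yv[np.argsort(x)][-2:].mean() >= yv[np.argsort(x)][:2].mean()
    b0 = float(yv.min() if increasing else yv.max())
    t0 = float(yv.max() if increasing else yv.min())
    if b0 == t0:
        t0 = b0 + max(noise, 1e-12, abs(b0) * 1e-6)

    grid = np.linspace(x.min(), x.max(), 6)

    def run(params) -> lmfit.minimizer.MinimizerResult:
        def residual(p):
            if model == "hill4":
                pred = hill4(x, p["bottom"].value, p["top"].value,
                             p["log_kd"].value, p["hill"].value)
            else:
                frac = 1.0 / (1.0 + math.exp(-p["logit_f"].value))
                pred = biphasic(x, p["bottom"].value, p["top"].value,
                                p["log_kd_1"].value, p["hill_1"].value,
                                p["log_kd_1"].value + math.exp(p["ln_gap"].value),
                                p["hill_2"].value, frac)
            return (yv - pred) * w
        return lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")

    best = None
    if model == "hill4":
        for lk0 in grid:
            params = lmfit.Parameters()
            params.add("bottom", value=b0)
            params.add("top", value=t0)
            params.add("log_kd", value=float(lk0))
            params.add("hill", value=1.0 if increasing else 1.0)
            try:
                result = run(params)
            except Exception:
                continue
            if best is None or result.chisqr < best.chisqr:
                best = result
    else:
        for lk0 in grid[:4]:
            for gap0 in (0.7, 1.5, 2.5):
                params = lmfit.Parameters()
                params.add("bottom", value=b0)
                params.add("top", value=t0)
                params.add("log_kd_1", value=float(lk0))
                params.add("hill_1", value=1.0)
                params.add("ln_gap", value=math.log(gap0))
                params.add("hill_2", value=1.0)
                params.add("logit_f", value=0.0)
                try:
                    result = run(params)
                except Exception:
                    continue
                if best is None or result.chisqr < best.chisqr:
                    best = result

    if best is None:
        return DoseResponseFit(model=model, bottom=b0, top=t0, chi2_reduced=math.nan,
                               param_errors={}, success=False,
                               message="no start converged", flags=("non_convergence",))

    p = best.params
    errors = {name: (p[name].stderr if p[name].stderr is not None else None) for name in p}
    if not best.success:
        flags.append("non_convergence")
    if model == "hill4":
        return DoseResponseFit(model=model, bottom=float(p["bottom"].value),
                               top=float(p["top"].value), log_kd=float(p["log_kd"].value),
                               hill=float(p["hill"].value),
                               chi2_reduced=float(best.redchi), param_errors=errors,
                               success=bool(best.success), message=str(best.message),
                               flags=tuple(flags))
    frac = 1.0 / (1.0 + math.exp(-p["logit_f"].value))
    if frac < 0.05 or frac > 0.95:
        flags.append("monophasic_sufficient")
        warnings.warn("biphasic fraction saturates; a monophasic model may suffice")
    lk1 = float(p["log_kd_1"].value)
    lk2 = lk1 + math.exp(p["ln_gap"].value)
    return DoseResponseFit(model=model, bottom=float(p["bottom"].value),
                           top=float(p["top"].value),
                           log_kd_1=lk1, hill_1=float(p["hill_1"].value),
                           log_kd_2=lk2, hill_2=float(p["hill_2"].value),
                           fraction_phase1=float(frac),
                           chi2_reduced=float(best.redchi), param_errors=errors,
                           success=bool(best.success), message=str(best.message),
                           flags=tuple(flags))


def plateau_change(high: float, low: float) -> float:
    """Percent drop 100·(high − low)/high; positive = signal decreased."""
    if high == 0:
        raise ValidationError("reference plateau must be nonzero")
    return 100.0 * (high - low) / high
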