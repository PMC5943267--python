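"""Instrument calibration: beam waists, observation volume, concentration.

A dye with a known diffusion coefficient (fluorescein, D = 436 µm²/s at room
temperature and high pH) ties the fitted correlation time to the radial beam
waist through τ_D = ω²/8D (two-photon excitation).  The axial ratio ω/z is
measured by globally fitting correlation curves of a dilution series, where
only ⟨N⟩ may change between curves.  The two-photon observation volume is
then V = π^{3/2}·ω²·z/8, which converts fitted ⟨N⟩ into molar concentration.

Units follow the conventions every worked number in this workflow uses:
ω in nm, z in µm, τ_D in µs, D in µm²/s, V in fl (1 fl = 1 µm³), C in nM.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import lmfit
import numpy as np

from .errors import FitError, ValidationError
from .fcs import GAMMA_2P, CorrelationCurve, fcs_model

__all__ = [
    "FLUORESCEIN_D_UM2_S",
    "AVOGADRO",
    "Calibration",
    "tau_d_to_D",
    "omega_from_standard",
    "observation_volume",
    "z_from_omega",
    "concentration_from_N",
    "global_fit_omega_z",
]

#: fluorescein diffusion coefficient in water at room temperature, high pH
#: (Culbertson, Jacobson & Ramsey, Talanta 56:365, 2002)
FLUORESCEIN_D_UM2_S = 436.0

AVOGADRO = 6.02214076e23  # 1/mol


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (value > 0 and math.isfinite(value)):
            raise ValidationError(f"{name} must be a positive finite number, got {value!r}")


def tau_d_to_D(tau_d_us: float, omega_nm: float) -> float:
    """Diffusion coefficient D = ω²/(8·τ_D) in µm²/s."""
    _require_positive(tau_d_us=tau_d_us, omega_nm=omega_nm)
    omega_um = omega_nm * 1e-3
    return omega_um**2 / (8.0 * tau_d_us * 1e-6)


def omega_from_standard(tau_d_us: float, d_um2_s: float = FLUORESCEIN_D_UM2_S) -> float:
    """Radial beam waist ω = sqrt(8·D·τ_D) in nm, from a diffusion standard."""
    _require_positive(tau_d_us=tau_d_us, d_um2_s=d_um2_s)
    omega_um = math.sqrt(8.0 * d_um2_s * tau_d_us * 1e-6)
    return omega_um * 1e3


def z_from_omega(omega_nm: float, omega_over_z: float) -> float:
    """Axial waist z = ω/(ω/z) in µm."""
    _require_positive(omega_nm=omega_nm, omega_over_z=omega_over_z)
    return omega_nm / omega_over_z * 1e-3


def observation_volume(omega_nm: float, z_um: float) -> float:
    """Two-photon observation volume V = π^{3/2}·ω²·z/8 in femtoliters."""
    _require_positive(omega_nm=omega_nm, z_um=z_um)
    omega_um = omega_nm * 1e-3
    return math.pi**1.5 * omega_um**2 * z_um / 8.0


def concentration_from_N(n_mean: float, volume_fl: float) -> float:
    """Molar concentration C = ⟨N⟩/(V·N_A) in nM."""
    _require_positive(volume_fl=volume_fl)
    if n_mean < 0:
        raise ValidationError("n_mean must be >= 0")
    liters = volume_fl * 1e-15
    return n_mean / (liters * AVOGADRO) * 1e9


@dataclass(frozen=True)
class Calibration:
    """Everything needed to convert fitted FCS parameters to physical units."""

    g_factor: float
    omega_nm: float
    omega_over_z: float
    gamma: float = GAMMA_2P
    excitation_power_mw: float | None = None
    standard_name: str = "fluorescein"
    standard_d_um2_s: float = FLUORESCEIN_D_UM2_S

    def __post_init__(self) -> None:
        _require_positive(g_factor=self.g_factor, omega_nm=self.omega_nm)
        if not 0 < self.omega_over_z < 1:
            raise ValidationError("omega_over_z must lie in (0, 1)")

    @property
    def z_um(self) -> float:
        return z_from_omega(self.omega_nm, self.omega_over_z)

    @property
    def volume_fl(self) -> float:
        return observation_volume(self.omega_nm, self.z_um)

    def diffusion_coefficient(self, tau_d_us: float) -> float:
        return tau_d_to_D(tau_d_us, self.omega_nm)

    def concentration_nM(self, n_mean: float) -> float:
        return concentration_from_N(n_mean, self.volume_fl)

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = asdict(self)
        payload["z_um"] = self.z_um
        payload["volume_fl"] = self.volume_fl
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "Calibration":
        raw = json.loads(Path(path).read_text())
        raw.pop("z_um", None)
        raw.pop("volume_fl", None)
        return cls(**raw)


@dataclass(frozen=True)
class GlobalDilutionFit:
    """Result of the ω/z global fit over a dilution series."""

    omega_over_z: float
    tau_d_us: float
    n_means: tuple
    dilution_factors: tuple
    proportionality_r2: float
    chi2_reduced: float
    param_errors: dict
    success: bool
    message: str


def global_fit_omega_z(curves: list, dilution_factors: list,
                       gamma: float = GAMMA_2P) -> GlobalDilutionFit:
    """Global fit of a dilution series: shared (ω/z, τ_D), per-curve ⟨N⟩.

    The calibration premise is that dilution changes only ⟨N⟩; the recovered
    ⟨N⟩ values are regressed (through the origin) against the dilution
    factors and the R² of that proportionality is reported.  R² < 0.95
    triggers a warning, as does a poor shared-τ_D global fit.
    """
    if len(curves) < 3:
        raise FitError("global ω/z fitting needs at least 3 dilution curves")
    if len(dilution_factors) != len(curves):
        raise ValidationError("need one dilution factor per curve")
    dilutions = np.asarray(dilution_factors, dtype=float)
    if np.any(dilutions <= 0):
        raise ValidationError("dilution factors must be > 0")

    params = lmfit.Parameters()
    g0 = max(float(curves[0].G[0]), 1e-8)
    # the axial ratio of a real two-photon volume lies well inside (0.005, 0.9);
    # bounding it keeps noisy series from collapsing the axial term entirely
    params.add("ln_woz", value=math.log(0.2),
               min=math.log(5e-3), max=math.log(0.9))
    half = np.flatnonzero(curves[0].G < g0 / 2)
    tau0 = float(curves[0].lag_s[half[0]]) if half.size else float(curves[0].lag_s[-1] / 4)
    params.add("ln_tau_d", value=math.log(tau0))
    for i, curve in enumerate(curves):
        gi = max(float(curve.G[0]), 1e-8)
        params.add(f"ln_n_{i}", value=math.log(gamma / gi))

    weights = []
    for curve in curves:
        if curve.G_err is not None:
            err = np.where((curve.G_err > 0) & np.isfinite(curve.G_err), curve.G_err, np.nan)
            fallback = np.nanmedian(err) if np.isfinite(err).any() else 1.0
            weights.append(1.0 / np.where(np.isfinite(err), err, fallback))
        else:
            weights.append(np.ones_like(curve.G))

    def residual(p):
        woz = math.exp(min(max(p["ln_woz"].value, -250.0), 250.0))
        tau_d = math.exp(min(max(p["ln_tau_d"].value, -250.0), 250.0))
        out = []
        for i, curve in enumerate(curves):
            n = math.exp(min(max(p[f"ln_n_{i}"].value, -250.0), 250.0))
            out.append((curve.G - fcs_model(curve.lag_s, n, tau_d, woz, gamma)) * weights[i])
        return np.concatenate(out)

    result = lmfit.minimize(residual, params, method="leastsq", nan_policy="raise")
    woz = math.exp(result.params["ln_woz"].value)
    tau_d = math.exp(result.params["ln_tau_d"].value)
    n_means = np.array([math.exp(result.params[f"ln_n_{i}"].value) for i in range(len(curves))])

    # proportionality of N with dilution, regression through the origin
    slope = float(np.sum(dilutions * n_means) / np.sum(dilutions**2))
    ss_res = float(np.sum((n_means - slope * dilutions) ** 2))
    ss_tot = float(np.sum((n_means - n_means.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0.95:
        warnings.warn(f"fitted ⟨N⟩ not proportional to dilution (R² = {r2:.3f}); "
                      "the dilution-series premise looks violated")
    if np.isfinite(result.redchi) and result.redchi > 5:
        warnings.warn(f"poor global fit (reduced chi² = {result.redchi:.2f}); "
                      "τ_D may not be shared across dilutions")

    errors: dict[str, float | None] = {}
    stderr = result.params["ln_woz"].stderr
    errors["omega_over_z"] = stderr * woz if stderr is not None else None
    stderr = result.params["ln_tau_d"].stderr
    errors["tau_d_us"] = stderr * tau_d * 1e6 if stderr is not None else None
    return GlobalDilutionFit(omega_over_z=woz, tau_d_us=tau_d * 1e6,
                             n_means=tuple(n_means), dilution_factors=tuple(dilutions),
                             proportionality_r2=r2, chi2_reduced=float(result.redchi),
                             param_errors=errors, success=bool(result.success),
                             message=str(result.message))
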