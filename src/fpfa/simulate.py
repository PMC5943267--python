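"""Monte-Carlo simulation of dual-polarization TCSPC photon streams.

The generator emulates the physics a two-photon FPFA microscope sees:

* molecules diffuse (Brownian motion, diffusion coefficient ``D``) through a
  periodic box containing a 3D-Gaussian two-photon detection profile
  ``W(x, y, z') = exp(-4x²/ω² - 4y²/ω² - 4z'²/z²)``;
* each molecule emits photons as an inhomogeneous Poisson process with
  instantaneous rate ``η_peak · W · B(t)``, where ``B(t)`` is a two-state
  bright/dark flicker telegraph with stationary dark fraction ``T`` and
  relaxation time ``τ_T``;
* each photon draws a fluorescence delay from the (multi-)exponential decay,
  folded into the sync period and quantized to TAC bins;
* the photon reaches the parallel detector with probability ``(1 + 2r)/3``
  and the perpendicular detector with probability ``(1 - r)/(3g)``, where
  ``r(t) = r_∞ + (r0 - r_∞)·exp(-t/θ)`` is the time-resolved anisotropy at
  its fluorescence delay; the remaining emission (the polarization component
  along the collection axis, plus the detection imbalance the g-factor
  corrects) is lost.  This reproduces ``I_∥ ∝ f(t)(1+2r)/3`` and
  ``I_⊥ ∝ f(t)(1-r)/(3g)`` — and hence the anisotropy and total-decay
  relations — exactly by construction;
* independent Poisson dark counts with uniform micro-times are added per
  channel.

Photon emission is sampled by Poisson thinning: candidate photon times are a
homogeneous Poisson process at the peak rate per molecule, the Brownian
position is sampled *exactly* at those times (Gaussian increments with
variance ``2DΔt`` per axis), and candidates are accepted with probability
``W``.  The flicker telegraph is evaluated exactly at the surviving candidate
times through its two-state transition kernel.  The scheme therefore has no
time-discretization error.

Brightness convention: ``eta_cpms`` is the molecular brightness that
⟨k⟩/⟨N⟩ analysis recovers, i.e. the detected count rate is
``⟨N⟩·η·(1-T) + 2·dark`` with ``⟨N⟩ = C·V_eff`` and
``V_eff = π^{3/2}ω²z/8``.  Because ``∫W dV = V_eff`` exactly, the emitted
peak rate equals ``η`` up to the mean polarization detection efficiency,
which the simulator divides out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numba
import numpy as np

from .errors import SimulationSizeError, ValidationError
from .photons import AcquisitionMeta, PhotonStream

__all__ = ["SimConfig", "simulate_stream", "expected_count_rate", "read_sim_config", "write_sim_config"]

_SYNC_RATE_DEFAULT = 80e6
_MICRO_BIN_DEFAULT = 1e9 / _SYNC_RATE_DEFAULT / 1024  # 1024 TAC bins over 12.5 ns

#: refuse configurations implying more detected photons than this
MAX_EXPECTED_PHOTONS = 1e8
#: refuse configurations implying more thinning candidates than this
MAX_CANDIDATES = 6e9


@dataclass(frozen=True)
class SimConfig:
    """Physical and numerical parameters of a simulated acquisition.

    Defaults emulate a Venus-monomer cell homogenate on the instrument the
    package targets: ⟨N⟩ ≈ 50 molecules in a 494 nm / ω/z = 0.049 two-photon
    volume, brightness ≈ 850 cpms, mono-exponential 3.154 ns lifetime, a
    ~16 ns rotational correlation time, g = 1.07 and a few hundred cps of
    detector dark counts.
    """

    n_molecules_mean: float = 50.0          # ⟨N⟩ in the effective volume
    D_um2_s: float = 81.0                   # diffusion coefficient, µm²/s
    omega_nm: float = 494.0                 # radial 1/e² waist
    omega_over_z: float = 0.049             # radial/axial waist ratio
    eta_cpms: float = 850.0                 # molecular brightness (fit convention)
    lifetime_components: tuple = ((1.0, 3.154),)  # (decay amplitude, tau_ns)
    r0: float = 0.50                        # initial anisotropy (two-photon limit 0.57)
    theta_rot_ns: float = 16.0              # rotational correlation time
    r_inf: float = 0.0                      # residual (hindered-rotor) anisotropy
    flicker_T: float = 0.0                  # stationary dark-state fraction
    flicker_tau_T_us: float = 50.0          # flicker relaxation time
    g_factor: float = 1.07                  # detection imbalance (perp / g)
    dark_cps: float = 450.0                 # dark counts per channel
    duration_s: float = 60.0
    seed: int = 0
    sync_rate_hz: float = _SYNC_RATE_DEFAULT
    micro_bin_ns: float = _MICRO_BIN_DEFAULT
    box_xy_margin: float = 4.0              # lateral box half-size, units of ω
    box_z_margin: float = 1.25              # axial box half-size, units of z
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_molecules_mean < 0:
            raise ValidationError("n_molecules_mean must be >= 0")
        for name in ("D_um2_s", "omega_nm", "omega_over_z", "eta_cpms", "theta_rot_ns",
                     "flicker_tau_T_us", "g_factor", "duration_s", "sync_rate_hz",
                     "micro_bin_ns", "box_xy_margin", "box_z_margin"):
            if getattr(self, name) < 0 or (name not in ("theta_rot_ns",) and getattr(self, name) == 0):
                raise ValidationError(f"{name} must be > 0")
        amps = np.array([a for a, _ in self.lifetime_components], dtype=float)
        taus = np.array([t for _, t in self.lifetime_components], dtype=float)
        if amps.size == 0 or np.any(amps <= 0) or np.any(taus <= 0):
            raise ValidationError("lifetime components need positive amplitudes and lifetimes")
        if not math.isclose(amps.sum(), 1.0, rel_tol=1e-6):
            raise ValidationError("lifetime component amplitudes must sum to 1")
        if not (0.0 <= self.r_inf <= self.r0 <= 0.57):
            raise ValidationError("need 0 <= r_inf <= r0 <= 0.57 (two-photon limit)")
        if not (0.0 <= self.flicker_T < 1.0):
            raise ValidationError("flicker_T must lie in [0, 1)")

    # -- derived quantities -------------------------------------------------

    @property
    def tau_d_us(self) -> float:
        """Diffusion (correlation) time ω²/8D, in µs."""
        omega_um = self.omega_nm * 1e-3
        return omega_um**2 / (8.0 * self.D_um2_s) * 1e6

    @property
    def z_um(self) -> float:
        return self.omega_nm * 1e-3 / self.omega_over_z

    @property
    def effective_volume_um3(self) -> float:
        omega_um = self.omega_nm * 1e-3
        return math.pi**1.5 * omega_um**2 * self.z_um / 8.0

    def photon_weights(self) -> np.ndarray:
        """Photon (area) fraction of each lifetime component, a_i·τ_i normalized."""
        a = np.array([c[0] for c in self.lifetime_components])
        t = np.array([c[1] for c in self.lifetime_components])
        w = a * t
        return w / w.sum()

    def anisotropy_at(self, t_ns) -> np.ndarray:
        t_ns = np.asarray(t_ns, dtype=float)
        if self.theta_rot_ns <= 0:
            return np.full_like(t_ns, self.r_inf)
        return self.r_inf + (self.r0 - self.r_inf) * np.exp(-t_ns / self.theta_rot_ns)

    def steady_state_anisotropy(self) -> float:
        """Photon-weighted mean of r(t): what steady-state analysis measures."""
        if self.theta_rot_ns <= 0:
            return self.r_inf
        w = self.photon_weights()
        taus = np.array([c[1] for c in self.lifetime_components])
        decay_mean = float(np.sum(w * self.theta_rot_ns / (self.theta_rot_ns + taus)))
        return self.r_inf + (self.r0 - self.r_inf) * decay_mean

    def mean_detection_efficiency(self) -> float:
        """⟨(1+2r)/3 + (1−r)/(3g)⟩ over the photon delay distribution.

        The fraction of emitted photons that reaches either detector,
        averaged over the fluorescence delay (Gauss-Laguerre quadrature per
        lifetime component); the simulator divides the brightness by this so
        the *detected* rate matches the ⟨k⟩/⟨N⟩ brightness convention.
        """
        x, lam = np.polynomial.laguerre.laggauss(64)
        w = self.photon_weights()
        taus = np.array([c[1] for c in self.lifetime_components])
        total = 0.0
        for wi, tau in zip(w, taus):
            r = self.anisotropy_at(tau * x)
            eff = (1.0 + 2.0 * r) / 3.0 + (1.0 - r) / (3.0 * self.g_factor)
            total += wi * float(np.sum(lam * eff))
        return total

    def acquisition_meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            sync_rate_hz=self.sync_rate_hz,
            macro_tick_s=1.0 / self.sync_rate_hz,
            micro_bin_ns=self.micro_bin_ns,
            duration_s=self.duration_s,
            dark_cps=self.dark_cps,
            label=self.label,
        )


def expected_count_rate(config: SimConfig) -> float:
    """Closed-form prediction of the detected count rate (both channels), cps.

    ``⟨k⟩ = ⟨N⟩ · η · (1 - T) + 2 · dark``: the simulator scales its internal
    peak emission rate so that the brightness convention holds exactly; the
    bright-state fraction (1 - T) and the two dark-count channels are the only
    other contributions.
    """
    return (config.n_molecules_mean * config.eta_cpms * (1.0 - config.flicker_T)
            + 2.0 * config.dark_cps)


@numba.njit(cache=False)
def _emission_pass(gaps, steps, starts, u_accept, inv_rate, two_d, duration,
                   half_xy, half_z, inv_w2, inv_z2,
                   out_times, out_counts):  # pragma: no cover
    """Fused per-chunk pass: Brownian chain, periodic wrap, W-thinning.

    Consumes pre-drawn randoms (exponential gaps, normal steps, uniform
    start positions and accept variables) so photon streams are reproducible
    from the numpy generator alone.  Accepted candidate times are written to
    ``out_times`` molecule-major; ``out_counts[i]`` receives the number of
    acceptances of molecule ``i``.  Returns the total count.
    """
    m, n = gaps.shape
    count = 0
    for i in range(m):
        t = 0.0
        x = starts[i, 0]
        y = starts[i, 1]
        z = starts[i, 2]
        n_i = 0
        for j in range(n):
            dt = gaps[i, j] * inv_rate
            t += dt
            if t >= duration:
                break
            if j > 0:
                sx = np.sqrt(two_d * dt)
                x += steps[i, j, 0] * sx
                y += steps[i, j, 1] * sx
                z += steps[i, j, 2] * sx
                if x > half_xy or x < -half_xy:
                    x = ((x + half_xy) % (2.0 * half_xy)) - half_xy
                if y > half_xy or y < -half_xy:
                    y = ((y + half_xy) % (2.0 * half_xy)) - half_xy
                if z > half_z or z < -half_z:
                    z = ((z + half_z) % (2.0 * half_z)) - half_z
            arg = (x * x + y * y) * inv_w2 + z * z * inv_z2
            # exp(-16) ~ 1e-7: candidates that far out never survive
            if arg < 16.0 and u_accept[i, j] < np.exp(-arg):
                out_times[count] = t
                count += 1
                n_i += 1
        out_counts[i] = n_i
    return count


@numba.njit(cache=False)
def _telegraph_thin(times, counts, u_relax, u_fresh, dark_fraction,
                    tau_t, keep):  # pragma: no cover
    """Exact two-state flicker thinning at the accepted candidate times.

    By the Markov property the bright/dark state only needs evaluating at
    the times where a photon could be emitted: over a gap Δ the state is
    kept with probability exp(-Δ/τ_T), otherwise redrawn stationary.
    """
    idx = 0
    for i in range(counts.size):
        prev_t = -1.0
        bright = False
        for _ in range(counts[i]):
            t = times[idx]
            if prev_t < 0.0 or u_relax[idx] < -np.expm1(-(t - prev_t) / tau_t):
                bright = u_fresh[idx] >= dark_fraction
            prev_t = t
            keep[idx] = bright
            idx += 1
    return idx


def simulate_stream(config: SimConfig) -> PhotonStream:
    """Generate a photon stream for ``config``; bit-identical for equal seeds."""
    rng = np.random.default_rng(config.seed)
    duration = config.duration_s

    omega_um = config.omega_nm * 1e-3
    z_um = config.z_um
    half_xy = config.box_xy_margin * omega_um
    half_z = config.box_z_margin * z_um
    v_box = (2 * half_xy) ** 2 * (2 * half_z)
    n_box = int(round(config.n_molecules_mean * v_box / config.effective_volume_um3))

    detection = config.mean_detection_efficiency()
    eta_peak = config.eta_cpms / detection

    expected = expected_count_rate(config) * duration
    if expected > MAX_EXPECTED_PHOTONS:
        raise SimulationSizeError(
            f"configuration implies ~{expected:.3g} detected photons "
            f"(limit {MAX_EXPECTED_PHOTONS:.0g}); shorten duration or dim the sample")
    n_candidates_est = n_box * eta_peak * duration
    if n_candidates_est > MAX_CANDIDATES:
        raise SimulationSizeError(
            f"configuration implies ~{n_candidates_est:.3g} candidate photons "
            f"(limit {MAX_CANDIDATES:.0g}); reduce box margins, ⟨N⟩ or duration")

    emission_times: list[np.ndarray] = []
    if n_box > 0 and config.eta_cpms > 0:
        lam = eta_peak * duration
        # candidate times are exponential-gap cumsums (a Poisson process at
        # the peak rate); nmax covers the Poisson count to ~6.5 sigma
        nmax = int(lam + 6.5 * math.sqrt(lam) + 20.0)
        chunk = max(1, int(2**21 / nmax))
        halves = np.array([half_xy, half_xy, half_z])
        tau_t_s = config.flicker_tau_T_us * 1e-6
        for start in range(0, n_box, chunk):
            m = min(chunk, n_box - start)
            gaps = rng.standard_exponential((m, nmax), dtype=np.float32)
            # position at the first candidate is uniform (stationary under
            # periodic wrap); Brownian increments thereafter
            steps = rng.standard_normal((m, nmax, 3), dtype=np.float32)
            starts = rng.random((m, 3)) * (2 * halves) - halves
            u_accept = rng.random((m, nmax), dtype=np.float32)
            out_times = np.empty(m * nmax, dtype=np.float64)
            out_counts = np.empty(m, dtype=np.int64)
            n_acc = _emission_pass(gaps, steps, starts, u_accept,
                                   1.0 / eta_peak, 2.0 * config.D_um2_s, duration,
                                   half_xy, half_z, 4.0 / omega_um**2, 4.0 / z_um**2,
                                   out_times, out_counts)
            accepted = out_times[:n_acc]
            if config.flicker_T > 0 and n_acc > 0:
                u_relax = rng.random(n_acc)
                u_fresh = rng.random(n_acc)
                keep = np.empty(n_acc, dtype=np.bool_)
                _telegraph_thin(accepted, out_counts, u_relax, u_fresh,
                                config.flicker_T, tau_t_s, keep)
                accepted = accepted[keep]
            emission_times.append(accepted.copy())

    if emission_times:
        t_emit = np.concatenate(emission_times)
    else:
        t_emit = np.empty(0, dtype=float)

    # fluorescence delay, polarization routing, detection thinning
    n = t_emit.size
    weights = config.photon_weights()
    taus = np.array([c[1] for c in config.lifetime_components])
    if weights.size == 1:
        delay_ns = rng.exponential(taus[0], size=n)
    else:
        comp = rng.choice(weights.size, size=n, p=weights)
        delay_ns = rng.exponential(1.0, size=n) * taus[comp]
    r = config.anisotropy_at(delay_ns)
    p_par = (1.0 + 2.0 * r) / 3.0
    p_perp = (1.0 - r) / (3.0 * config.g_factor)
    u = rng.random(n)
    parallel = u < p_par
    perp = (~parallel) & (u < p_par + p_perp)  # the rest of the emission is lost
    keep = parallel | perp
    t_emit = t_emit[keep]
    delay_ns = delay_ns[keep]
    channel = np.where(parallel[keep], 0, 1).astype(np.int8)

    meta = config.acquisition_meta()
    period_ns = meta.sync_period_ns
    n_micro = meta.n_micro_bins
    micro = np.minimum((np.mod(delay_ns, period_ns) / config.micro_bin_ns).astype(np.int64),
                       n_micro - 1)
    macro = (t_emit / meta.macro_tick_s).astype(np.int64)

    # dark counts: uniform macro times, uniform micro-times, per channel
    dark_parts_macro = [macro]
    dark_parts_micro = [micro]
    dark_parts_chan = [channel]
    if config.dark_cps > 0:
        max_tick = int(duration / meta.macro_tick_s)
        for ch in (0, 1):
            n_dark = rng.poisson(config.dark_cps * duration)
            dark_parts_macro.append(rng.integers(0, max(max_tick, 1), size=n_dark))
            dark_parts_micro.append(rng.integers(0, n_micro, size=n_dark))
            dark_parts_chan.append(np.full(n_dark, ch, dtype=np.int8))
    macro = np.concatenate(dark_parts_macro)
    micro = np.concatenate(dark_parts_micro)
    channel = np.concatenate(dark_parts_chan)

    order = np.lexsort((micro, channel, macro))
    return PhotonStream(macro_time=macro[order], micro_time=micro[order],
                        channel=channel[order], meta=meta)


# ---------------------------------------------------------------------------
# flat key = value serialization
# ---------------------------------------------------------------------------

def write_sim_config(config: SimConfig, path) -> Path:
    """Serialize a SimConfig as a flat ``key = value`` text file."""
    path = Path(path)
    d = asdict(config)
    d["lifetime_components"] = ";".join(f"{a}:{t}" for a, t in config.lifetime_components)
    with open(path, "w") as fh:
        fh.write("# fpfa simulation config (units encoded in key names)\n")
        for key, value in d.items():
            fh.write(f"{key} = {value}\n")
    return path


def read_sim_config(path) -> SimConfig:
    """Read a SimConfig from a flat key = value file or a JSON file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
    else:
        raw = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
    kwargs = {}
    for f_name, f_type in _FIELD_TYPES.items():
        if f_name not in raw:
            continue
        value = raw[f_name]
        if f_name == "lifetime_components":
            if isinstance(value, str):
                parts = [p for p in value.split(";") if p.strip()]
                value = tuple((float(a), float(t)) for a, t in (p.split(":") for p in parts))
            else:
                value = tuple((float(a), float(t)) for a, t in value)
            kwargs[f_name] = value
        else:
            kwargs[f_name] = f_type(value)
    return SimConfig(**kwargs)


_FIELD_TYPES = {
    "n_molecules_mean": float, "D_um2_s": float, "omega_nm": float, "omega_over_z": float,
    "eta_cpms": float, "lifetime_components": tuple, "r0": float, "theta_rot_ns": float,
    "r_inf": float, "flicker_T": float, "flicker_tau_T_us": float, "g_factor": float,
    "dark_cps": float, "duration_s": float, "seed": int, "sync_rate_hz": float,
    "micro_bin_ns": float, "box_xy_margin": float, "box_z_margin": float, "label": str,
}
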