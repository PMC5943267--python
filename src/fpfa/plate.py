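"""Plate-level orchestration: per-well analysis, replicate QC, reports.

A plate run takes a manifest mapping wells to photon files (and optionally
ligand concentrations and replicate groups), analyzes every well with the
FCS + micro-time pipeline, and aggregates replicate statistics with
D'Agostino–Pearson normality-based outlier QC.  Outliers are flagged, never
silently removed: statistics with and without the flagged wells are both
reported.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import Calibration
from .errors import FpfaError, ValidationError
from .fcs import cross_correlate, fit_fcs, molecular_brightness
from .photons import PhotonStream, count_rate, read_photons
from .trfa import (anisotropy_decay, build_decay, fit_anisotropy_decay,
                   fit_lifetime, steady_state_anisotropy)

__all__ = [
    "AnalysisConfig",
    "WellSpec",
    "PlateManifest",
    "WellResult",
    "GroupStats",
    "PlateReport",
    "analyze_stream",
    "analyze_well",
    "replicate_stats",
    "run_plate",
    "export_report",
]

#: count-rate guidance band, cps: below ~20 kcps dark counts bite, above
#: ~100 kcps TCSPC pile-up distorts lifetimes
COUNT_RATE_BAND = (20_000.0, 100_000.0)

_METRICS = ("count_rate_cps", "n_mean", "brightness_cpms", "tau_d_us",
            "r_steady", "tau_avg_ns", "concentration_nM")


@dataclass(frozen=True)
class AnalysisConfig:
    """Per-well analysis settings."""

    n_repeats: int = 3              # equal segments analyzed independently
    base_bin_s: float = 2e-6
    corr_segments: int = 8          # error blocks per repeat for G_err
    decay_bins: int = 1024
    lifetime_components: int = 1
    #: significance level of the reduced-chi2 improvement needed to adopt the
    #: flicker model; the ratio threshold is 1 + chi2_{2,1-alpha}/dof so the
    #: rule stays calibrated regardless of how many lag points a curve has
    flicker_alpha: float = 1e-3
    try_flicker: bool = True
    min_counts_aniso: float = 25.0

    def flicker_ratio_threshold(self, n_points: int) -> float:
        dof = max(n_points - 4, 1)
        return 1.0 + stats.chi2.ppf(1.0 - self.flicker_alpha, 2) / dof


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    photon_file: str
    sample_label: str = ""
    conc_molar: float | None = None
    replicate_group: str = ""


@dataclass(frozen=True)
class PlateManifest:
    wells: tuple
    calibration_ref: str = ""

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValidationError("well_ids in a manifest must be unique")

    @classmethod
    def from_file(cls, path) -> "PlateManifest":
        path = Path(path)
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
            wells = tuple(WellSpec(**w) for w in raw["wells"])
            return cls(wells=wells, calibration_ref=raw.get("calibration_ref", ""))
        df = pd.read_csv(path)
        required = {"well_id", "photon_file"}
        if not required.issubset(df.columns):
            raise ValidationError(f"manifest needs columns {sorted(required)}")
        wells = []
        for _, row in df.iterrows():
            conc = row.get("conc_molar", np.nan)
            wells.append(WellSpec(
                well_id=str(row["well_id"]), photon_file=str(row["photon_file"]),
                sample_label=str(row.get("sample_label", "") or ""),
                conc_molar=None if pd.isna(conc) else float(conc),
                replicate_group=str(row.get("replicate_group", "") or "")))
        return cls(wells=tuple(wells))


@dataclass
class WellResult:
    """Per-well averaged observables (mean ± SD over repeats)."""

    well_id: str
    sample_label: str = ""
    replicate_group: str = ""
    conc_molar: float | None = None
    status: str = "ok"              # ok | failed | low_signal
    error: str = ""
    model: str = ""                 # FCS model chosen: plain | flicker
    flags: tuple = ()
    count_rate_cps: float = math.nan
    n_mean: float = math.nan
    brightness_cpms: float = math.nan
    tau_d_us: float = math.nan
    r_steady: float = math.nan
    tau_avg_ns: float = math.nan
    concentration_nM: float = math.nan
    flicker_T: float = math.nan
    flicker_tau_t_us: float = math.nan
    sd: dict = field(default_factory=dict)   # per-metric SD over repeats


def _segment_stream(stream: PhotonStream, n_repeats: int):
    from dataclasses import replace as dc_replace
    duration = stream.meta.duration_s
    seg = duration / n_repeats
    t = stream.seconds()
    for i in range(n_repeats):
        sel = (t >= i * seg) & (t < (i + 1) * seg)
        meta = dc_replace(stream.meta, duration_s=seg)
        macro = stream.macro_time[sel] - int(round(i * seg / stream.meta.macro_tick_s))
        yield PhotonStream(macro_time=macro, micro_time=stream.micro_time[sel],
                           channel=stream.channel[sel], meta=meta)


def analyze_stream(stream: PhotonStream, calibration: Calibration,
                   config: AnalysisConfig = AnalysisConfig(),
                   well_id: str = "", sample_label: str = "",
                   replicate_group: str = "", conc_molar: float | None = None) -> WellResult:
    """Analyze one acquisition: FCS + micro-time observables per repeat.

    The stream is split into ``n_repeats`` equal segments which are analyzed
    independently and averaged; the segment scatter is the per-well SD.  The
    FCS model (plain vs flicker) is chosen per well by a reduced-χ²
    improvement ratio.  The measured correlation amplitude is corrected for
    the uncorrelated dark-count background before ⟨N⟩ is read off, and the
    dark rate is subtracted from the count rate before brightness.
    """
    result = WellResult(well_id=well_id, sample_label=sample_label,
                        replicate_group=replicate_group, conc_molar=conc_molar)
    flags: list[str] = []
    total_rate = count_rate(stream)
    dark_total = 2.0 * stream.meta.dark_cps
    signal_rate = total_rate - dark_total
    result.count_rate_cps = total_rate
    if total_rate < COUNT_RATE_BAND[0] or total_rate > COUNT_RATE_BAND[1]:
        flags.append("count_rate_outside_guidance_band")
    if signal_rate <= 0 or (dark_total > 0 and signal_rate < 2 * dark_total):
        result.status = "low_signal"
        result.error = "signal below dark level; no fits attempted"
        result.flags = tuple(flags)
        return result

    background_factor = (total_rate / signal_rate) ** 2

    per_repeat: dict[str, list] = {m: [] for m in _METRICS}
    models = []
    t_fracs, tau_ts = [], []
    try:
        for seg in _segment_stream(stream, config.n_repeats):
            seg_total = count_rate(seg)
            seg_signal = seg_total - dark_total
            curve = cross_correlate(seg, base_bin_s=config.base_bin_s,
                                    n_segments=config.corr_segments)
            fit = fit_fcs(curve, model="plain", omega_over_z=calibration.omega_over_z,
                          gamma=calibration.gamma)
            chosen = fit
            if config.try_flicker:
                try:
                    flick = fit_fcs(curve, model="flicker",
                                    omega_over_z=calibration.omega_over_z,
                                    gamma=calibration.gamma)
                    threshold = config.flicker_ratio_threshold(flick.n_points)
                    if (flick.success and np.isfinite(flick.chi2_reduced)
                            and fit.chi2_reduced / flick.chi2_reduced > threshold):
                        chosen = flick
                except FpfaError:
                    pass
            models.append(chosen.model)
            n_corr = chosen.n_mean / background_factor
            per_repeat["count_rate_cps"].append(seg_total)
            per_repeat["n_mean"].append(n_corr)
            per_repeat["tau_d_us"].append(chosen.tau_d_us)
            per_repeat["brightness_cpms"].append(molecular_brightness(seg_signal, n_corr))
            per_repeat["concentration_nM"].append(calibration.concentration_nM(n_corr))
            if chosen.model == "flicker":
                t_fracs.append(chosen.T)
                tau_ts.append(chosen.tau_t_us)
            hist = build_decay(seg, n_bins=config.decay_bins)
            lt = fit_lifetime(hist, g_factor=calibration.g_factor,
                              n_components=config.lifetime_components)
            per_repeat["tau_avg_ns"].append(lt.tau_avg_ns)
            per_repeat["r_steady"].append(steady_state_anisotropy(hist, calibration.g_factor))
    except FpfaError as exc:
        result.status = "failed"
        result.error = str(exc)
        result.flags = tuple(flags)
        return result

    for metric, values in per_repeat.items():
        arr = np.asarray(values, dtype=float)
        setattr(result, metric, float(arr.mean()))
        result.sd[metric] = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    result.model = "flicker" if models.count("flicker") > len(models) / 2 else "plain"
    if t_fracs:
        result.flicker_T = float(np.mean(t_fracs))
        result.flicker_tau_t_us = float(np.mean(tau_ts))
    result.flags = tuple(flags)
    return result


def analyze_well(photon_file, calibration: Calibration,
                 config: AnalysisConfig = AnalysisConfig(),
                 spec: WellSpec | None = None) -> WellResult:
    """Load a photon file and analyze it (see :func:`analyze_stream`)."""
    stream = read_photons(photon_file)
    kwargs = {}
    if spec is not None:
        kwargs = dict(well_id=spec.well_id, sample_label=spec.sample_label,
                      replicate_group=spec.replicate_group, conc_molar=spec.conc_molar)
    return analyze_stream(stream, calibration, config, **kwargs)


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupStats:
    """Replicate summary for one group and one metric."""

    group: str
    metric: str
    n: int
    mean: float
    sd: float
    normality_p: float | None        # D'Agostino-Pearson omnibus p (n >= 8)
    normality_note: str
    outlier_wells: tuple             # flagged, never excluded automatically
    mean_excluding: float | None
    sd_excluding: float | None
    normality_p_excluding: float | None


def replicate_stats(results: list, group_key=None,
                    metrics=("brightness_cpms", "tau_d_us", "r_steady", "tau_avg_ns"),
                    z_threshold: float = 3.5, alpha: float = 0.05) -> list:
    """Group replicate wells and QC them with a normality test.

    Wells are grouped by ``replicate_group`` (or ``group_key(result)``); per
    metric the mean ± SD (ddof = 1) and a D'Agostino–Pearson omnibus p-value
    are reported.  If a group fails normality (p < alpha), wells with
    |z| > ``z_threshold`` are flagged and the statistics excluding them are
    reported alongside — flagged wells stay in the primary statistics.
    """
    if group_key is None:
        group_key = lambda r: r.replicate_group
    groups: dict[str, list] = {}
    for r in results:
        if r.status != "ok":
            continue
        groups.setdefault(group_key(r), []).append(r)

    out: list[GroupStats] = []
    for group in sorted(groups):
        members = groups[group]
        for metric in metrics:
            values = np.array([getattr(m, metric) for m in members], dtype=float)
            ids = np.array([m.well_id for m in members])
            ok = np.isfinite(values)
            values, ids = values[ok], ids[ok]
            n = values.size
            if n < 3:
                out.append(GroupStats(group, metric, n,
                                      float(values.mean()) if n else math.nan,
                                      math.nan, None, "n < 3: no SD-based QC",
                                      (), None, None, None))
                continue
            mean = float(values.mean())
            sd = float(values.std(ddof=1))
            p = None
            note = ""
            outliers: tuple = ()
            mean_ex = sd_ex = p_ex = None
            if sd == 0:
                note = "degenerate variance: normality test skipped"
            elif n < 8:
                note = "n < 8: normality test skipped"
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = float(stats.normaltest(values).pvalue)
                if p < alpha:
                    z = (values - np.median(values)) / max(sd, 1e-300)
                    flagged = np.abs(z) > z_threshold
                    outliers = tuple(ids[flagged])
                    if flagged.any() and (~flagged).sum() >= 3:
                        kept = values[~flagged]
                        mean_ex = float(kept.mean())
                        sd_ex = float(kept.std(ddof=1))
                        if kept.size >= 8:
                            with warnings.catch_warnings():
                                warnings.simplefilter("ignore")
                                p_ex = float(stats.normaltest(kept).pvalue)
                    note = "group failed normality; flagged wells reported, not excluded"
            out.append(GroupStats(group, metric, n, mean, sd, p, note,
                                  outliers, mean_ex, sd_ex, p_ex))
    return out


# ---------------------------------------------------------------------------
# plate runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateReport:
    wells: tuple                  # WellResult, manifest order (row-major ids)
    groups: tuple                 # GroupStats
    calibration: Calibration
    timestamp: str                # isolated here so reports stay diff-able

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            row = {"well_id": w.well_id, "sample_label": w.sample_label,
                   "replicate_group": w.replicate_group, "conc_molar": w.conc_molar,
                   "status": w.status, "fcs_model": w.model,
                   "flags": ";".join(w.flags)}
            for metric in _METRICS:
                row[metric] = getattr(w, metric)
                row[f"{metric}_sd"] = w.sd.get(metric, math.nan)
            row["flicker_T"] = w.flicker_T
            row["flicker_tau_t_us"] = w.flicker_tau_t_us
            rows.append(row)
        return pd.DataFrame(rows)


def _well_sort_key(well_id: str):
    # row-major A1..H12; fall back to plain string ordering
    if len(well_id) >= 2 and well_id[0].isalpha() and well_id[1:].isdigit():
        return (0, well_id[0].upper(), int(well_id[1:]))
    return (1, well_id, 0)


def run_plate(manifest: PlateManifest, calibration: Calibration,
              config: AnalysisConfig = AnalysisConfig(), base_dir=None,
              log=None) -> PlateReport:
    """Analyze every well in a manifest; per-well failures never abort."""
    if calibration is None:
        raise ValidationError("missing calibration: run `fpfa calibrate` first")
    base = Path(base_dir) if base_dir is not None else None
    results = []
    for spec in sorted(manifest.wells, key=lambda w: _well_sort_key(w.well_id)):
        path = Path(spec.photon_file)
        if base is not None and not path.is_absolute():
            path = base / path
        try:
            res = analyze_well(path, calibration, config, spec=spec)
        except Exception as exc:  # fault isolation: record and continue
            res = WellResult(well_id=spec.well_id, sample_label=spec.sample_label,
                             replicate_group=spec.replicate_group,
                             conc_molar=spec.conc_molar, status="failed",
                             error=f"{type(exc).__name__}: {exc}")
        if log is not None:
            log(f"well {res.well_id}: {res.status}"
                + (f" ({res.error})" if res.error else ""))
        results.append(res)
    groups = replicate_stats(results)
    return PlateReport(wells=tuple(results), groups=tuple(groups),
                       calibration=calibration,
                       timestamp=datetime.now(timezone.utc).isoformat())


def export_report(report: PlateReport, path, fmt: str = "csv"):
    """Write a plate report as CSV (one row per well) or JSON (full detail)."""
    path = Path(path)
    if fmt == "csv":
        report.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "timestamp": report.timestamp,
            "calibration": asdict(report.calibration),
            "wells": [asdict(w) for w in report.wells],
            "groups": [asdict(g) for g in report.groups],
        }
        path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r}")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
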