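"""Photon-stream data model, on-disk formats, and basic intensity reductions.

A TCSPC acquisition is stored as three equal-length columns:

macro_time
    integer macro-clock ticks since acquisition start (tick duration in
    seconds in :class:`AcquisitionMeta`); the experiment-scale arrival time.
micro_time
    integer TAC bins since the last excitation pulse (bin width in ns in the
    metadata); the nanosecond-scale fluorescence delay.
channel
    0 = parallel, 1 = perpendicular polarization detector.

Two self-describing formats are supported: an HDF5 container with groups
``/photons/{macro_time,micro_time,channel}`` and ``/meta`` attributes, and a
CSV dialect (header ``macro_tick_index,micro_bin_index,channel`` with the
metadata in leading ``# key = value`` comment lines) intended for tiny,
diff-able fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "Channel",
    "AcquisitionMeta",
    "PhotonStream",
    "IntensityTrace",
    "read_photons",
    "write_photons",
    "count_rate",
    "bin_intensity",
]


class Channel(IntEnum):
    PARALLEL = 0
    PERPENDICULAR = 1


_META_FIELDS = ("sync_rate_hz", "macro_tick_s", "micro_bin_ns", "duration_s")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Acquisition metadata attached to every photon stream.

    Parameters
    ----------
    sync_rate_hz : float
        Laser repetition rate (80 MHz for the instrument emulated here).
    macro_tick_s : float
        Duration of one macro-clock tick in seconds.  The macro-clock
        resolution is hardware dependent, so it is carried explicitly rather
        than assumed; by convention the simulator uses one sync period.
    micro_bin_ns : float
        TAC bin width in nanoseconds.
    duration_s : float
        Length of the acquisition in seconds.
    dark_cps : float
        Detector dark count rate per channel (counts/s).  Hybrid detectors
        run at a few hundred cps at room temperature.
    label : str
        Free-text sample label.
    """

    sync_rate_hz: float
    macro_tick_s: float
    micro_bin_ns: float
    duration_s: float
    dark_cps: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in _META_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(f"AcquisitionMeta.{name} must be > 0, got {value!r}")
        if self.dark_cps < 0:
            raise ValidationError("dark_cps must be >= 0")

    @property
    def sync_period_ns(self) -> float:
        return 1e9 / self.sync_rate_hz

    @property
    def n_micro_bins(self) -> int:
        return int(round(self.sync_period_ns / self.micro_bin_ns))


@dataclass(frozen=True)
class PhotonStream:
    """Dual-channel TCSPC photon record arrays plus acquisition metadata."""

    macro_time: np.ndarray
    micro_time: np.ndarray
    channel: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        macro = np.ascontiguousarray(self.macro_time, dtype=np.int64)
        micro = np.ascontiguousarray(self.micro_time, dtype=np.int64)
        chan = np.ascontiguousarray(self.channel, dtype=np.int8)
        object.__setattr__(self, "macro_time", macro)
        object.__setattr__(self, "micro_time", micro)
        object.__setattr__(self, "channel", chan)
        if not (macro.shape == micro.shape == chan.shape) or macro.ndim != 1:
            raise ValidationError("macro_time, micro_time and channel must be equal-length 1-d arrays")
        if macro.size:
            if macro.min() < 0:
                raise ValidationError("negative macro_time tick")
            bad = np.flatnonzero((micro < 0) | (micro >= self.meta.n_micro_bins))
            if bad.size:
                raise ValidationError(
                    f"micro_time out of [0, sync period) at record index {int(bad[0])} "
                    f"(value {int(micro[bad[0]])}, n_micro_bins {self.meta.n_micro_bins})"
                )
            if not np.isin(chan, (0, 1)).all():
                raise ValidationError("channel must be 0 (parallel) or 1 (perpendicular)")
            for ch in (0, 1):
                t = macro[chan == ch]
                if t.size > 1 and np.any(np.diff(t) < 0):
                    raise ValidationError(f"macro_time not sorted within channel {ch}")

    def __len__(self) -> int:
        return int(self.macro_time.size)

    @property
    def n_photons(self) -> int:
        return len(self)

    def seconds(self) -> np.ndarray:
        """Macro arrival times in seconds."""
        return self.macro_time * self.meta.macro_tick_s

    def micro_ns(self) -> np.ndarray:
        """Micro (pulse-relative) times in nanoseconds, at bin centres."""
        return (self.micro_time + 0.5) * self.meta.micro_bin_ns

    def channel_mask(self, channel: Channel | int | str) -> np.ndarray:
        ch = _normalize_channel(channel)
        if ch == "both":
            return np.ones(len(self), dtype=bool)
        return self.channel == int(ch)

    def select(self, channel: Channel | int | str) -> "PhotonStream":
        m = self.channel_mask(channel)
        return replace(self, macro_time=self.macro_time[m], micro_time=self.micro_time[m], channel=self.channel[m])


@dataclass(frozen=True)
class IntensityTrace:
    """Binned intensity of both channels vs macro time."""

    bin_edges_s: np.ndarray
    counts_parallel: np.ndarray
    counts_perpendicular: np.ndarray
    last_bin_partial: bool = False

    @property
    def bin_centers_s(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_s[:-1] + self.bin_edges_s[1:])


def _normalize_channel(channel) -> Channel | str:
    if isinstance(channel, str):
        key = channel.lower()
        if key in ("both", "all"):
            return "both"
        if key in ("parallel", "par", "p"):
            return Channel.PARALLEL
        if key in ("perpendicular", "perp", "s"):
            return Channel.PERPENDICULAR
        raise ValidationError(f"unknown channel selector {channel!r}")
    return Channel(channel)


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix in (".csv", ".txt"):
        return "csv"
    raise FormatError(f"cannot infer photon format from suffix {suffix!r} of {path}")


def write_photons(stream: PhotonStream, path, format_id: str | None = None):
    """Write a photon stream losslessly; format inferred from suffix by default."""
    path = Path(path)
    fmt = format_id or _detect_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "w") as h5:
            grp = h5.create_group("photons")
            grp.create_dataset("macro_time", data=stream.macro_time)
            grp.create_dataset("micro_time", data=stream.micro_time)
            grp.create_dataset("channel", data=stream.channel)
            meta = h5.create_group("meta")
            for name in (*_META_FIELDS, "dark_cps", "label"):
                meta.attrs[name] = getattr(stream.meta, name)
    elif fmt == "csv":
        with open(path, "w") as fh:
            for name in (*_META_FIELDS, "dark_cps", "label"):
                fh.write(f"# {name} = {getattr(stream.meta, name)!r}\n")
            fh.write("macro_tick_index,micro_bin_index,channel\n")
            for row in zip(stream.macro_time, stream.micro_time, stream.channel):
                fh.write(f"{row[0]},{row[1]},{row[2]}\n")
    else:
        raise FormatError(f"unknown photon format {fmt!r}")
    return path


def read_photons(path, format_id: str | None = None) -> PhotonStream:
    """Read a photon stream written by :func:`write_photons`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_id or _detect_format(path)
    if fmt == "hdf5":
        with h5py.File(path, "r") as h5:
            try:
                grp = h5["photons"]
                macro = grp["macro_time"][:]
                micro = grp["micro_time"][:]
                chan = grp["channel"][:]
                attrs = dict(h5["meta"].attrs)
            except KeyError as exc:
                raise SchemaError(f"missing dataset/group in {path}: {exc}") from exc
        meta = _meta_from_mapping(attrs, path)
    elif fmt == "csv":
        attrs: dict = {}
        rows: list[tuple[int, int, int]] = []
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition("=")
                    attrs[key.strip()] = _parse_scalar(value.strip())
                    continue
                if not header_seen:
                    cols = [c.strip() for c in line.split(",")]
                    if cols != ["macro_tick_index", "micro_bin_index", "channel"]:
                        raise SchemaError(f"unexpected CSV header {cols} in {path}")
                    header_seen = True
                    continue
                a, b, c = line.split(",")
                rows.append((int(a), int(b), int(c)))
        if not header_seen:
            raise SchemaError(f"no header row found in {path}")
        meta = _meta_from_mapping(attrs, path)
        arr = np.asarray(rows, dtype=np.int64).reshape(-1, 3)
        macro, micro, chan = arr[:, 0], arr[:, 1], arr[:, 2]
    else:
        raise FormatError(f"unknown photon format {fmt!r}")
    return PhotonStream(macro_time=macro, micro_time=micro, channel=chan, meta=meta)


def _parse_scalar(text: str):
    if text.startswith(("'", '"')) and text.endswith(("'", '"')):
        return text[1:-1]
    try:
        return int(text)
    except ValueError:
        try:
            return float(text)
        except ValueError:
            return text


def _meta_from_mapping(attrs: dict, path: Path) -> AcquisitionMeta:
    missing = [k for k in _META_FIELDS if k not in attrs]
    if missing:
        raise SchemaError(f"missing metadata keys {missing} in {path}")
    label = attrs.get("label", "")
    if isinstance(label, bytes):
        label = label.decode()
    return AcquisitionMeta(
        sync_rate_hz=float(attrs["sync_rate_hz"]),
        macro_tick_s=float(attrs["macro_tick_s"]),
        micro_bin_ns=float(attrs["micro_bin_ns"]),
        duration_s=float(attrs["duration_s"]),
        dark_cps=float(attrs.get("dark_cps", 0.0)),
        label=str(label),
    )


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def count_rate(stream: PhotonStream, channel: Channel | int | str = "both") -> float:
    """Photon count rate in counts/s for the selected channel(s)."""
    if stream.meta.duration_s <= 0:
        raise ValidationError("duration must be > 0 for a count rate")
    return float(stream.channel_mask(channel).sum() / stream.meta.duration_s)


def bin_intensity(stream: PhotonStream, bin_width_s: float) -> IntensityTrace:
    """Histogram macro arrival times per channel with half-open bins [lo, hi).

    The trailing partial bin is kept and flagged so downstream consumers can
    drop it when uniform exposure matters.
    """
    if bin_width_s <= 0:
        raise ValidationError("bin_width_s must be > 0")
    duration = stream.meta.duration_s
    if bin_width_s > duration:
        warnings.warn("bin width exceeds acquisition duration; returning a single bin")
        bin_width_s = duration
    n_bins = int(np.ceil(duration / bin_width_s - 1e-9))
    n_bins = max(n_bins, 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_s
    last_partial = edges[-1] > duration * (1 + 1e-12) or not np.isclose(edges[-1], duration)
    edges[-1] = min(edges[-1], duration)
    t = stream.seconds()
    idx = np.minimum((t / bin_width_s).astype(np.int64), n_bins - 1)
    par = np.bincount(idx[stream.channel == 0], minlength=n_bins).astype(np.int64)
    perp = np.bincount(idx[stream.channel == 1], minlength=n_bins).astype(np.int64)
    return IntensityTrace(bin_edges_s=edges, counts_parallel=par, counts_perpendicular=perp,
                          last_bin_partial=bool(last_partial))
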