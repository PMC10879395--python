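"""Reading and writing LFP recordings, immobility masks and event tables.

All time values are in seconds, 0-based from the start of the recording, and
intervals are half-open ``[start, end)``.  Two on-disk recording formats are
supported:

``csv``
    Comma-separated, ``.`` decimal, mandatory header row.  Metadata appears as
    ``# key=value`` comment lines before the header.  Columns are ``time_s``
    and ``voltage_uv``; the time column must be uniformly increasing at the
    declared sampling rate.

``f32bin``
    Little-endian IEEE-754 float32 samples, with a mandatory JSON sidecar at
    ``<path>.json`` carrying at least ``sampling_rate``.

Proprietary acquisition formats are not read here; export upstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LfpRecording",
    "IntervalMask",
    "FormatError",
    "ValidationError",
    "ProvenanceError",
    "read_lfp",
    "write_lfp",
    "read_mask",
    "write_mask",
    "write_events",
    "read_events",
]


class ValidationError(ValueError):
    """Input data violate a documented invariant."""


class FormatError(ValueError):
    """File is structurally not in the declared format."""


class ProvenanceError(ValueError):
    """An artifact is missing the parameters that produced it."""


@dataclass(frozen=True)
class LfpRecording:
    """Uniformly sampled single-channel voltage trace.

    Parameters
    ----------
    samples : ndarray
        Voltage in microvolts; finite, length >= 2.
    sampling_rate : float
        Samples per second, > 0.
    start_time : float
        Time of the first sample in seconds (default 0).
    label : str
        Free-text channel/session label.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValidationError("recording needs a 1-D trace of length >= 2")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("recording contains non-finite samples")
        if not (self.sampling_rate > 0 and math.isfinite(self.sampling_rate)):
            raise ValidationError("sampling_rate must be a positive finite number")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording span in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class IntervalMask:
    """Sorted, non-overlapping set of half-open [start, end) intervals (s)."""

    intervals: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.intervals)
        for a, b in ivs:
            if not (math.isfinite(a) and math.isfinite(b)):
                raise ValidationError("interval bounds must be finite")
            if b <= a:
                raise ValidationError(f"interval end {b} <= start {a}")
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValidationError("intervals overlap or are unsorted")
        object.__setattr__(self, "intervals", ivs)

    @classmethod
    def from_intervals(cls, intervals: Iterable[Sequence[float]]) -> "IntervalMask":
        """Build a mask, sorting and merging touching intervals."""
        ivs = sorted((float(a), float(b)) for a, b in intervals)
        for a, b in ivs:
            if b <= a:
                raise ValidationError(f"interval end {b} <= start {a}")
        merged: list[tuple[float, float]] = []
        for a, b in ivs:
            if merged and a < merged[-1][1]:
                raise ValidationError("intervals overlap")
            if merged and a == merged[-1][1]:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        return cls(tuple(merged))

    @property
    def total_duration(self) -> float:
        return float(sum(b - a for a, b in self.intervals))

    def bind(self, recording: LfpRecording) -> "IntervalMask":
        """Validate that all intervals fall inside the recording span."""
        t0 = recording.start_time
        t1 = t0 + recording.duration
        for a, b in self.intervals:
            if a < t0 - 1e-9 or b > t1 + 1e-9:
                raise ValidationError(
                    f"interval [{a}, {b}) outside recording span [{t0}, {t1})"
                )
        if self.total_duration > recording.duration + 1e-9:
            raise ValidationError("mask duration exceeds recording duration")
        return self

    def contains(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.intervals)

    def covers(self, start: float, end: float) -> bool:
        """True if [start, end) lies fully inside a single interval."""
        return any(a <= start and end <= b for a, b in self.intervals)

    def sample_indices(self, recording: LfpRecording) -> np.ndarray:
        """Indices of recording samples whose times fall inside the mask."""
        fs = recording.sampling_rate
        idx: list[np.ndarray] = []
        for a, b in self.intervals:
            i0 = int(np.ceil((a - recording.start_time) * fs - 1e-9))
            i1 = int(np.ceil((b - recording.start_time) * fs - 1e-9))
            i0 = max(i0, 0)
            i1 = min(i1, recording.n_samples)
            if i1 > i0:
                idx.append(np.arange(i0, i1))
        if not idx:
            return np.empty(0, dtype=int)
        return np.concatenate(idx)


# ---------------------------------------------------------------------------
# recordings


def _read_metadata_lines(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_lfp(path: str | Path, format: str = "auto") -> LfpRecording:
    """Read a recording from ``csv`` or ``f32bin``.

    ``format='auto'`` decides from the file suffix (.csv vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "csv" if path.suffix.lower() == ".csv" else "f32bin"

    if format == "csv":
        import pandas as pd

        meta = _read_metadata_lines(path)
        if "sampling_rate" not in meta:
            raise FormatError("csv recording lacks '# sampling_rate=' metadata line")
        fs = float(meta["sampling_rate"])
        data = pd.read_csv(path, comment="#")
        if "time_s" not in data.columns or "voltage_uv" not in data.columns:
            raise FormatError("csv recording needs 'time_s' and 'voltage_uv' columns")
        t = data["time_s"].to_numpy(dtype=float)
        v = data["voltage_uv"].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValidationError("csv recording contains non-finite samples")
        dt = np.diff(t)
        if t.size >= 2 and (np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / fs) > 0.01 / fs)):
            raise ValidationError("csv time column is non-monotonic or irregular")
        return LfpRecording(
            samples=v,
            sampling_rate=fs,
            start_time=float(meta.get("start_time", t[0] if t.size else 0.0)),
            label=meta.get("label", ""),
        )

    if format == "f32bin":
        sidecar = path.with_name(path.name + ".json")
        if not sidecar.exists():
            raise FormatError(f"f32bin recording lacks JSON sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        if "sampling_rate" not in meta:
            raise FormatError("sidecar lacks 'sampling_rate'")
        samples = np.fromfile(path, dtype="<f4").astype(float)
        if not np.all(np.isfinite(samples)):
            raise ValidationError("f32bin recording contains non-finite samples")
        return LfpRecording(
            samples=samples,
            sampling_rate=float(meta["sampling_rate"]),
            start_time=float(meta.get("start_time", 0.0)),
            label=str(meta.get("label", "")),
        )

    raise ValueError(f"unknown format {format!r}")


def write_lfp(recording: LfpRecording, path: str | Path, format: str = "auto") -> Path:
    """Write a recording as ``csv`` or ``f32bin`` (+ JSON sidecar)."""
    path = Path(path)
    if format == "auto":
        format = "csv" if path.suffix.lower() == ".csv" else "f32bin"
    if format == "csv":
        with open(path, "w") as fh:
            fh.write(f"# sampling_rate={recording.sampling_rate!r}\n")
            fh.write(f"# start_time={recording.start_time!r}\n")
            if recording.label:
                fh.write(f"# label={recording.label}\n")
            fh.write("time_s,voltage_uv\n")
            for t, v in zip(recording.times, recording.samples):
                fh.write(f"{t:.6f},{v:.6f}\n")
    elif format == "f32bin":
        recording.samples.astype("<f4").tofile(path)
        sidecar = path.with_name(path.name + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "sampling_rate": recording.sampling_rate,
                    "start_time": recording.start_time,
                    "label": recording.label,
                    "n_samples": recording.n_samples,
                    "dtype": "<f4",
                },
                indent=2,
            )
        )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# masks


def read_mask(path: str | Path) -> IntervalMask:
    """Read a two-column ``start_s,end_s`` CSV into a validated mask.

    Touching intervals are merged; overlapping intervals are an error.
    """
    path = Path(path)
    data = np.genfromtxt(path, delimiter=",", names=True, comments="#")
    names = data.dtype.names or ()
    if "start_s" not in names or "end_s" not in names:
        raise FormatError("mask csv needs 'start_s' and 'end_s' columns")
    starts = np.atleast_1d(data["start_s"]).astype(float)
    ends = np.atleast_1d(data["end_s"]).astype(float)
    return IntervalMask.from_intervals(zip(starts, ends))


def write_mask(mask: IntervalMask, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("start_s,end_s\n")
        for a, b in mask.intervals:
            fh.write(f"{a:.6f},{b:.6f}\n")
    return path


# ---------------------------------------------------------------------------
# event tables

_EVENT_COLUMNS = ("onset_s", "offset_s", "peak_s", "duration_ms", "peak_z")
_REQUIRED_PROVENANCE = ("band_low_hz", "band_high_hz", "threshold_sd", "min_duration_ms")


def write_events(result, path: str | Path) -> Path:
    """Write a detection result as CSV plus a JSON provenance sidecar.

    The sidecar records the detection band, threshold, minimum duration,
    analyzed time and incidence so the table can be interpreted on its own.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(_EVENT_COLUMNS) + "\n")
        for ev in result.events:
            fh.write(
                f"{ev.onset_s:.6f},{ev.offset_s:.6f},{ev.peak_s:.6f},"
                f"{ev.duration_ms:.6f},{ev.peak_z:.6f}\n"
            )
    params = result.params
    sidecar = path.with_name(path.name + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "band_low_hz": params.band.low,
                "band_high_hz": params.band.high,
                "threshold_sd": params.threshold_sd,
                "min_duration_ms": params.min_duration_ms,
                "boundary_def": params.boundary_def,
                "analyzed_time_s": result.analyzed_time_s,
                "incidence_hz": result.incidence_hz,
                "n_events": len(result.events),
                "n_discarded": result.n_discarded,
            },
            indent=2,
        )
    )
    return path


def read_events(path: str | Path):
    """Read back an event table written by :func:`write_events`.

    Raises :class:`ProvenanceError` if the sidecar is missing or lacks any of
    the detection parameters.
    """
    from .swr import SwrDetectionParams, SwrDetectionResult, SwrEvent
    from .signal import Band

    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise ProvenanceError(f"event table {path} lacks sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _REQUIRED_PROVENANCE if k not in meta]
    if missing:
        raise ProvenanceError(f"event sidecar lacks detection parameters: {missing}")
    params = SwrDetectionParams(
        band=Band(float(meta["band_low_hz"]), float(meta["band_high_hz"])),
        threshold_sd=float(meta["threshold_sd"]),
        min_duration_ms=float(meta["min_duration_ms"]),
        boundary_def=str(meta.get("boundary_def", "envelope_mean")),
    )
    rows = np.genfromtxt(path, delimiter=",", names=True, comments="#")
    events = []
    if rows.size:
        for row in np.atleast_1d(rows):
            events.append(
                SwrEvent(
                    onset_s=float(row["onset_s"]),
                    offset_s=float(row["offset_s"]),
                    peak_s=float(row["peak_s"]),
                    duration_ms=float(row["duration_ms"]),
                    peak_z=float(row["peak_z"]),
                )
            )
    return SwrDetectionResult(
        events=tuple(events),
        params=params,
        analyzed_time_s=float(meta.get("analyzed_time_s", 0.0)),
        n_discarded=int(meta.get("n_discarded", 0)),
    )
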