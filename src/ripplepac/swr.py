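"""Sharp-wave-ripple detection and SWR metrics.

Detection rule
--------------
The LFP is bandpass filtered in the ripple band (default 150-250 Hz) and the
Hilbert envelope is taken.  The envelope mean and SD are computed over the
immobility samples only.  Candidate cores are maximal runs where the
envelope exceeds ``mean + threshold_sd * SD`` for at least
``min_duration_ms`` (defaults: 5 SD, 15 ms).  Each core is then extended
backward and forward to the nearest crossing of the baseline (the envelope
mean), so the reported event spans the whole supra-baseline excursion.
Events whose extended spans touch are merged; events overlapping
non-immobility time or the filter edge-transient regions are discarded (and
counted), never truncated.  The incidence rate is events per second of
immobility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import IntervalMask, LfpRecording, ValidationError
from .signal import (
    Band,
    ParameterError,
    RIPPLE_BAND,
    SLOW_GAMMA_BAND,
    Spectrogram,
    analytic,
    mt_spectrogram,
)

__all__ = [
    "SwrDetectionParams",
    "SwrEvent",
    "SwrDetectionResult",
    "ZScoredSpectrogram",
    "DegenerateInputError",
    "detect_swr",
    "duration_stats",
    "swr_triggered_spectrogram",
    "slow_gamma_power",
]


class DegenerateInputError(ValueError):
    """The trace carries no variance to threshold against."""


@dataclass(frozen=True)
class SwrDetectionParams:
    """Parameters of the envelope-threshold ripple detector."""

    band: Band = RIPPLE_BAND
    threshold_sd: float = 5.0
    min_duration_ms: float = 15.0
    boundary_def: str = "envelope_mean"
    reestimate_excluding_events: bool = False

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ParameterError("threshold_sd must be > 0")
        if self.min_duration_ms <= 0:
            raise ParameterError("min_duration_ms must be > 0")
        if self.boundary_def != "envelope_mean":
            raise ParameterError(f"unknown boundary_def {self.boundary_def!r}")


@dataclass(frozen=True)
class SwrEvent:
    onset_s: float
    offset_s: float
    peak_s: float
    duration_ms: float
    peak_z: float

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_s <= self.offset_s):
            raise ValidationError("event requires onset < peak <= offset")


@dataclass(frozen=True)
class SwrDetectionResult:
    events: tuple[SwrEvent, ...]
    params: SwrDetectionParams
    analyzed_time_s: float
    n_discarded: int = 0
    baseline_mean: float = float("nan")
    baseline_sd: float = float("nan")

    @property
    def incidence_hz(self) -> float:
        if self.analyzed_time_s <= 0:
            return float("nan")
        return len(self.events) / self.analyzed_time_s

    @property
    def durations_ms(self) -> np.ndarray:
        return np.array([ev.duration_ms for ev in self.events])


@dataclass(frozen=True)
class ZScoredSpectrogram:
    """Event-averaged spectrogram, z-scored per frequency row.

    ``times`` are seconds relative to event onset; ``norm_stats`` holds the
    per-frequency (mean, sd) of the averaged power used for normalization,
    so the raw average can be recovered as ``zpower * sd + mean``.
    """

    times: np.ndarray
    freqs: np.ndarray
    zpower: np.ndarray
    n_events: int
    norm_stats: tuple[np.ndarray, np.ndarray]
    n_excluded: int = 0
    taper_params: tuple[float, int, float, float] | None = None


# ---------------------------------------------------------------------------


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``above`` is True."""
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [above.size]))
    return list(zip(starts.tolist(), stops.tolist()))


def _detect_from_envelope(
    env: np.ndarray,
    fs: float,
    mu: float,
    sd: float,
    threshold_sd: float,
    min_samples: int,
) -> list[tuple[int, int]]:
    """Cores above mu + threshold_sd*sd lasting >= min_samples, each extended
    to the nearest crossing of the baseline mu, merged where spans touch."""
    thr = mu + threshold_sd * sd
    spans: list[tuple[int, int]] = []
    for i0, i1 in _runs_above(env > thr):
        if i1 - i0 < min_samples:
            continue
        lo = i0
        while lo > 0 and env[lo - 1] > mu:
            lo -= 1
        hi = i1
        while hi < env.size and env[hi] > mu:
            hi += 1
        if spans and lo <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], hi))
        else:
            spans.append((lo, hi))
    return spans


def detect_swr(
    recording: LfpRecording,
    params: SwrDetectionParams | None = None,
    mask: IntervalMask | None = None,
) -> SwrDetectionResult:
    """Detect sharp-wave ripples in an LFP recording.

    Parameters
    ----------
    recording : LfpRecording
        Raw LFP (at least 2 s).
    params : SwrDetectionParams
        Band, threshold and duration criterion.
    mask : IntervalMask
        Immobility intervals; envelope statistics and incidence are computed
        over these samples only.  Required and non-empty.
    """
    params = params or SwrDetectionParams()
    if recording.duration < 2.0:
        raise ParameterError("detection requires a recording of at least 2 s")
    if mask is None or not mask.intervals:
        raise ParameterError("detection requires a non-empty immobility mask")
    mask.bind(recording)

    fs = recording.sampling_rate
    asig = analytic(recording, params.band)
    env = asig.envelope
    n = env.size

    in_mask = np.zeros(n, dtype=bool)
    in_mask[mask.sample_indices(recording)] = True
    usable = in_mask & asig.valid
    stat_samples = env[usable]
    if stat_samples.size == 0:
        raise ParameterError("mask leaves no usable samples after edge trimming")
    mu = float(stat_samples.mean())
    sd = float(stat_samples.std())
    if sd == 0:
        if np.max(env) == 0:
            # silent trace: nothing to detect, by contract not an error
            return SwrDetectionResult(
                events=(),
                params=params,
                analyzed_time_s=mask.total_duration,
                baseline_mean=mu,
                baseline_sd=sd,
            )
        raise DegenerateInputError("envelope SD is zero (constant trace)")

    min_samples = int(np.ceil(params.min_duration_ms / 1000.0 * fs))
    spans = _detect_from_envelope(env, fs, mu, sd, params.threshold_sd, min_samples)

    if params.reestimate_excluding_events and spans:
        # one round of event-excluded re-estimation (sensitivity analysis)
        keep = usable.copy()
        for lo, hi in spans:
            keep[lo:hi] = False
        if keep.any() and env[keep].std() > 0:
            mu = float(env[keep].mean())
            sd = float(env[keep].std())
            spans = _detect_from_envelope(env, fs, mu, sd, params.threshold_sd, min_samples)

    events: list[SwrEvent] = []
    n_discarded = 0
    t0 = recording.start_time
    for lo, hi in spans:
        # drop events clipped by edges, the transient region or mask gaps
        if lo == 0 or hi == n or not usable[lo:hi].all():
            n_discarded += 1
            continue
        peak = lo + int(np.argmax(env[lo:hi]))
        events.append(
            SwrEvent(
                onset_s=t0 + lo / fs,
                offset_s=t0 + hi / fs,
                peak_s=t0 + peak / fs,
                duration_ms=(hi - lo) / fs * 1000.0,
                peak_z=(float(env[peak]) - mu) / sd,
            )
        )

    return SwrDetectionResult(
        events=tuple(events),
        params=params,
        analyzed_time_s=mask.total_duration,
        n_discarded=n_discarded,
        baseline_mean=mu,
        baseline_sd=sd,
    )


# ---------------------------------------------------------------------------
# duration statistics


@dataclass(frozen=True)
class DurationStats:
    median_ms: float
    ci95: tuple[float, float]
    bin_edges_ms: np.ndarray = field(default_factory=lambda: np.empty(0))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_events: int = 0

    @property
    def empty(self) -> bool:
        return self.n_events == 0


def duration_stats(
    result: SwrDetectionResult | np.ndarray,
    bin_width_ms: float = 10.0,
    n_boot: int = 10_000,
    seed: int = 0,
) -> DurationStats:
    """Median SWR duration with a seeded bootstrap 95% CI and a histogram.

    An empty event list returns an empty-result sentinel (NaN median), not an
    exception.
    """
    durations = (
        result.durations_ms if isinstance(result, SwrDetectionResult) else np.asarray(result, float)
    )
    if durations.size == 0:
        return DurationStats(median_ms=float("nan"), ci95=(float("nan"), float("nan")))
    med = float(np.median(durations))
    if durations.size == 1:
        ci = (med, med)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, durations.size, size=(n_boot, durations.size))
        boot = np.median(durations[idx], axis=1)
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    hi = max(durations.max(), bin_width_ms)
    edges = np.arange(0.0, hi + bin_width_ms, bin_width_ms)
    counts, edges = np.histogram(durations, bins=edges)
    return DurationStats(
        median_ms=med, ci95=ci, bin_edges_ms=edges, counts=counts, n_events=int(durations.size)
    )


# ---------------------------------------------------------------------------
# SWR-triggered spectrograms


def swr_triggered_spectrogram(
    recording: LfpRecording,
    result: SwrDetectionResult | np.ndarray,
    window_s: float = 0.4,
    spec_window_s: float = 0.1,
    spec_step_s: float = 0.01,
    nw: float = 3.0,
    k: int = 5,
    norm: str = "event_window",
) -> ZScoredSpectrogram | None:
    """Event-onset-aligned average multitaper spectrogram, z-scored per frequency.

    A multitaper spectrogram is computed for a window of ``window_s`` before
    and after each event onset, averaged across events, and each frequency
    row is z-scored.  With ``norm='event_window'`` (default) the mean/SD come
    from that row of the averaged +/-window matrix itself; ``norm='session'``
    uses the whole-recording spectrogram row instead.  Events without enough
    data on either side are excluded and counted.  Returns ``None`` when no
    event is usable.
    """
    if isinstance(result, SwrDetectionResult):
        onsets = np.array([ev.onset_s for ev in result.events])
    else:
        onsets = np.asarray(result, dtype=float)

    fs = recording.sampling_rate
    n_win = int(round(spec_window_s * fs))
    half = n_win // 2
    n400 = int(round(window_s * fs))
    t0 = recording.start_time

    acc = None
    n_used = 0
    n_excluded = 0
    times = freqs = None
    taper_params = None
    for onset in onsets:
        c = int(round((onset - t0) * fs))
        lo = c - n400 - half
        hi = c + n400 + half + 1
        if lo < 0 or hi > recording.n_samples:
            n_excluded += 1
            continue
        seg = recording.samples[lo:hi]
        spec = mt_spectrogram(
            seg, fs, window_s=spec_window_s, step_s=spec_step_s, nw=nw, k=k,
            t0=(lo - c) / fs,
        )
        if acc is None:
            acc = np.zeros_like(spec.power)
            times, freqs = spec.times, spec.freqs
            taper_params = spec.taper_params
        acc += spec.power
        n_used += 1

    if acc is None:
        return None
    avg = acc / n_used

    if norm == "event_window":
        mean = avg.mean(axis=1)
        sd = avg.std(axis=1)
    elif norm == "session":
        sess = mt_spectrogram(
            recording.samples, fs, window_s=spec_window_s, step_s=spec_step_s, nw=nw, k=k
        )
        mean = sess.power.mean(axis=1)
        sd = sess.power.std(axis=1)
    else:
        raise ParameterError(f"unknown norm {norm!r}")
    sd_safe = np.where(sd > 0, sd, 1.0)
    z = (avg - mean[:, None]) / sd_safe[:, None]
    return ZScoredSpectrogram(
        times=times,
        freqs=freqs,
        zpower=z,
        n_events=n_used,
        norm_stats=(mean, sd),
        n_excluded=n_excluded,
        taper_params=taper_params,
    )


def slow_gamma_power(
    zspec: ZScoredSpectrogram,
    band: Band = SLOW_GAMMA_BAND,
    window: tuple[float, float] = (0.001, 0.100),
) -> float:
    """Mean z-scored power in ``band`` over time-bin centers inside ``window``.

    Defaults quantify slow-gamma (30-50 Hz) power in the first 100 ms after
    ripple onset.
    """
    frow = (zspec.freqs >= band.low) & (zspec.freqs <= band.high)
    tcol = (zspec.times >= window[0]) & (zspec.times <= window[1])
    if not frow.any() or not tcol.any():
        raise ParameterError("band/window outside the spectrogram axes")
    return float(zspec.zpower[np.ix_(frow, tcol)].mean())
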