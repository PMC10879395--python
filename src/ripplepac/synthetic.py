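"""Synthetic LFP with fully known ground truth.

The generated trace is the sum of

* pink (1/f power) or white Gaussian background noise,
* a theta-band sinusoid,
* a slow-gamma carrier whose envelope is multiplicatively modulated by the
  theta phase, ``[1 + k*cos(theta_phase - preferred_phase)] * base_amp``,
  with programmable coupling strength ``k`` in [0, 1],
* transient ripple events: Hann-windowed pure-tone bursts (150-250 Hz, tens
  of ms) at a programmable Poisson rate, placed only inside immobility
  epochs with a 200 ms refractory gap so events never overlap,
* optionally a ripple-locked slow-gamma burst (Hann-windowed 40 Hz tone over
  the first 100 ms of each ripple), emulating the transient slow-gamma
  power increase seen at ripple onset.

Every injected component is returned in a :class:`SyntheticGroundTruth`, so
detector recall/precision, envelope recovery and coupling estimates can all
be scored against exact truth.  Identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .io import IntervalMask, LfpRecording
from .signal import ParameterError

__all__ = [
    "NoiseConfig",
    "ThetaConfig",
    "GammaConfig",
    "RippleConfig",
    "SgBurstConfig",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate",
    "make_group_fixtures",
    "GROUP_PROFILES",
]

RIPPLE_REFRACTORY_S = 0.2   # minimum gap between injected events
EDGE_MARGIN_S = 0.6         # keep events clear of interval edges / transients


@dataclass(frozen=True)
class NoiseConfig:
    kind: str = "pink"          # 'pink' (1/f power) or 'white'
    sd: float = 20.0            # µV


@dataclass(frozen=True)
class ThetaConfig:
    freq: float = 8.0           # Hz
    amp: float = 40.0           # µV


@dataclass(frozen=True)
class GammaConfig:
    freq: float = 40.0          # Hz
    base_amp: float = 10.0      # µV carrier envelope at zero coupling
    coupling_k: float = 0.5     # in [0, 1]
    preferred_phase: float = 0.0  # rad of theta phase at max gamma


@dataclass(frozen=True)
class RippleConfig:
    rate: float = 0.2           # events / s of immobility
    freq: float = 200.0         # Hz tone
    amp_sd: float = 8.0         # peak amplitude in multiples of noise SD
    duration_ms: float | tuple[float, float] = (np.log(50.0), 0.25)
    """Fixed duration in ms, or (mu, sigma) of a log-normal in ms."""


@dataclass(frozen=True)
class SgBurstConfig:
    amp: float = 0.0            # µV; 0 disables the ripple-locked burst
    freq: float = 40.0          # Hz
    duration_ms: float = 100.0  # from ripple onset


@dataclass(frozen=True)
class SyntheticConfig:
    duration_s: float = 120.0
    sampling_rate: float = 1000.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    theta: ThetaConfig = field(default_factory=ThetaConfig)
    gamma: GammaConfig = field(default_factory=GammaConfig)
    ripples: RippleConfig = field(default_factory=RippleConfig)
    sg_burst: SgBurstConfig = field(default_factory=SgBurstConfig)
    immobility_fraction: float = 1.0
    seed: int | None = None     # mandatory at generate() time

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma.coupling_k <= 1.0):
            raise ParameterError("coupling_k must lie in [0, 1]")
        if self.ripples.rate < 0:
            raise ParameterError("ripple rate must be >= 0")
        if min(self.noise.sd, self.theta.amp, self.gamma.base_amp, self.ripples.amp_sd) < 0:
            raise ParameterError("amplitude parameters must be >= 0")
        if not (0.0 < self.immobility_fraction <= 1.0):
            raise ParameterError("immobility_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Injected events and per-sample latent state of a generated trace."""

    ripple_events: tuple[tuple[float, float, float, float], ...]
    """(onset_s, offset_s, freq_hz, peak_amp_uv) per injected ripple."""
    theta_phase: np.ndarray
    coupling_k: float
    immobility_mask: IntervalMask
    noise_sd: float


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power noise via spectral amplitude shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])   # amplitude ~ f^-1/2 -> power ~ 1/f
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    return x / x.std()


def _immobility_intervals(duration_s: float, fraction: float) -> IntervalMask:
    """Alternating immobile/mobile epochs with the requested immobile fraction.

    Uses a 30 s cycle: the first ``fraction`` of each cycle is immobile.
    """
    if fraction >= 1.0:
        return IntervalMask(((0.0, duration_s),))
    cycle = 30.0
    intervals = []
    t = 0.0
    while t < duration_s:
        end = min(t + cycle * fraction, duration_s)
        if end > t:
            intervals.append((t, end))
        t += cycle
    return IntervalMask(tuple(intervals))


def _place_events(
    rng: np.random.Generator,
    mask: IntervalMask,
    rate: float,
    durations_s: np.ndarray,
) -> list[tuple[float, float]]:
    """Place len(durations_s) events inside mask intervals, non-overlapping.

    The count is drawn upstream as Poisson(rate x immobile time); placement
    is rejection sampling with a refractory gap, preserving the count so the
    programmed rate is realized without dead-time bias.
    """
    usable = [
        (a + EDGE_MARGIN_S, b - EDGE_MARGIN_S)
        for a, b in mask.intervals
        if b - a > 2 * EDGE_MARGIN_S + float(np.max(durations_s, initial=0.0))
    ]
    if not usable:
        return []
    weights = np.array([b - a for a, b in usable])
    weights = weights / weights.sum()
    placed: list[tuple[float, float]] = []
    for dur in durations_s:
        for _ in range(200):
            k = rng.choice(len(usable), p=weights)
            a, b = usable[k]
            if b - a <= dur:
                continue
            onset = a + rng.random() * (b - a - dur)
            off = onset + dur
            if all(
                off + RIPPLE_REFRACTORY_S <= o0 or onset >= o1 + RIPPLE_REFRACTORY_S
                for o0, o1 in placed
            ):
                placed.append((onset, off))
                break
    placed.sort()
    return placed


def generate(config: SyntheticConfig) -> tuple[LfpRecording, SyntheticGroundTruth]:
    """Generate a synthetic LFP recording and its ground truth.

    ``config.seed`` must be set; identical config + seed is bit-identical.
    """
    if config.seed is None:
        raise ParameterError("SyntheticConfig.seed must be set")
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    # background noise
    if config.noise.kind == "pink":
        noise = _pink_noise(n, rng) * config.noise.sd
    elif config.noise.kind == "white":
        noise = rng.standard_normal(n) * config.noise.sd
    else:
        raise ParameterError(f"unknown noise kind {config.noise.kind!r}")

    # theta with phase convention phase(cos) = 0
    theta_phase_unwrapped = 2 * np.pi * config.theta.freq * t
    theta = config.theta.amp * np.cos(theta_phase_unwrapped)
    theta_phase = np.angle(np.exp(1j * theta_phase_unwrapped))

    # phase-coupled gamma
    g = config.gamma
    envelope = g.base_amp * (1.0 + g.coupling_k * np.cos(theta_phase_unwrapped - g.preferred_phase))
    gamma = envelope * np.cos(2 * np.pi * g.freq * t)

    trace = noise + theta + gamma

    # ripple bursts inside immobility epochs (mask spans the realized trace)
    mask = _immobility_intervals(n / fs, config.immobility_fraction)
    r = config.ripples
    events: list[tuple[float, float, float, float]] = []
    if r.rate > 0:
        expected = r.rate * mask.total_duration
        if expected < 1:
            warnings.warn(
                f"expected ripple count {expected:.2f} < 1 for this duration",
                stacklevel=2,
            )
        count = int(rng.poisson(expected))
        if isinstance(r.duration_ms, tuple):
            mu, sigma = r.duration_ms
            durs_ms = rng.lognormal(mu, sigma, size=count)
        else:
            durs_ms = np.full(count, float(r.duration_ms))
        spans = _place_events(rng, mask, r.rate, durs_ms / 1000.0)
        amp = r.amp_sd * config.noise.sd
        sgb = config.sg_burst
        for onset, off in spans:
            i0 = int(round(onset * fs))
            i1 = int(round(off * fs))
            m = i1 - i0
            if m < 4:
                continue
            win = np.hanning(m)
            tt = np.arange(m) / fs
            trace[i0:i1] += amp * win * np.cos(2 * np.pi * r.freq * tt)
            if sgb.amp > 0:
                msg = int(round(sgb.duration_ms / 1000.0 * fs))
                j1 = min(i0 + msg, n)
                wg = np.hanning(j1 - i0)
                tg = np.arange(j1 - i0) / fs
                trace[i0:j1] += sgb.amp * wg * np.cos(2 * np.pi * sgb.freq * tg)
            events.append((i0 / fs, i1 / fs, r.freq, amp))

    rec = LfpRecording(samples=trace, sampling_rate=fs, label=f"synthetic(seed={config.seed})")
    truth = SyntheticGroundTruth(
        ripple_events=tuple(events),
        theta_phase=theta_phase,
        coupling_k=g.coupling_k,
        immobility_mask=mask,
        noise_sd=config.noise.sd,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# group fixtures

# Presets emulating the direction of the reported group differences:
# wild-type > stimulated disease model > untreated disease model on ripple
# rate, ripple duration, coupling strength and ripple-locked slow-gamma
# burst amplitude.  Values are the generator's study conditions, not fits.
GROUP_PROFILES: dict[str, dict[str, float]] = {
    "WT-like": dict(rate=0.35, dur_mu=np.log(60.0), coupling_k=0.80, sg_amp=12.0),
    "AD-TMAS-like": dict(rate=0.25, dur_mu=np.log(48.0), coupling_k=0.50, sg_amp=7.0),
    "AD-like": dict(rate=0.15, dur_mu=np.log(38.0), coupling_k=0.25, sg_amp=3.0),
}


def make_group_fixtures(
    profile: str,
    n_subjects: int,
    seed: int,
    duration_s: float = 300.0,
) -> list[tuple[LfpRecording, SyntheticGroundTruth]]:
    """Generate per-subject recordings for a named group profile.

    Subject configs are jittered +/-10% (multiplicative, uniform) around the
    profile presets, with the subject index folded into the seed, so cohorts
    are heterogeneous but reproducible.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    if profile not in GROUP_PROFILES:
        raise ParameterError(f"unknown profile {profile!r}; options: {sorted(GROUP_PROFILES)}")
    preset = GROUP_PROFILES[profile]
    out = []
    base = SyntheticConfig(duration_s=duration_s)
    ss = np.random.SeedSequence([seed, zlib.crc32(profile.encode()) % (2**31)])
    child_seeds = ss.generate_state(n_subjects) % (2**31)
    for i in range(n_subjects):
        jrng = np.random.default_rng(child_seeds[i])
        jit = lambda v: float(v) * jrng.uniform(0.9, 1.1)
        cfg = replace(
            base,
            ripples=RippleConfig(
                rate=jit(preset["rate"]),
                # jitter the median duration on the linear (ms) scale
                duration_ms=(float(np.log(jit(np.exp(preset["dur_mu"])))), 0.2),
            ),
            gamma=replace(base.gamma, coupling_k=min(jit(preset["coupling_k"]), 1.0)),
            sg_burst=SgBurstConfig(amp=jit(preset["sg_amp"])),
            seed=int(child_seeds[i]),
        )
        out.append(generate(cfg))
    return out
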