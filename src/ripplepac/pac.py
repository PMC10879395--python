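"""Theta-slow-gamma phase-amplitude coupling (PAC).

The coupling statistic is the entropy-normalized modulation index: the
instantaneous phase of the slow band and the envelope of the fast band are
taken from Hilbert transforms, the envelope samples are averaged within
``n_bins`` equal phase bins, the per-bin means are normalized to a
distribution ``p``, and

    MI = (log N - H(p)) / log N,      H(p) = -sum p_j log p_j,

i.e. the Kullback-Leibler divergence of ``p`` from uniform, normalized to
[0, 1].  MI is 0 iff the amplitude is distributed uniformly over phase and
1 iff all amplitude mass falls in a single bin.

Phase bins are half-open ``[left, right)`` starting at -pi; the phase
convention is ``phase(cos) = 0``.  Filter edge-transient samples are always
excluded; when an immobility mask is given, only samples inside it enter the
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IntervalMask, LfpRecording
from .signal import (
    Band,
    ParameterError,
    SLOW_GAMMA_BAND,
    THETA_BAND,
    analytic,
)
from .swr import DegenerateInputError

__all__ = [
    "PacParams",
    "PacResult",
    "pac_mi",
    "mi_from_distribution",
    "comodulogram",
    "phase_amp_distribution",
    "surrogate_z_mi",
]


@dataclass(frozen=True)
class PacParams:
    """Bands and binning for PAC estimation."""

    phase_band: Band = THETA_BAND
    amp_band: Band = SLOW_GAMMA_BAND
    n_bins: int = 18
    mask: IntervalMask | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 6:
            raise ParameterError("n_bins must be >= 6")
        if self.amp_band.low < self.phase_band.high:
            raise ParameterError("phase and amplitude bands must not overlap")


@dataclass(frozen=True)
class PacResult:
    bin_centers: np.ndarray     # radians, n_bins values in (-pi, pi)
    mean_amp: np.ndarray        # per-bin mean envelope, >= 0
    p: np.ndarray               # mean_amp / sum(mean_amp)
    mi: float                   # modulation index in [0, 1]
    n_samples: int
    n_bins: int


def mi_from_distribution(p: np.ndarray) -> float:
    """Entropy-normalized modulation index of a phase-bin distribution.

    Uses the convention 0*log(0) = 0, so empty bins contribute nothing to
    the entropy (and push MI toward 1).
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return float((np.log(n) - h) / np.log(n))


def _binned_amplitude(
    phase: np.ndarray, amp: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean amplitude over half-open phase bins starting at -pi."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    # np.digitize with right=False gives half-open [left, right) bins;
    # phase == +pi (angle() upper boundary) wraps into the last bin
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=amp, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    mean_amp = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean_amp


def pac_mi(
    recording: LfpRecording,
    params: PacParams | None = None,
) -> PacResult:
    """Modulation index of phase-amplitude coupling in a recording.

    Phase comes from the analytic signal of ``phase_band``, amplitude from
    the envelope of ``amp_band``; the recording must span at least 10 cycles
    of the slow band's low edge.
    """
    params = params or PacParams()
    min_dur = 10.0 / params.phase_band.low
    if recording.duration < min_dur:
        raise ParameterError(
            f"PAC requires >= {min_dur:.1f} s ({params.phase_band.low} Hz x 10 cycles)"
        )
    phase_sig = analytic(recording, params.phase_band)
    amp_sig = analytic(recording, params.amp_band)

    valid = phase_sig.valid & amp_sig.valid
    if params.mask is not None:
        in_mask = np.zeros(recording.n_samples, dtype=bool)
        in_mask[params.mask.bind(recording).sample_indices(recording)] = True
        valid &= in_mask
    phase = phase_sig.phase[valid]
    amp = amp_sig.envelope[valid]
    if amp.size == 0:
        raise ParameterError("no usable samples for PAC")
    if not np.any(amp > 0):
        raise DegenerateInputError("amplitude envelope is identically zero")

    centers, mean_amp = _binned_amplitude(phase, amp, params.n_bins)
    p = mean_amp / mean_amp.sum()
    return PacResult(
        bin_centers=centers,
        mean_amp=mean_amp,
        p=p,
        mi=mi_from_distribution(p),
        n_samples=int(amp.size),
        n_bins=params.n_bins,
    )


def phase_amp_distribution(
    recording: LfpRecording, params: PacParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Phase-binned amplitude distribution replicated over two cycles.

    Returns (bin centers in degrees over 0-720, mean amplitude per bin
    duplicated), the conventional visualization of theta-gamma coupling.
    """
    params = params or PacParams()
    res = pac_mi(recording, params)
    deg = np.degrees(res.bin_centers + np.pi)          # 0..360
    centers = np.concatenate([deg, deg + 360.0])
    amps = np.concatenate([res.mean_amp, res.mean_amp])
    return centers, amps


def comodulogram(
    recording: LfpRecording,
    phase_freqs: np.ndarray,
    amp_freqs: np.ndarray,
    phase_bandwidth: float = 4.0,
    amp_bandwidth: float = 20.0,
    n_bins: int = 18,
    mask: IntervalMask | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MI over a grid of (phase frequency, amplitude frequency) centers.

    Each cell evaluates :func:`pac_mi` with bands of the stated bandwidths
    centered on the grid point.  Returns (matrix [amp x phase], phase_freqs,
    amp_freqs).
    """
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    if phase_freqs.size == 0 or amp_freqs.size == 0:
        raise ParameterError("empty frequency grid")
    if np.any(np.diff(phase_freqs) <= 0) or np.any(np.diff(amp_freqs) <= 0):
        raise ParameterError("frequency grids must be strictly increasing")
    if phase_bandwidth < 2.0:
        raise ParameterError("phase bandwidth must be >= 2 Hz")
    nyq = recording.sampling_rate / 2
    if phase_freqs[-1] + phase_bandwidth / 2 >= nyq or amp_freqs[-1] + amp_bandwidth / 2 >= nyq:
        raise ParameterError("grid extends beyond Nyquist")

    # phase signals are reused across the amplitude axis
    phase_cache = {}
    for pf in phase_freqs:
        band = Band(max(pf - phase_bandwidth / 2, 0.1), pf + phase_bandwidth / 2)
        phase_cache[pf] = (band, analytic(recording, band))

    in_mask = None
    if mask is not None:
        in_mask = np.zeros(recording.n_samples, dtype=bool)
        in_mask[mask.bind(recording).sample_indices(recording)] = True

    mi = np.zeros((amp_freqs.size, phase_freqs.size))
    for i, af in enumerate(amp_freqs):
        aband = Band(af - amp_bandwidth / 2, af + amp_bandwidth / 2)
        amp_sig = analytic(recording, aband)
        for j, pf in enumerate(phase_freqs):
            _, phase_sig = phase_cache[pf]
            valid = phase_sig.valid & amp_sig.valid
            if in_mask is not None:
                valid &= in_mask
            _, mean_amp = _binned_amplitude(
                phase_sig.phase[valid], amp_sig.envelope[valid], n_bins
            )
            total = mean_amp.sum()
            mi[i, j] = mi_from_distribution(mean_amp / total) if total > 0 else 0.0
    return mi, phase_freqs, amp_freqs


def surrogate_z_mi(
    recording: LfpRecording,
    params: PacParams | None = None,
    n_surrogates: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Surrogate-normalized MI (z against time-shifted amplitude surrogates).

    The amplitude series is circularly shifted by >= 1 s random offsets,
    breaking phase-amplitude alignment while preserving both marginals.
    Returns (observed MI, z-score vs the surrogate distribution).
    """
    params = params or PacParams()
    obs = pac_mi(recording, params)
    phase_sig = analytic(recording, params.phase_band)
    amp_sig = analytic(recording, params.amp_band)
    valid = phase_sig.valid & amp_sig.valid
    phase = phase_sig.phase[valid]
    amp = amp_sig.envelope[valid]
    fs = recording.sampling_rate
    rng = np.random.default_rng(seed)
    min_shift = int(fs)
    mis = np.empty(n_surrogates)
    for s in range(n_surrogates):
        shift = int(rng.integers(min_shift, amp.size - min_shift))
        _, mean_amp = _binned_amplitude(phase, np.roll(amp, shift), params.n_bins)
        mis[s] = mi_from_distribution(mean_amp / mean_amp.sum())
    sd = mis.std()
    z = (obs.mi - mis.mean()) / sd if sd > 0 else float("inf")
    return obs.mi, float(z)
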