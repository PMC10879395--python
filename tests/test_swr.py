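import numpy as np
import pytest

from ripplepac import (
    IntervalMask,
    LfpRecording,
    SwrDetectionParams,
    detect_swr,
    duration_stats,
    slow_gamma_power,
    swr_triggered_spectrogram,
)
from ripplepac.signal import Band, ParameterError, analytic, RIPPLE_BAND
from ripplepac.swr import DegenerateInputError, ZScoredSpectrogram
from ripplepac.synthetic import (
    RippleConfig,
    SgBurstConfig,
    SyntheticConfig,
    generate,
)

from _reference import scan_events

FS = 1000.0
FULL_MASK = lambda dur: IntervalMask(((0.0, dur),))  # noqa: E731


class TestDetectSwr:
    def test_all_zero_recording_yields_no_events(self):
        rec = LfpRecording(np.zeros(10_000), FS)
        res = detect_swr(rec, SwrDetectionParams(), FULL_MASK(10.0))
        assert res.events == ()
        assert res.incidence_hz == 0.0

    def test_constant_nonzero_envelope_is_degenerate(self, monkeypatch):
        # a positive constant envelope (SD 0, nothing to threshold against)
        # must raise rather than silently return nothing
        import ripplepac.swr as swr_mod
        from ripplepac.signal import AnalyticSignal, RIPPLE_BAND

        def fake_analytic(rec, band, **kw):
            n = rec.n_samples
            return AnalyticSignal(
                phase=np.zeros(n), envelope=np.full(n, 3.0),
                source_band=RIPPLE_BAND, sampling_rate=FS, edge_samples=10,
            )

        monkeypatch.setattr(swr_mod, "analytic", fake_analytic)
        rec = LfpRecording(np.random.default_rng(0).standard_normal(10_000), FS)
        with pytest.raises(DegenerateInputError):
            detect_swr(rec, SwrDetectionParams(), FULL_MASK(10.0))

    def test_empty_mask_rejected(self, ripple_session):
        rec, _ = ripple_session
        with pytest.raises(ParameterError):
            detect_swr(rec, SwrDetectionParams(), IntervalMask(()))

    def test_short_recording_rejected(self):
        rec = LfpRecording(np.zeros(1000), FS)
        with pytest.raises(ParameterError):
            detect_swr(rec, SwrDetectionParams(), FULL_MASK(1.0))

    def test_recovers_injected_events(self, ripple_session):
        rec, truth = ripple_session
        res = detect_swr(rec, SwrDetectionParams(), truth.immobility_mask)
        assert len(res.events) == len(truth.ripple_events)
        # onsets extend to the baseline crossing, so errors are one-sided
        # (early) and heavy-tailed through the correlated noise envelope:
        # typically within 10 ms, never late, bounded by ~2 envelope
        # correlation times
        errors = [
            ev.onset_s - onset
            for ev, (onset, _, _, _) in zip(res.events, truth.ripple_events)
        ]
        assert all(-0.025 <= e <= 0.005 for e in errors)
        assert np.mean([abs(e) <= 0.010 for e in errors]) >= 0.75
        assert res.incidence_hz == pytest.approx(
            len(truth.ripple_events) / 60.0, rel=1e-9
        )

    def test_subthreshold_duration_burst_rejected(self, rng):
        # a 10 ms supra-threshold burst fails the >= 15 ms criterion
        from ripplepac.signal import analytic

        n = int(30 * FS)
        x = rng.standard_normal(n)
        t = np.arange(int(0.010 * FS)) / FS
        burst = 8.0 * np.hanning(t.size) * np.cos(2 * np.pi * 200 * t)
        x[15_000 : 15_000 + t.size] += burst
        rec = LfpRecording(x, FS)
        res = detect_swr(rec, SwrDetectionParams(), FULL_MASK(30.0))
        # the burst does cross the 5 SD threshold ...
        asig = analytic(rec, RIPPLE_BAND)
        thr = res.baseline_mean + 5 * res.baseline_sd
        assert asig.envelope[14_990:15_030].max() > thr
        # ... but is too brief to register as an event
        assert all(not (14.9 < ev.onset_s < 15.2) for ev in res.events)

    def test_event_invariants(self, ripple_session):
        rec, truth = ripple_session
        res = detect_swr(rec, SwrDetectionParams(), truth.immobility_mask)
        for ev in res.events:
            assert ev.onset_s < ev.peak_s <= ev.offset_s
            assert ev.duration_ms == pytest.approx((ev.offset_s - ev.onset_s) * 1000)
            assert ev.peak_z >= res.params.threshold_sd
        onsets = [ev.onset_s for ev in res.events]
        assert onsets == sorted(onsets)
        for a, b in zip(res.events, res.events[1:]):
            assert a.offset_s <= b.onset_s

    def test_monotone_in_threshold_and_duration(self, ripple_session):
        rec, truth = ripple_session
        counts_thr = []
        for thr in [3.0, 4.0, 5.0, 6.0, 8.0]:
            res = detect_swr(
                rec, SwrDetectionParams(threshold_sd=thr), truth.immobility_mask
            )
            counts_thr.append(len(res.events))
        assert counts_thr == sorted(counts_thr, reverse=True)
        counts_dur = []
        for md in [5.0, 15.0, 25.0, 35.0, 45.0]:
            res = detect_swr(
                rec, SwrDetectionParams(min_duration_ms=md), truth.immobility_mask
            )
            counts_dur.append(len(res.events))
        assert counts_dur == sorted(counts_dur, reverse=True)

    def test_matches_brute_force_scan(self):
        # event-for-event equality against a naive per-sample reference
        for seed in range(8):
            cfg = SyntheticConfig(
                duration_s=8.0,
                seed=900 + seed,
                ripples=RippleConfig(rate=0.6, duration_ms=(np.log(40.0), 0.3)),
            )
            rec, truth = generate(cfg)
            params = SwrDetectionParams()
            res = detect_swr(rec, params, truth.immobility_mask)

            asig = analytic(rec, params.band)
            usable = asig.valid.copy()
            idx = truth.immobility_mask.sample_indices(rec)
            in_mask = np.zeros(rec.n_samples, bool)
            in_mask[idx] = True
            usable &= in_mask
            ref = scan_events(asig.envelope, FS, usable, 5.0, 15.0)
            got = [
                (int(round(ev.onset_s * FS)), int(round(ev.offset_s * FS)))
                for ev in res.events
            ]
            assert got == ref

    def test_events_in_masked_out_time_dropped(self):
        cfg = SyntheticConfig(duration_s=90.0, seed=31, immobility_fraction=0.5,
                              ripples=RippleConfig(rate=0.4, duration_ms=40.0))
        rec, truth = generate(cfg)
        res = detect_swr(rec, SwrDetectionParams(), truth.immobility_mask)
        for ev in res.events:
            assert truth.immobility_mask.covers(ev.onset_s, ev.offset_s)
        assert res.analyzed_time_s == pytest.approx(truth.immobility_mask.total_duration)


class TestDurationStats:
    def test_median_of_known_values(self):
        st = duration_stats(np.array([20.0, 30.0, 40.0]))
        assert st.median_ms == 30.0

    def test_single_event_ci_collapses(self):
        st = duration_stats(np.array([42.0]))
        assert st.ci95 == (42.0, 42.0)

    def test_empty_is_sentinel_not_error(self):
        st = duration_stats(np.array([]))
        assert st.empty
        assert np.isnan(st.median_ms)

    def test_histogram_binning(self):
        st = duration_stats(np.array([5.0, 15.0, 25.0, 26.0]), bin_width_ms=10.0)
        assert st.counts.tolist() == [1, 1, 2]

    def test_bootstrap_ci_is_seeded(self):
        d = np.random.default_rng(3).lognormal(np.log(50), 0.3, 200)
        a = duration_stats(d, seed=0)
        b = duration_stats(d, seed=0)
        c = duration_stats(d, seed=1)
        assert a.ci95 == b.ci95
        assert a.ci95 != c.ci95

    def test_bootstrap_ci_coverage(self):
        # CI covers the true distribution median in >= 93% of replicates
        true_median = float(np.exp(np.log(50.0)))
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            d = rng.lognormal(np.log(50.0), 0.4, 500)
            st = duration_stats(d, n_boot=1000, seed=int(rng.integers(2**31)))
            hits += st.ci95[0] <= true_median <= st.ci95[1]
        assert hits >= 93


@pytest.fixture(scope="module")
def session_with_zspec():
    cfg = SyntheticConfig(
        duration_s=120.0,
        seed=55,
        ripples=RippleConfig(rate=0.3, duration_ms=50.0),
        sg_burst=SgBurstConfig(amp=10.0),
    )
    rec, truth = generate(cfg)
    res = detect_swr(rec, SwrDetectionParams(), truth.immobility_mask)
    zspec = swr_triggered_spectrogram(rec, res)
    return rec, res, zspec


class TestTriggeredSpectrogram:

    def test_zscore_identity_per_row(self, session_with_zspec):
        _, _, zspec = session_with_zspec
        assert np.all(np.abs(zspec.zpower.mean(axis=1)) < 1e-9)
        assert np.all(np.abs(zspec.zpower.std(axis=1) - 1.0) < 1e-9)

    def test_ripple_band_peak_at_event_time(self, session_with_zspec):
        _, _, zspec = session_with_zspec
        rows = (zspec.freqs >= 150) & (zspec.freqs <= 250)
        peak_bins = zspec.times[np.argmax(zspec.zpower[rows], axis=1)]
        assert np.all((peak_bins >= -0.01) & (peak_bins <= 0.06))

    def test_window_axis(self, session_with_zspec):
        _, _, zspec = session_with_zspec
        assert zspec.times[0] == pytest.approx(-0.4, abs=0.001)
        assert zspec.times[-1] == pytest.approx(0.4, abs=0.001)

    def test_null_pseudo_events_bounded(self, rng):
        rec = LfpRecording(rng.standard_normal(int(60 * FS)), FS)
        onsets = rng.uniform(1.0, 59.0, size=40)
        zspec = swr_triggered_spectrogram(rec, np.sort(onsets))
        frac = np.mean(np.abs(zspec.zpower) < 2.0)
        assert frac >= 0.95

    def test_events_near_edges_excluded(self, ripple_session):
        rec, _ = ripple_session
        zspec = swr_triggered_spectrogram(rec, np.array([0.1, 30.0, 59.95]))
        assert zspec.n_events == 1
        assert zspec.n_excluded == 2

    def test_no_usable_events_returns_none(self, ripple_session):
        rec, _ = ripple_session
        assert swr_triggered_spectrogram(rec, np.array([0.01])) is None


class TestSlowGammaPower:
    @staticmethod
    def _zspec(values: np.ndarray) -> ZScoredSpectrogram:
        times = np.arange(-0.4, 0.401, 0.01)
        freqs = np.arange(0.0, 510.0, 10.0)
        z = np.broadcast_to(values, (freqs.size, times.size)).copy()
        return ZScoredSpectrogram(
            times=times, freqs=freqs, zpower=z, n_events=10,
            norm_stats=(np.zeros(freqs.size), np.ones(freqs.size)),
        )

    def test_zero_matrix_gives_zero(self):
        assert slow_gamma_power(self._zspec(np.array(0.0))) == 0.0

    def test_constant_matrix_returns_constant(self):
        assert slow_gamma_power(self._zspec(np.array(2.0))) == pytest.approx(2.0)

    def test_band_window_outside_axes_rejected(self):
        zs = self._zspec(np.array(0.0))
        with pytest.raises(ParameterError):
            slow_gamma_power(zs, band=Band(600, 700))
        with pytest.raises(ParameterError):
            slow_gamma_power(zs, window=(0.5, 0.6))

    def test_gamma_burst_raises_sg_power(self):
        # paired comparison: same seeds with and without ripple-locked
        # slow-gamma bursts; SG z must be strictly greater with bursts
        for seed in [5, 6]:
            vals = {}
            for amp in (0.0, 10.0):
                cfg = SyntheticConfig(
                    duration_s=120.0,
                    seed=seed,
                    ripples=RippleConfig(rate=0.3, duration_ms=50.0),
                    sg_burst=SgBurstConfig(amp=amp),
                )
                rec, truth = generate(cfg)
                res = detect_swr(rec, SwrDetectionParams(), truth.immobility_mask)
                zspec = swr_triggered_spectrogram(rec, res)
                vals[amp] = slow_gamma_power(zspec)
            assert vals[10.0] > vals[0.0]
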