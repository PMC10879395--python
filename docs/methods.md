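# Methods

This note documents the models, numerical choices and limitations behind
`ripplepac`.  It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and conventions

All analysis assumes a single-channel LFP uniformly sampled at ~1 kHz,
in microvolts.  Time is in seconds, 0-based from the recording start;
intervals are half-open `[start, end)`, which removes boundary
double-counting when masks and events are intersected.  The instantaneous
phase convention is `phase(cos(2πft)) = 0` at `t = 0`; a sine therefore
carries phase −π/2 at its positive-going zero crossing.  Phase bins for
coupling start at −π and are half-open.

## Filtering

Bandpass filters are symmetric Kaiser-windowed FIRs (`scipy.signal.firwin`)
designed for a 30 dB stopband beginning one octave below the band's low
edge.  A symmetric kernel has exactly linear phase, so one FFT convolution
with `'same'` alignment is zero-phase; no forward–backward pass is needed.
The 30 dB target is deliberate: it comfortably exceeds the 20 dB/octave
requirement while keeping the ripple-band kernel short (23 taps at
150–250 Hz, 1 kHz), and kernel length is what limits the detector's
temporal resolution (see below).  The trace is demeaned before filtering so
the kernel's finite stopband cannot leak a DC offset into the band.  An
order-4 Butterworth applied with `sosfiltfilt` is available as an
alternative (`design='iir'`).

Each filtered trace carries an edge-transient region (half the kernel
length per end, ~3 cycles of the low edge for the IIR).  Event detection
and PAC exclude these samples.

## SWR detection

The ripple-band (150–250 Hz) Hilbert envelope is thresholded at
`mean + 5 SD`, with both moments computed over immobility samples only
(outside edge transients).  Cores must last ≥ 15 ms; each core is extended
to the nearest crossing of the baseline (the envelope mean — the natural
baseline of a Hilbert envelope, recorded in provenance), overlapping
extensions are merged with the peak taken at the maximum envelope of the
merged span, and events clipped by recording edges or mask boundaries are
discarded and counted rather than truncated, so duration statistics are
never silently censored.  An optional flag re-estimates the baseline once
with detected events excluded (sensitivity analysis); the default uses the
simple all-immobility moments.

Two physical consequences of band-limited envelopes are worth knowing:

* **Onset accuracy is one-sided and heavy-tailed.**  Extension to the
  baseline crossing walks through the noise envelope, whose correlation
  time is ~1/bandwidth = 10 ms; detected onsets are typically within
  ~5 ms *before* the true burst start but occasionally 10–20 ms early.
* **Very short bursts are rejected statistically, not absolutely.**  A
  100 Hz-wide band cannot represent an envelope narrower than ~10 ms, so a
  10 ms burst far above threshold produces a ~14–16 ms excursion and can
  pass the 15 ms criterion; near threshold the excursion is much shorter
  and rejection is near-certain (measured noise-extension tail ~0.1% per
  burst at 4× background SD).  The duration rule is exact about envelope
  excursions, not about the underlying burst.

Incidence is `n_events / total immobility time`.  Durations are summarized
by the median with a bootstrap 95% percentile CI (10 000 resamples,
mandatory seed, default 0) and a 10 ms-bin histogram.

## Ripple-triggered spectrograms and slow-gamma power

Multitaper spectrograms use DPSS tapers with window 100 ms, step 10 ms,
NW = 3, K = 5 — defaults chosen so K ≤ 2NW−1 and the 30–50 Hz band is
resolvable within one window; they are recorded in output provenance
because they are this package's choice, not a community constant.  Power is
the mean over tapered one-sided periodograms (unit-energy tapers, density
scaling).

For each detected event with ±400 ms of data around its onset (others are
excluded and counted), a spectrogram is computed on the aligned segment;
the per-event matrices are averaged and each frequency row is z-scored.
By default the normalizing mean/SD come from the row of the averaged
±400 ms matrix itself (`norm='event_window'`), which makes every row
exactly mean 0 / SD 1 under its own recorded `norm_stats` — a checkable
identity; a `norm='session'` flag normalizes by the whole-recording
spectrogram instead for users who want absolute z levels.  Slow-gamma
power during SWRs is the mean z over the 30–50 Hz rows and the time bins
whose centers fall in 1–100 ms after onset.

Because each row is normalized by its own SD, the statistic is
self-normalized: with no ripple-locked gamma it fluctuates around 0 with a
per-subject SD of roughly 0.5 (set by the effective number of independent
time–frequency cells in the window, not by event count), and it grows with
the ratio of burst power to residual averaged noise.  Stable per-subject
values therefore need sessions long enough for ~50+ events.

## Phase–amplitude coupling

Phase from the 4–12 Hz analytic signal, amplitude from the 30–50 Hz
envelope; amplitudes are averaged within 18 half-open phase bins and
normalized to p.  The modulation index is the entropy-normalized
KL-from-uniform statistic `MI = (log N − H(p))/log N` with the convention
`0·log 0 = 0` — the index conventionally paired with phase-binned
amplitude distributions.  MI is invariant to amplitude scaling and bounded
in [0, 1]; on fully coupled clean signals of this construction it reaches
only ~0.02 because a `1 + cos` envelope modulation is far from a delta
distribution — MI values are comparable across conditions, not absolute
coupling fractions.  Bin count matters (MI at N ∈ {12, 18, 36} varies
smoothly); N is recorded in results.  When an immobility mask is given,
only masked samples enter the estimate, else the whole edge-trimmed
recording.

The comodulogram evaluates MI per (phase, amplitude) grid point with
stated bandwidths (defaults 4 Hz and 20 Hz).  No surrogate significance is
attached by default; an optional time-shift surrogate z-MI (≥ 200 shifted
surrogates, seeded) is provided.  Note that time-shift surrogates only
destroy coupling for aperiodic rhythms: circularly shifting a strictly
periodic signal merely rotates the preferred phase and preserves MI, which
matters when validating against purely sinusoidal synthetics.

Per-epoch MI is supported by masking; epoch length is a caller decision.

## Synthetic generator

The generator emulates the signal structure the analyses assume:

* **Pink noise** via spectral shaping (amplitude ∝ f^(−1/2), so power
  ∝ 1/f; fitted log–log PSD slope −1 ± 0.3 in 1–100 Hz), default SD 20 µV.
* **Theta**: 8 Hz cosine, 40 µV.
* **Slow gamma**: 40 Hz carrier, 10 µV base envelope, multiplicatively
  modulated by theta phase with programmable k ∈ [0, 1] and preferred
  phase.  A constant-frequency carrier keeps the analytic MI oracle exact.
* **Ripples**: Hann-windowed pure tones (default 200 Hz) with log-normal
  durations (median 50 ms, σ_log 0.25) at a programmable Poisson rate.
  The event count is drawn as Poisson(rate × immobile time) first, then
  placed by rejection sampling with a 200 ms refractory gap and a 0.6 s
  interval-edge margin — count-preserving placement avoids the dead-time
  bias that a thinned sequential process would put on the realized rate.
  Burst amplitude is in multiples of the background-noise SD (default 8,
  clearly supra-threshold).  Hann tones give exact ground-truth
  onset/offset/amplitude, unlike filtered-noise bursts.
* **Ripple-locked slow-gamma bursts** (optional): 100 ms Hann 40 Hz tone
  from each ripple onset, emulating the transient gamma increase at SWRs.
* **Immobility**: a fraction of the session in 30 s cycles (immobile first
  part of each cycle); events are placed only inside immobility.

Identical config + seed is bit-identical.  What the generator does *not*
emulate: sharp-wave low-frequency deflections, movement artifacts,
non-stationary theta frequency, broadband ripple spectra, or inter-channel
structure — so passing tests demonstrate correctness of the analysis chain
on its assumed signal model, not robustness to every property of real LFP.

**Cohort fixtures** (`make_group_fixtures`) preset ripple rate
(0.35/0.25/0.15 Hz), ripple duration median (60/48/38 ms), coupling k
(0.80/0.50/0.25) and SG-burst amplitude (12/7/3 µV) for wild-type-like,
stimulated-model-like and untreated-model-like cohorts, strictly ordered on
all four axes; per-subject parameters are jittered ±10% with the subject
index folded into the seed.  Sessions default to 300 s — a realistic
home-cage recording epoch giving ~50–100 ripples per subject, the scale at
which the self-normalized SG z statistic is stable per subject.

## Statistics layer

Base tests come from `scipy.stats` (Levene with mean centering, one-way
ANOVA sums of squares computed explicitly, Kruskal–Wallis with tie
correction, Mann–Whitney pairwise).  The Scheffé pairwise p-value is
implemented from its definition: `F_ij = (m_i − m_j)² / (MSE·(1/n_i+1/n_j))`
referred to `(k−1)·F(k−1, N−k)`.  Bonferroni caps `m·p_raw` at 1 with
`m = k(k−1)/2`.  The routing rule is explicit and logged: Levene p < 0.05
or any within-group Shapiro–Wilk p < 0.05 routes to the rank tests,
otherwise ANOVA; callers can override.  Degenerate inputs (all values
identical) report F = 0, p = 1 rather than NaN.  The unit of analysis
(animal, session, epoch) is the caller's: the layer compares whatever rows
it is given.

## Pipeline and provenance

`pipeline.run` executes simulate/load → detect → triggered spectrogram →
SG power → PAC → group report from a single JSON config carrying either
real input paths or a synthetic block (exactly one).  Every output is
checksummed into a manifest written last; a stage failure stops downstream
stages, keeps completed outputs and flags the manifest incomplete.  Seeded
runs are bit-reproducible (verified by checksum equality in the tests).

## Known limitations

* Single-channel only; no sharp-wave (stratum-radiatum) component, no unit
  coupling, no streaming detection.
* The 15 ms duration rule interacts with filter bandwidth as described
  above; comparisons across pipelines should hold the filter design fixed.
* MI has small positive bias at finite sample size (empty-bin convention);
  at the 60–300 s scales used here the null level is < 0.01 against a
  ~0.02 fully coupled signal, but very short epochs need surrogate
  correction.
* The event-window z-normalization makes SG z a relative, self-normalized
  measure; comparing absolute z levels across sessions with very different
  event counts should use `norm='session'`.
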