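# Methods

This note documents the models, estimators and numerical choices behind
`emergelp`: what the synthetic generator emulates, how each analysis stage is
defined, and where genuinely open design decisions were resolved.

## The phenomenon and the pipeline

During emergence from propofol anesthesia, auditory stimuli can evoke large
(hundreds of µV), slow (~1 s) potentials resembling the K-complexes of N2
sleep. Each event coincides with a transient suppression of broadband gamma
(40–100 Hz) power — the electrophysiological index of a cortical DOWN state.
The pipeline detects these events automatically, characterizes their
waveform and spectral signature, tracks their timecourse around behavioral
transitions (infusion stop, loss of consciousness, first movement, first
response/ROC), and compares them with sleep K-complexes.

Because no public raw recordings exist for this phenomenon, the package
ships a first-class synthetic-data generator whose defaults plant the
published summary statistics; the test suite and the acceptance script then
demand that the full pipeline — preprocessing, detection, ERP and spectral
analysis — recovers those statistics end to end.

## Synthetic recordings

**Background.** Each behavioral state has a one-sided PSD built from a 1/f²
continuum (knee 0.4 Hz) normalized to a per-state broadband amplitude, plus
a flat high-frequency noise floor of 1 µV²/Hz, with multiplicative dB
components: a slow-oscillation bump (< 2 Hz), frontal alpha (~10 Hz, frontal
channels only), sleep spindles (10–14 Hz), and a flat 10–40 Hz shelf.
Signals are spectrally shaped Gaussian noise (FFT filtering), fully
deterministic per seed, plus a 60 Hz line-noise sinusoid. The noise floor is
deliberately non-negligible: ECoG has broadband high-frequency power, and a
realistic gamma floor is what makes the event-locked gamma statistic
estimable (see "leakage" below).

Key state defaults: anesthetized maintenance has a large slow-oscillation
bump (total sd ≈ 140 µV — large enough that its 0.2–4 Hz content reaches the
detector's amplitude threshold, as it does in clinical recordings, which is
why detection is windowed to the emergence segment); the emergence state has
modest slow power (the ongoing slow oscillation has subsided by the time LPs
appear), a frontal alpha peak, and a +5.6 dB 10–40 Hz shelf; N2 sleep has
spindles, no frontal alpha, no shelf, and the *same* broadband scale as
emergence so the planted emergence-minus-sleep band offset is exactly the
shelf value. The shelf's sigmoid edges sit just outside 10 and 40 Hz so the
offset is flat across the whole comparison band.

**Event template.** The LP is a piecewise double exponential (fast rise,
slow fall) with a Gaussian-smoothed peak (σ = 60 ms) and an opposite-sign
Gaussian rebound (25% of the peak, centered 1.0 s post-peak, σ = 750 ms).
The broad rebound approximately balances the main lobe's area, which is what
a recorded (AC-coupled) biphasic transient looks like. Rise and fall
parameters are *threshold-referred*: the times between the 200 µV threshold
and the peak for the 550 µV reference amplitude; internal time constants are
iteratively calibrated so the sampled template reproduces the requested
values exactly, and the template shape is amplitude-invariant (scaling the
amplitude scales the waveform, so detector scale-equivariance is exact).

Because the published waveform statistics describe events *as recorded*
(i.e., after the 0.16–200 Hz acquisition passband, which shaves several
percent off the peak of a second-scale transient and shortens its
threshold-referred rise/fall), the generator plants templates whose
post-chain morphology equals the nominal parameters. The compensation
factors are computed once per sampling rate by passing the template through
the same zero-phase chain the pipeline uses.

**Event placement.** Stimuli arrive every 3.5–4.5 s (uniform jitter; a fixed
6 s mode exists) with a 40/30/30 click/word/sound mix (80/10/10
click/word/name for the scalp profile). In the transitional window (the
400 s before first response) each stimulus evokes an LP with probability
0.2; the evoked latency is lognormal (median 1.01 s, σ = 0.3, truncated to
[0.25, 1.65] s). Outside that window the probability is 0.02 (0 in awake or
sedated states). Spontaneous events are placed in inter-stimulus gaps more
than 2 s after the previous onset and at least 1 s before the next one, only
in gaps whose stimulus evoked nothing (so a spontaneous event never rides a
neighboring event's rebound lobe), with a probability calibrated so 28% of
planted events are spontaneous. These margins exist so that the 2 s
evoked-classification rule recovers the planted split exactly — with 3.5–4.5 s
inter-stimulus intervals a *uniformly* placed event would fall in an evoked
window about half the time, which would say nothing about the pipeline.

Each event has a lognormal amplitude (median 550 µV, σ = 0.15 in log space,
truncated to [420, 1000] µV). The narrow σ is a deliberate choice: the
detector's 400 µV threshold then truncates the planted distribution only
mildly, so the peak-locked mean recovers the planted median; the lower
truncation guarantees planted events are detectable, the upper one keeps
the peak-to-trough range of event trials safely below the 1500 µV artifact
screen. Per-event rise/fall times are Gaussian (165 ± 15 ms, 285 ± 25 ms,
fall ≥ rise + 40 ms).

**Spatial structure.** Each subject has a fixed per-channel gain profile
(frontal channels highest, parietal lowest; the two lead channels pinned
near 1 so every session has an analyzable maximum-event channel), a fixed
per-channel polarity (negative with probability 0.8 — re-referenced
potentials can take either sign), and a fixed per-channel timing offset
(N(0, 0.18 s), clipped to ±0.3 s) modeling the spatial variation in evoked
peak latency. Sleep/emergence subject pairs share all three, which is what
makes the cross-state spatial correlation informative.

**Gamma suppression.** During each event (0.6 s before to 1.1 s after the
peak, with 50 ms cosine ramps) the 33–112 Hz component of the background is
multiplicatively attenuated by the planted dB value (−1.29 dB default). The
suppressed band is slightly wider than the measured 40–100 Hz band so the
attenuation filter's transition skirts do not dilute the planted value.

**What the generator does not emulate:** volume conduction and realistic
electrode geometry, non-stationary drug kinetics (states switch at timeline
boundaries), epileptiform or movement artifacts beyond amplitude screening,
non-Gaussian background statistics, and any biophysical circuit mechanism.
Passing tests therefore demonstrate that the *pipeline* is correct and
unbiased under known ground truth — not that the detector would perform
identically on clinical data.

## Analysis stages

**Preprocessing.** Linear detrend; zero-phase (forward-backward) 4th-order
Butterworth lowpass at 200 Hz; integer-factor polyphase decimation to
500 Hz; zero-phase 4th-order Butterworth highpass at 0.16 Hz. Zero-phase
filtering preserves ERP latencies. Stimulus-locked trials use a (−2.5,
+2.5) s window; a trial is rejected on a channel when its peak-to-trough
range exceeds 1500 µV.

**Detection.** Rules are applied in a fixed order on the 0.2–4 Hz filtered
trace: enumerate strict local extrema of either sign with |amplitude| ≥
400 µV; require the contiguous same-sign excursion beyond 40 µV containing
the peak to last ≥ 400 ms; discard peaks above 1200 µV; then walk events in
time order discarding any within 500 ms of the last kept event (the earlier
event wins — deterministic and order-independent). Majority polarity is then
enforced per channel, with a negative tie-break (the conventional surface
polarity of K-complexes), logged when invoked. Amplitudes are measured on
the filtered trace (peak-to-zero); both conventions ("peak amplitude" vs
peak-to-trough) are defensible, and peak-to-zero matches a threshold applied
to identified peaks. The test suite pins the whole rule set against an
independent brute-force scan, exactly, on random traces.

**ERPs.** Stimulus-locked averages use event trials (a detected event on
that channel within 2 s of the stimulus) on channels with ≥ 5 event trials,
sign-flipped so the deflection is negative; cohort summaries pool channels.
Peak-locked averages center raw-trace segments on detected peaks of the
per-subject maximum-event channel. Rise/fall times are measured on the
absolute mean waveform at 200 µV with linear sub-sample interpolation.

**Timecourse.** 60 s windows sliding by 15 s; within each window the ERP is
the mean of the window's trials and its post-stimulus peak is normalized by
the standard deviation of the pooled pre-stimulus (1.5 s) samples of those
trials. Pooling across trials (rather than using the mean trace's own
baseline) makes the null z-scale ~1/√n_trials, which is what gives the
event-free control band its headroom; windows with fewer than 8 stimuli
carry no value. Condition-epoch amplitudes are |mean ERP| averaged over
0.5–1.5 s post-stimulus (a 0.5–1.0 s variant is available via the
`post_window` argument).

**Spectral estimation.** Multitaper with the convention NW = (K+1)/2 for K
tapers (3 tapers → NW 2 for 200 ms spectrogram windows; 19 tapers → NW 10
for 30 s epochs); dB is always 10·log10. Every window is linearly detrended
before tapering: a ~500 µV slow deflection inside a 200 ms window otherwise
leaks broadband power that swamps the few-µV² gamma floor and flips the sign
of the measured suppression. Event-triggered spectrograms are normalized per
frequency to the mean power in [−2, −1] s pre-peak (baseline columns average
exactly 0 dB); the gamma statistic is the mean normalized 40–100 Hz power
over 0–300 ms post-peak, averaged per subject on the maximum-event channel,
with a signed-rank test and a subject-resampling bootstrap CI across the
cohort. Epoch spectra report leave-one-epoch-out jackknife t-intervals and
exclude epochs with sd > 500 µV.

**Hierarchical bootstrap.** Each of the 1000 draws resamples subjects with
replacement, then epochs within each resampled subject, computes the two
cohort mean spectra and their dB difference; frequencies whose [2.5, 97.5]
percentile band excludes zero are flagged, and only contiguous runs wider
than the spectral resolution 2·NW/T survive. Percentile intervals (no BCa);
fewer than 100 draws are refused as unstable.

**Sleep comparison.** Four 30 s epochs per state per electrode (emergence:
ending 40 s before ROC; sleep: from t = 60 s); the per-electrode statistic
is the mean over 10–40 Hz of the per-frequency dB difference; the cohort
median gets a pooled electrode-resampling bootstrap CI and each subject a
signed-rank test. Spatial similarity: events detected on a single trigger
channel (≥ 20 in both states), per-channel mean of the peak-triggered
waveform within ±100 ms, Pearson correlation across channels (the field
reports "R"; Pearson is the default reading). Amplitude distributions are
compared on channels with ≥ 4 events in both states, pooled across subjects
for the bootstrap CI, with the rank-sum test run on equal-sized per-subject
subsamples drawn once with a fixed seed.

**Scalp variant.** Trials are normalized to the mean and sd of their 2 s
pre-stimulus baseline; the statistic is the maximum |z| in the 1 s following
the stimulus (absolute value — the scalp polarity of these events is not
fixed a priori), detected above 7 s.d. with a relaxed 5 s.d. setting. The
steady-state auditory response is the multitaper power at the bin nearest
40 Hz over the 2 s click train minus the matched pre-stimulus power (so
state-dependent background shifts cancel), with 22 Hz as the control
frequency, averaged over 1-minute windows. The scalp generator profile
halves the background scale, makes LPs word/name-selective with faster
latencies (median 0.6 s) so they fall inside the 1 s detection window, and
gates the 40 Hz response off during anesthesia and emergence.

## Problem sizes and determinism

Default synthetic sessions are 600 s at 500 Hz with 16 grid channels
(frontal/temporal/parietal labels, 4-row grid neighbors); the default
emergence cohort has 13 sessions and the sleep-pair cohort 3 subjects —
sizes chosen so the full acceptance analysis runs in well under a minute
while leaving ~25–30 detected events per session on the maximum-event
channel. All randomness derives from integer seeds via
`numpy.random.SeedSequence` (per-session seeds are spawned from the cohort
seed); identical configurations are bit-identical, and every bootstrap or
subsampling routine takes an explicit seed.

## Known limitations

- The detector is deliberately conservative (the thresholds miss smaller
  K-complex-like events by design) and is not a general-purpose clinical
  K-complex detector.
- The gamma statistic retains a small (≈ 0.1–0.2 dB) bias toward zero from
  residual spectral leakage of the event waveform; it is well inside the
  recovery tolerance but would matter for much smaller planted effects.
- Laplacian/bipolar re-referencing is implemented and tested but not applied
  in the default synthetic pipeline: the generator emits already-referenced
  signals in which one event spans neighboring channels with similar gains,
  so a Laplacian would cancel the very events under study.
- EDF export is not provided; signals interchange as flat float32 arrays
  with JSON sidecars plus tab-separated tables.
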