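# Methods

This note documents the models, conventions and numerical choices behind
`cardiosync`, in the order data flows through the package.

## Synthetic audiences

The generator exists so that every downstream stage is testable with
known ground truth. It emulates a two-concert study layout: by default 2
concerts × 8 participants, three "pieces" of 180 s (with 7, 9 and 9
sections), each presented in AV and AO conditions.

**Stimuli.** A synthetic piece is a schedule of sine tones (default: one
tone struck every 250 ms, pitch drawn from an equal-tempered octave,
amplitude following a smoothed random walk). Spectral flux therefore has
known peaks exactly at schedule onsets and broadband power at the slow
(0.1–2 Hz) modulation rates that heart and respiration can track. Audio
is rendered at 8 kHz mono — ample for flux, cheap for tests; the
real-data path accepts any WAV rate.

**Participants.** Each participant is an inhomogeneous point process for
heartbeats and one for breaths, with instantaneous rate (BPM)

    rate(t) = base + gain · flux_z(t − lag) + orienting(t) + noise(t)

- `base`: 60 × a participant frequency drawn near 1.01 Hz (heart) or
  0.30 Hz (respiration), the audience averages the analysis assumes.
- `gain` (default 1.5 BPM per SD of normalized flux) couples the rate to
  the stimulus with a fixed lag (default 600 ms heart, 1600 ms
  respiration; each must stay below one mean cycle, matching the search
  bound of the lag estimator). Respiration reuses heart parameters scaled
  by 0.4.
- `orienting(t)`: at each annotated section boundary, a deceleration–
  acceleration waveform — a negative half-sine lobe over [−5, +5] s with
  trough `depth` (default 0.5 BPM) at the boundary, then a positive
  recovery lobe over [+5, +15] s at 0.4 × depth. The trough is placed on
  the boundary itself so that (a) epoch windows ±10 s away have higher
  rate than the boundary window and (b) the shared excursion, hence
  inter-subject correlation, peaks at the boundary — the event-related
  orienting pattern the epoched analysis is designed to detect. Enabled
  in AV only by default; the AV/AO mechanism is left as free parameters
  rather than asserted.
- `noise(t)`: Gaussian noise smoothed with a 2-s kernel, rescaled to
  `noise_sd` (default 1.0 BPM heart, 0.5 respiration); a fresh stream per
  participant × signal × piece × condition, all derived from the
  participant seed, so reruns are bit-identical but conditions are not
  spuriously correlated.

Peaks are emitted by time rescaling: a peak fires whenever the running
integral of rate/60 gains one unit, so a constant rate λ yields intervals
of exactly 60/λ, and rate modulation maps exactly onto inter-beat
intervals — the property the lag-recovery and round-trip tests rely on.
Rates must stay positive; a spec that drives them ≤ 0 is rejected.

**Continuous rendering.** For preprocessing tests, ECG-like traces place
a narrow Gaussian QRS spike plus a smaller, wider T-like bump at each
heartbeat over baseline noise; respiration traces are piecewise sinusoids
peaking at each inspiration. What the generator does **not** emulate:
realistic ECG morphology variation, heart-rate-variability spectra,
respiratory sinus arrhythmia, movement artifacts, or electrode dropouts.
Passing tests therefore demonstrate correctness of the analysis chain,
not robustness to every pathology of real recordings.

## Preprocessing

Gaps flagged in the raw signal are linearly interpolated when ≤ 60 ms;
longer gaps stay flagged and count against the piece. Respiration is
low-passed at 2 Hz and ECG band-passed 0.6–20 Hz (Butterworth, 4th
order), both applied forward–backward (zero phase — any phase distortion
would bias the phase-coherence family) and demeaned.

R-peaks come from a derivative-energy detector: the squared first
derivative smoothed over 150 ms, peaks above 0.2 × the maximum energy,
refined to the local signal maximum, with a 250 ms refractory period so
T waves are never double-counted. A quality gate (the energy peak must
exceed 50 × the median energy) returns an empty series on flat or
noise-only input. Inspiration peaks are local maxima above a threshold
set relative to the rolling 60-s signal range (drift-robust), separated
by ≥ 1.5 s. Manual screening is reproducible: an edit list of
add/remove operations applied with ±20 ms matching tolerance and
per-peak provenance. A participant-piece is rejected when more than 10%
of intervals are implausible (outside 0.33–3 s for heart, 1–20 s for
respiration), when unfillable gaps remain, or when fewer than two peaks
survive; thresholds are configurable and echoed into run metadata.

## Rates and cycle phase

Instantaneous rate: BPM = 60/interval, linearly interpolated at 1000 Hz
and decimated to 20 Hz through a zero-phase anti-alias FIR
(`resample_poly`). Each BPM value is anchored at the **midpoint** of its
interval: 60/interval estimates the mean rate over the interval, so the
midpoint is the unbiased placement. (End-anchoring — the causal
convention, available as `anchor="end"` — delays the reconstructed series
by about half a cycle and correspondingly inflates estimated
stimulus-response lags; measured on synthetic audiences this pushed lag
estimates against the one-cycle search bound.) Edge values are held
constant to the piece bounds. The anti-alias filter adds ≤ ~0.02 BPM of
passband ripple, which the tests account for.

Cycle phase: a sinusoid of frequency 1/IBI is fitted per cycle with its
maximum on the detected peak; the analytic-signal angle of that surrogate
is, in closed form, a linear ramp 0 → 2π across the cycle, wrapped to
(−π, π] — 0 at the peak, ±π at mid-cycle — and is evaluated exactly
rather than through a numerical Hilbert transform (which would only add
edge error). Samples before the first peak, after the last, and inside
implausible cycles are NaN: phase is never fabricated.

## Stimulus features

Spectral flux: Hann-windowed magnitude spectra of 25 ms frames at 50%
overlap (80 Hz frame rate); flux is the plain Euclidean distance between
successive spectra (a half-wave-rectified option exists but is off by
default), with the first frame 0. A 20 Hz resampled copy rides along for
the synchrony grid. The audience band is [Q1, Q3]
(linear-interpolation quantiles) of retained participants' mean rates;
a degenerate IQR is widened by ±0.05 Hz so low-variance synthetic
audiences stay analyzable. Sub-band phase: 4th-order zero-phase
Butterworth band-pass of the flux at its native frame rate, Hilbert
angle, unwrap-interpolated onto the 20 Hz grid.

## Synchrony

Windows are 10 s long with a 1-s hop (the printed "1-s overlap" is read
as hop: the epoched analysis needs per-second resolution to fill five
6-s windows). Windows with zero variance are masked. Fisher averaging
clips |r| at 1 − 1e−12 to keep atanh finite. Lag shifting is by integer
samples on the 20 Hz grid (50 ms quantum); the constants estimated from
the original concert recordings (579/1573 ms for HR/RR correlation,
500/1820 ms for phase) ship as documented data-dependent defaults for
the `fixed` lag mode, not as substitutes for estimation.

The group lag is the mean of per-participant optima: for each
participant, the lag in [0, mean cycle] maximizing the positive
correlation (or coherence) between stimulus and shifted response over the
first 10 s after onset; participants with no positive value at any lag
are excluded and logged. Note a precision caveat: through the full
point process the recovered lag carries a stimulus-realization
uncertainty of roughly ±2 grid steps (the beat train low-passes the flux,
and 10 s of data identify the peak of a smoothed cross-correlation);
recovery to one grid step holds for responses that track the rate
function directly.

SRPC's window statistic defaults to the per-time-point two-signal
clustering value |cos(Δθ/2)| averaged over the window; a windowed PLV
over the phase difference is available as `mode="plv"` (a constant phase
offset scores |cos(Δ/2)| in the first mode and 1 in the second — both are
exposed because either convention is defensible for time-resolved
output). ISC/ISPC pair only within a concert, never across. For
participant-level modelling, ISC is also provided one-vs-rest (Fisher
mean of the pairs containing that participant).

## Inference

**Permutation test.** Each permutation rotates every participant's peak
train independently by a uniform offset over the piece length (the
offset distribution is not prescribed anywhere authoritative; uniform
over the full length is the least informative choice, and shifting the
raw peak trains lets rate and phase derivatives inherit the shift
coherently). The statistic is the pooled one-sample t of the
time-averaged per-section observations (per-participant granularity is
available through the observation function). p = (1 + #{null ≥
observed}) / (1 + n_perm), guaranteed in (0, 1]; q-values are
Benjamini–Hochberg across measures.

**Aggregation and epochs.** Time-averaged synchrony is the mean of window
values whose centers fall in each section (7 + 9 + 9 sections → 25
observations per participant, condition and measure) or in 30-s bins as
a length-controlled check. Epochs are ±15 s around boundaries, split at
{−15, −9, −3, 3, 9, 15} s into five 6-s windows labeled
{−10, −5, 0, 5, 10}; the labels are conventional names while the
partition fixes the geometry (the [−15, −9] bin's center is −12 s).
Boundaries within 15 s of a piece edge are dropped and logged.

**Mixed models.** `fit_modality_models` emulates crossed random effects
in `MixedLM` through variance components on a single grouping level:
intercepts for concert, piece and participant (IDs are globally unique,
so participant-in-concert nesting is implicit) plus an uncorrelated
participant-by-modality slope (`C(participant_id):C(condition)`). On
convergence failure or a singular component, the structure is simplified
in a declared order — slope first, then concert, piece, participant
(and, for custom structures, smallest variance first) — down to OLS if
necessary, with the path reported. Marginal/conditional R² follow the
variance-decomposition convention (fixed variance over total; fixed +
random over total). Window contrasts are estimated-marginal-means style:
linear combinations of the fixed effects with normal-approximation
p-values from the fixed-effect covariance, Bonferroni-corrected across
the five windows (AO−AV) or the four non-boundary windows
(window-vs-boundary). The paired sanity check gates on Shapiro normality
of the AO−AV differences at α = 0.05, then runs a one-sample t-test or
Wilcoxon signed-rank.

## Problem sizes

The default synthetic study (2 × 8 participants, 3 × 180 s pieces, both
conditions) is the reference configuration. Calibration and power
experiments in the test suite run smaller worlds — 3–4 participants,
60–120 s pieces, 200 permutations, 50–200 replicates — chosen so the
Monte-Carlo error of the quantity under test (binomial intervals on
rejection rates, CI coverage over replicates) is the binding constraint
rather than simulation size. The acceptance script uses 100 permutations
per measure on the full default study, giving a p-value resolution of
~0.01.

## Known limitations

- The permutation t statistic pools observations across participants and
  sections; within-participant autocorrelation across sections makes the
  observed t large in absolute terms, but exchangeability with the
  circular-shift surrogates (which preserve the same pooling) keeps the
  p-value calibrated — verified empirically in the calibration suite.
- Mixed-model p-values use large-sample (normal) approximations, not
  Satterthwaite/Kenward–Roger degrees of freedom; with the small cluster
  counts typical here (2 concerts, 3 pieces) random-effect variances for
  those factors are weakly identified and frequently simplified away.
- The QRS detector targets clean, template-like ECG; it is validated by
  round-trip on rendered signals, not on clinical recordings.
- Phase measures inherit the masking policy: heavily masked cycles reduce
  the effective window count rather than being interpolated.
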