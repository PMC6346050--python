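# Methods

`striatune` implements the analysis chain of an auditory-striatum study: a
cloud-of-tones two-alternative forced-choice (2AFC) task analyzed with a
logistic psychometric model, and tetrode single-unit recordings analyzed for
cell type, tone responsiveness, frequency tuning, and the effect of
transiently silencing an input pathway. Because no public dataset exists for
this preparation, the package ships a first-class synthetic generator that
produces recordings and behavior with the statistical structure the analysis
assumes; every claim the test suite makes is a claim about recovery of known
generative structure, not about new biology.

## Task and psychometric model

The stimulus is a stream of 30-ms overlapping pure tones at 100 onsets/s,
drawn from an 18-point grid log-spaced over 5–40 kHz (six grid frequencies
per octave). One flanking octave — low (5–10 kHz) or high (20–40 kHz) — is
the trial's target; each tone lands in the target octave with probability
(1 + 2r/100)/3, where r ∈ [0, 100] is the stimulus strength, and otherwise
uniformly in one of the two remaining octaves. This parenthesization is the
only reading bounded in [1/3, 1] that equals chance (one of three octaves)
at r = 0. Tone onsets sit on the regular 10-ms grid: a fixed presentation
rate with 30-ms tones describes a deterministic overlapping stream, not a
Poisson process. The per-trial evidence strength is
(#high − #low)/(#high + #low); middle-octave tones count in neither term.

Choices are modeled as Bernoulli with log(p/(1−p)) = β₀ + r·β₁, where p is
the probability of choosing the port associated with high frequencies
(convention: the right port; counterbalancing across animals is a labeling
issue only). The fit is trial-level maximum likelihood (statsmodels Logit),
not least squares on binned accuracies, and deliberately has no lapse
parameter; the generator can produce non-reported trials, but lapses are
not part of the fitted model. Perfect separation is flagged as
non-convergence and estimates are capped at |β₀| ≤ 25 and |100·β₁| ≤ 25
rather than returned unbounded. Session metrics count completed and
non-reported trials and summarize accuracy and reaction time per nominal r
level (the median for reaction time — a skewed, log-normal-like quantity);
binning by realized evidence is exposed as an option. Saline/CNO session
pairs are compared with two-sided paired t tests; all-zero difference
vectors are reported as t = 0, p = 1 (the textbook formula is 0/0 there).

## Cell-type classification

Units are classified from the mean spike waveform's half-valley width: the
duration of the trough at half its depth. Strictly below 100 µs → FS
(fast-spiking interneuron), strictly above 150 µs → ChI (cholinergic
interneuron), the closed interval [100, 150] µs → putative MSN (medium
spiny neuron), so every positive width receives exactly one class. Depth is
measured from a pre-trough baseline (mean of samples up to the pre-trough
maximum; the reference level is otherwise under-determined), and half-depth
crossings are linearly interpolated between samples — at ~32 kHz sampling
the raw resolution (~31 µs) is too coarse for thresholds 50 µs apart. A
trough at the first or last sample is rejected as no valley.

## Tone-response detection and taxonomy

The PSTH uses a 3-ms window sliding in 1-ms steps from 100 ms before tone
onset to 200 ms after tone end; bins are indexed by window start, and the
rate in a bin is the pooled spike count across trials divided by
(n_trials × 3 ms). Baseline mean and SD come from the bins starting in
[−50, 0) ms (sample SD; SD floored at 0.1 Hz so a silent baseline cannot
yield a zero threshold). A unit is responsive when a contiguous run of bins
at or after onset (and within 200 ms of tone end) exceeds mean + 3 SD; if
no excitatory run exists, a run below mean − 2 SD is a suppression
response. The earliest qualifying run is the response window; its start is
the latency, and the response rate is the mean in-window rate minus the
baseline mean.

**Minimum run length.** A per-bin 3-SD rule tested over ~300 overlapping
bins false-positives at a practically relevant rate: Poisson tails are
fatter than Gaussian, and one chance spike cluster elevates up to three
consecutive overlapping windows. The default therefore requires a run of at
least 4 bins (≥ 6 ms of contiguous elevation), which leaves real responses
(tens of ms) untouched while suppressing spurious windows; it is
configurable, including back to single-bin runs.

Excitatory windows are labeled onset (ends before 50 ms after onset),
sustained (ends at or after 50 ms; a window ending exactly at 50 ms is
sustained), or offset (starts at or after tone end and strictly within
20 ms of it; start time takes precedence when rules collide for long
tones). Windows are always determined on control (light-off) trials and
then applied to light-on trials.

## Tuning curves, Gaussian fits, and the silencing decomposition

Tones for recording span 2–50 kHz (the generator uses a quarter-octave
grid, 19 points from 2 to ~45 kHz) at 50/60/70 dB SPL. Most units do not
respond at 50 dB, so analysis uses the lower responsive intensity among 60
and 70 dB; units responsive at neither are excluded. The tuning curve is
the mean baseline-subtracted rate per frequency inside the unit's
control-determined response window; each condition subtracts its own
pre-tone baseline so light effects on spontaneous rate do not contaminate
the evoked estimate. Best frequency is the raw-curve argmax (ties to the
lowest frequency). The half-peak tuning width is read from the curve after
five-point Savitzky–Golay smoothing (polynomial order 2 — the lowest order
that preserves a local peak), with linear interpolation on the log2 axis
and a truncation flag when a flank never falls below half peak.

Tuning is fitted with R(f) = A·exp(−0.5(f−f₀)²/σ²) + B on the
log2-frequency axis, so σ is in octaves, matching every octave-scaled
comparison. Initialization A = max−min, B = min, f₀ = argmax, with a
multi-start sweep σ₀ ∈ {0.25, 0.5, 1, 2} and bounds A ≥ 0,
σ ∈ (0.05, 5]. R² = 1 − SS_res/SS_tot is computed on the raw (unsmoothed)
curve, and a unit counts as tuned when R² > 0.4.

Silencing effects are quantified two ways:

- **Aligned population curves.** Each unit's curves are re-indexed by
  octave offset from that condition's own best frequency and both
  conditions are divided by the unit's control best-frequency rate; the
  control population curve is 1 at offset 0 by construction. Peak (offset
  0) and shoulder (mean of ±½ octave) rates are compared across conditions
  with paired t tests.
- **Offset/divisive-gain decomposition.** Under
  R_light = (R_ctrl − offset)/scale with shared f₀ and σ (justified by the
  empirical invariance of best frequency and width under thalamic
  silencing): scale = A_ctrl/A_light, offset = B_ctrl − scale·B_light. The
  pipeline reports the offset in control-peak-normalized units (dividing by
  A_ctrl + B_ctrl), the scale being dimensionless either way, and
  summarizes populations as mean ± SEM of the per-unit values. A joint
  least-squares (offset, scale) regression on the curve samples is provided
  as a fallback when the two conditions are not Gaussian with shared shape.

**A caveat on the shoulder metric.** Re-determining the best frequency per
condition makes the shoulder statistic slightly biased: under measurement
noise, or when suppression is deep and narrow enough to flatten or split
the peak, the light-condition argmax wanders and the re-aligned shoulders
sample systematically lower parts of the curve (a few percent). The robust
signature separating the two silencing models is therefore effect size, not
a null-hypothesis test on shoulders: a divisive gain of 1.8 pulls the
shoulder ratio to ≈ 0.55, while peak-preferential suppression leaves it
near 1.

## Synthetic generator

Spike trains are inhomogeneous Poisson by thinning, with a 1-ms absolute
refractory period (optional; the analysis does not depend on it). The rate
is λ(t, f) = baseline + kernel(t)·[A·exp(−0.5(log₂f−f₀)²/σ²) + B],
rectified at zero, with rectangular kernels: onset (latency ~15 ms,
duration ~25 ms), sustained (latency to tone end + ~30 ms), offset
(starting ~5 ms after tone end), and suppression (a negative kernel; such
units need baselines ≳ 20 Hz to be detectable, as in the data the taxonomy
comes from). Intensities scale the evoked term (0 at 50 dB, 1 at 60/70 dB
by default, emulating the empirical 50-dB unresponsiveness). On light-on
trials — randomly interleaved at 50%, with the light epoch covering 100 ms
before onset to 100 ms after tone end — the evoked term is transformed by
one of three models: divisive (subtract offset·peak, divide by scale;
default 1.8 and 0.01, the thalamic gain-control model), peak-subtractive
(multiply by 1 − depth·bump(f), default depth 0.15 with bump FWHM 0.5
octave — the deepest narrow notch that keeps the suppressed curve
single-peaked at f₀, which the modeled phenomenon requires), or abolition
(evoked term zeroed; the dual-pathway model).

Waveforms are Gaussian troughs whose FWHM equals the target half-valley
width, with a small rebound hump and optional additive noise; measured
widths round-trip within ~2 µs. Behavior sessions draw a signed strength
per trial, build an actual tone cloud lasting until the (log-normal)
reaction time, and choose by the logistic model; non-reported trials carry
no reaction time. Default population composition is ≈ 80/13/7%
MSN/FS/ChI, matching the field's reported proportions, with class-typical
width and baseline-rate ranges.

What the generator does **not** emulate: spike-sorting errors and unit
drift, correlated noise across units or trials, adaptation within and
across trials, non-Gaussian (multi-peaked) receptive fields, intensity
tuning beyond the 50/60/70 on-off pattern, and history effects in
behavior. Passing tests therefore demonstrate that the analysis recovers
the structure it assumes at realistic rates and sample sizes — not that
real recordings satisfy those assumptions.

## Problem sizes and numerical choices

- Recovery experiments quantify per-frequency measurement noise at the
  Poisson count level: a frequency measured over n trials with a response
  window T has rate variance (baseline + rate)/(nT). Module-level
  end-to-end tests use spike-level simulation at smaller n.
- Single-condition Gaussian-fit recovery is assessed at 20
  trials/frequency (200 units): the median per-unit mean parameter error
  is ≈ 6.5%. The amplitude alone sits at ≈ 10%, which is its
  Cramér–Rao-implied floor under that noise — weighted least squares does
  not improve it.
- Condition-comparison experiments (transform recovery, peak/shoulder
  signatures) use a dedicated silencing session of 80
  trials/frequency/condition (~100 minutes of recording at the 0.5-Hz tone
  rate, a realistic chronic-session length). At 20 trials the per-unit
  scale estimate A_ctrl/A_light has a coefficient of variation ≈ 0.3 for
  scales near 3, and the mean of per-unit ratios then carries an
  irreducible Jensen bias above 5%; at 80 trials all transforms in
  scale ∈ [1.2, 3] recover within ≈ 2.5%.
- The demo recordings built by `analysis/01_simulate.py` use 10 units and
  6 trials/frequency/condition per pathway so the full driver chain runs
  in a few minutes; at that length the qualitative peak/shoulder effects
  are resolvable but per-unit transforms are not (the drivers say so).
- Intervals are half-open [start, end); times are seconds, frequencies
  kHz; ties in best frequency break to the lowest frequency; degenerate
  inputs (no trials, no trough, zero-variance baselines, empty sessions)
  raise typed errors rather than propagating NaNs.
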