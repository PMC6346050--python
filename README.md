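# striatune

Analysis pipeline for auditory-striatum electrophysiology and psychophysics:
how the two major auditory inputs to the posterior ("auditory") striatum —
the medial geniculate body (MGB) and primary auditory cortex (ACx) — shape
striatal sound representations, studied through a cloud-of-tones
frequency-discrimination task and tetrode single-unit recordings with
transient pathway silencing.

The package is for systems neuroscientists who need the full chain as
tested, reusable code:

- **Task & behavior** — cloud-of-tones stimulus generation (tones at 100 Hz
  from an 18-point 5–40 kHz log grid; target-octave probability
  (1 + 2r/100)/3), per-trial evidence strength
  (#high − #low)/(#high + #low), and the logistic psychometric model
  log(p/(1−p)) = β₀ + r·β₁ fitted by trial-level maximum likelihood, with
  paired saline/CNO session comparisons.
- **Cell types** — spike-waveform half-valley width with FS (< 100 µs),
  MSN (100–150 µs), ChI (> 150 µs) classification.
- **Tone responses** — 3-ms sliding-window PSTHs, baseline-referenced
  3-SD response-window detection, onset/sustained/offset/suppression
  taxonomy, latency and baseline-subtracted response rate.
- **Tuning** — per-frequency response curves at the lower responsive
  intensity (60/70 dB rule), best frequency, Savitzky–Golay-smoothed
  half-peak tuning width, and Gaussian receptive-field fits
  R(f) = A·exp(−0.5(f−f₀)²/σ²) + B on the log2-frequency axis with an
  R² > 0.4 inclusion criterion.
- **Silencing decomposition** — best-frequency-aligned, control-normalized
  population curves; peak and ±½-octave shoulder comparisons; and the
  offset/divisive-gain transform R_light = (R_ctrl − offset)/scale that
  separates a thalamic gain-control effect from cortical peak-preferential
  suppression.
- **Synthetic data** — a seeded generator (inhomogeneous Poisson spikes,
  parametric waveforms, Bernoulli/logistic behavior) standing in for the
  unreleased recordings; every analysis is validated by recovering known
  generative structure.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `01_simulate.py` writes three tetrode sessions (MGB silencing =
divisive, ACx silencing = peak-subtractive, dual silencing = abolition)
plus paired saline/CNO behavior under `scratch/data/`; the later scripts
analyze them into small tables under `results/`.

```bash
python analysis/01_simulate.py
python analysis/02_classify_units.py
python analysis/03_detect_responses.py
python analysis/04_tuning_and_gain.py
python analysis/05_behavior.py
```

`04_tuning_and_gain.py` prints (abridged):

```
mgb: peak diff -0.53 (p=0.000526), shoulder diff -0.24 (p=0.0827)
acx: peak diff -0.43 (p=0.00563), shoulder diff -0.10 (p=0.361)
dual: peak diff -0.69 (p=2.56e-07), shoulder diff -0.28 (p=0.00954)
divisive session (25 units): scale 1.83 +/- 0.04, offset 0.012 +/- 0.008 (generated 1.8 / 0.010)
  f0 shift p=0.75, sigma shift p=0.68 (both expected non-significant)
peak-subtractive session (25 units): peak ratio 0.88 (p=3.3e-05), shoulder ratio 0.98 (p=0.53)
```

Reading this: silencing the simulated MGB pathway reduces normalized
responses at the best frequency *and* at the half-octave shoulders (a gain
change), and a dedicated session recovers the generating transform —
divide by 1.8, subtract a 0.01 offset — without moving the preferred
frequency or tuning width. Silencing the simulated ACx pathway reduces the
peak while the shoulder ratio stays near 1 (tuning information, not gain).
Silencing both nearly abolishes the evoked response.

`05_behavior.py` prints the behavioral arm:

```
ctrl   beta1        saline    0.050  cno    0.051  p=0.302
hm4di  beta1        saline    0.044  cno    0.022  p=0.017*
hm4di  n_nonreport  saline   22.000  cno   16.667  p=0.416
hm4di  median_rt_s  saline    0.352  cno    0.347  p=0.214
```

CNO flattens the psychometric slope only in hM4Di-expressing animals,
with no change in non-reported trials, completed trials, or reaction time
— the silencing degrades the frequency decision, not motivation or motor
output.

A `striatune` command-line tool wraps the same library
(`striatune simulate|classify|respond|tune|compare|behave|run`); the
analysis scripts are the narrative entry points.

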