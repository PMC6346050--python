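"""Seeded synthetic recordings and behavior with the statistical structure
the analysis assumes.

No public dataset accompanies the recordings this pipeline targets, so this
module generates them: inhomogeneous Poisson spike trains whose rate is a
baseline plus a temporal response kernel (onset, sustained, offset, or
suppression) scaled by a Gaussian frequency-tuning profile; mean spike
waveforms with controlled half-valley widths; and Bernoulli 2AFC choices
from a logistic psychometric model. Pathway-silencing experiments are
emulated by modulating the tone-evoked rate on light-on trials over the
light epoch (100 ms before tone onset to 100 ms after tone end): a divisive
gain with subtractive offset (the thalamic model), a peak-preferential
subtraction confined to frequencies near the preferred one (the cortical
model), or full abolition (both pathways silenced).

Everything is reproducible from (spec, seed). Spike generation uses Poisson
thinning with an optional absolute refractory period (default 1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import HIGH_PORT
from .stimulus import ToneCloudConfig, evidence_strength, generate_tone_cloud

KernelType = Literal["onset", "sustained", "offset", "suppression"]

LIGHT_PRE_S = 0.100   # light epoch starts this long before tone onset
LIGHT_POST_S = 0.100  # and ends this long after tone end

# quarter-octave grid spanning 2-50 kHz (19 points, 2 to ~45 kHz)
DEFAULT_FREQ_GRID_KHZ = tuple(2.0 * 2.0 ** (0.25 * np.arange(19)))

# observed striatal composition: ~80% MSN, 13% FS, 7% ChI
CLASS_PROPORTIONS = {"MSN": 0.80, "FS": 0.13, "ChI": 0.07}
CLASS_WIDTH_RANGES_US = {"FS": (60.0, 92.0), "MSN": (108.0, 142.0), "ChI": (158.0, 240.0)}


@dataclass(frozen=True)
class Modulation:
    """Light-on transformation of the tone-evoked rate component."""

    kind: Literal["none", "divisive", "peak_subtractive", "abolition"] = "none"
    scale: float = 1.0          # divisive gain (divisive)
    offset: float = 0.0         # subtractive offset, fraction of peak (divisive)
    depth: float = 0.15         # fractional loss at the peak (peak_subtractive)
    # FWHM of the suppressed bump. Together with the default depth this stays
    # in the regime where the suppressed curve keeps a single peak at f0;
    # deeper or narrower notches carve the peak into two flanking humps and
    # displace the light-condition best frequency.
    half_width_oct: float = 0.5


@dataclass(frozen=True)
class ResponseKernel:
    kind: KernelType = "onset"
    latency_s: float = 0.015
    duration_s: float = 0.025   # for sustained kernels, extends to tone end + this


@dataclass(frozen=True)
class UnitSpec:
    """Generative description of one synthetic single unit."""

    unit_id: int
    cell_class: Literal["MSN", "FS", "ChI"] = "MSN"
    waveform_width_us: float = 125.0
    baseline_rate_hz: float = 5.0
    tuning_A_hz: float = 20.0
    tuning_f0_log2khz: float = float(np.log2(11.3))
    tuning_sigma_oct: float = 0.5
    tuning_B_hz: float = 0.0
    kernel: ResponseKernel = field(default_factory=ResponseKernel)
    modulation: Modulation = field(default_factory=Modulation)
    intensity_gain: Mapping[float, float] = field(
        default_factory=lambda: {50.0: 0.0, 60.0: 1.0, 70.0: 1.0}
    )
    refractory_s: float = 0.001


@dataclass(frozen=True)
class RecordingSpec:
    """One synthetic tetrode session: units plus the tone protocol.

    Pure tones are played once every ``trial_interval_s`` (0.5 Hz) in random
    order over the frequency grid, at 50/60/70 dB SPL, with light-on trials
    randomly interleaved at ``light_fraction``.
    """

    units: Sequence[UnitSpec]
    freq_grid_khz: tuple[float, ...] = DEFAULT_FREQ_GRID_KHZ
    intensities_db: tuple[float, ...] = (50.0, 60.0, 70.0)
    trials_per_condition: int = 10
    light_fraction: float = 0.5
    tone_duration_s: float = 0.100
    trial_interval_s: float = 2.0
    seed: int = 0


def _tuning_profile(spec: UnitSpec, freq_khz: np.ndarray) -> np.ndarray:
    x = np.log2(np.asarray(freq_khz, dtype=float))
    return spec.tuning_A_hz * np.exp(
        -0.5 * (x - spec.tuning_f0_log2khz) ** 2 / spec.tuning_sigma_oct**2
    ) + spec.tuning_B_hz


def modulated_evoked(spec: UnitSpec, freq_khz, light_on: bool) -> np.ndarray:
    """Tone-evoked rate amplitude per frequency, after light modulation."""
    evoked = np.atleast_1d(_tuning_profile(spec, freq_khz)).astype(float)
    if light_on:
        m = spec.modulation
        if m.kind == "divisive":
            peak = spec.tuning_A_hz + spec.tuning_B_hz
            evoked = (evoked - m.offset * peak) / m.scale
        elif m.kind == "peak_subtractive":
            x = np.log2(np.atleast_1d(np.asarray(freq_khz, dtype=float)))
            sigma_n = m.half_width_oct / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            bump = np.exp(-0.5 * (x - spec.tuning_f0_log2khz) ** 2 / sigma_n**2)
            evoked = evoked * (1.0 - m.depth * bump)
        elif m.kind == "abolition":
            evoked = np.zeros_like(evoked)
    return np.clip(evoked, 0.0, None)


def _kernel_interval(kernel: ResponseKernel, tone_dur: float) -> tuple[float, float]:
    if kernel.kind == "onset":
        return kernel.latency_s, kernel.latency_s + kernel.duration_s
    if kernel.kind == "sustained":
        return kernel.latency_s, tone_dur + kernel.duration_s
    if kernel.kind == "offset":
        return tone_dur + kernel.latency_s, tone_dur + kernel.latency_s + kernel.duration_s
    if kernel.kind == "suppression":
        return kernel.latency_s, tone_dur + kernel.duration_s
    raise ValueError(f"unknown kernel kind {kernel.kind!r}")


def unit_rate(
    spec: UnitSpec,
    t_rel_s: np.ndarray,
    freq_khz: float,
    intensity_db: float,
    light_on: bool,
    tone_duration_s: float,
) -> np.ndarray:
    """Instantaneous firing rate lambda(t, f) for one trial, rectified at 0."""
    gain = float(spec.intensity_gain.get(float(intensity_db), 1.0))
    evoked = float(modulated_evoked(spec, freq_khz, light_on)[0]) * gain
    k0, k1 = _kernel_interval(spec.kernel, tone_duration_s)
    in_kernel = (t_rel_s >= k0) & (t_rel_s < k1)
    sign = -1.0 if spec.kernel.kind == "suppression" else 1.0
    rate = spec.baseline_rate_hz + sign * evoked * in_kernel
    return np.clip(rate, 0.0, None)


def _thinned_spikes(
    rng: np.random.Generator,
    rate_fn,
    t0: float,
    t1: float,
    rate_max: float,
    refractory_s: float,
) -> np.ndarray:
    """Inhomogeneous Poisson spikes on [t0, t1) by thinning."""
    if rate_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_max * (t1 - t0))
    if n_cand == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    accept = rng.random(n_cand) < rate_fn(cand) / rate_max
    spikes = cand[accept]
    if refractory_s > 0 and spikes.size > 1:
        kept = [spikes[0]]
        for s in spikes[1:]:
            if s - kept[-1] >= refractory_s:
                kept.append(s)
        spikes = np.asarray(kept)
    return spikes


def simulate_unit_trials(
    spec: UnitSpec,
    trials: pd.DataFrame,
    seed: int | np.random.Generator,
    tone_duration_s: float = 0.100,
    trial_span_s: tuple[float, float] = (-0.200, 0.400),
) -> np.ndarray:
    """Spike times for one unit across a trial table.

    ``trials`` needs columns onset_s, freq_khz, intensity_db, light_on (and
    optionally duration_s). Spikes are generated per trial on
    ``trial_span_s`` around each onset and reported on the session clock.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    all_spikes = []
    peak_evoked = max(
        spec.tuning_A_hz + max(spec.tuning_B_hz, 0.0), 0.0
    ) * max(spec.intensity_gain.values(), default=1.0)
    rate_max = spec.baseline_rate_hz + peak_evoked
    for row in trials.itertuples(index=False):
        dur = float(getattr(row, "duration_s", tone_duration_s))
        fn = lambda t: unit_rate(
            spec, t, row.freq_khz, row.intensity_db, bool(row.light_on), dur
        )
        rel = _thinned_spikes(
            rng, fn, trial_span_s[0], trial_span_s[1] + dur, rate_max, spec.refractory_s
        )
        all_spikes.append(rel + row.onset_s)
    return np.sort(np.concatenate(all_spikes)) if all_spikes else np.empty(0)


def simulate_waveform(
    width_us: float,
    sample_rate_hz: float = 32000.0,
    seed: int | np.random.Generator = 0,
    n_samples: int = 48,
    depth_uv: float = 100.0,
    noise_uv: float = 0.0,
) -> np.ndarray:
    """Mean spike waveform with a Gaussian trough of the given half-valley width.

    The trough's full width at half depth equals ``width_us`` (the Gaussian
    FWHM, 2 sigma sqrt(2 ln 2)); a small positive rebound follows the trough.
    Additive Gaussian noise is configurable and off by default.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(n_samples) / sample_rate_hz
    center = t[n_samples // 2]
    sigma = width_us * 1e-6 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = -depth_uv * np.exp(-0.5 * (t - center) ** 2 / sigma**2)
    y += 0.12 * depth_uv * np.exp(-0.5 * (t - center - 4.5 * sigma) ** 2 / (2.0 * sigma) ** 2)
    if noise_uv > 0:
        y = y + rng.normal(0.0, noise_uv, n_samples)
    return y


def simulate_behavior(
    beta0: float,
    beta1: float,
    r_levels: Sequence[float] = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0),
    n_trials: int = 1000,
    nonreport_p: float = 0.05,
    seed: int | np.random.Generator = 0,
    session_id: str = "s0",
    treatment: str = "saline",
    rt_median_s: float = 0.35,
    rt_sigma: float = 0.35,
    cloud_config: ToneCloudConfig | None = None,
) -> pd.DataFrame:
    """One synthetic 2AFC session from the logistic psychometric model.

    Each trial draws a signed stimulus strength uniformly from +/-
    ``r_levels``, builds a tone cloud lasting until the (log-normal) reaction
    time, and chooses the high port with probability
    logistic(beta0 + r * beta1). Non-reported trials (no side-port choice)
    occur with probability ``nonreport_p`` and carry no reaction time.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    config = cloud_config or ToneCloudConfig()
    signed = sorted({s * lv for lv in r_levels for s in (+1.0, -1.0)})
    rows = []
    for tid in range(n_trials):
        r = float(signed[rng.integers(len(signed))])
        if r > 0:
            target = "high"
        elif r < 0:
            target = "low"
        else:
            target = "high" if rng.random() < 0.5 else "low"
        rt = float(np.exp(np.log(rt_median_s) + rt_sigma * rng.standard_normal()))
        rt = max(rt, 0.1)
        stim = generate_tone_cloud(config, abs(r), target, duration_s=rt, seed=rng)
        try:
            ev = evidence_strength(stim)
        except ValueError:
            ev = 0.0
        reported = rng.random() >= nonreport_p
        if reported:
            p_high = 1.0 / (1.0 + np.exp(-(beta0 + r * beta1)))
            choice = HIGH_PORT if rng.random() < p_high else (
                "left" if HIGH_PORT == "right" else "right"
            )
            chose_high = choice == HIGH_PORT
            correct = chose_high == (target == "high")
        else:
            choice, correct, rt = "none", False, np.nan
        rows.append(
            {
                "trial_id": tid,
                "r": r,
                "evidence": ev,
                "choice": choice,
                "correct": bool(correct),
                "reaction_time_s": rt,
                "reported": bool(reported),
                "session_id": session_id,
                "treatment": treatment,
            }
        )
    return pd.DataFrame(rows)


def noisy_tuning_curve(
    freqs_khz,
    evoked_hz,
    trials_per_freq: int,
    seed: int | np.random.Generator,
    baseline_hz: float = 5.0,
    window_s: float = 0.050,
):
    """Measured tuning curve with Poisson spike-count noise.

    Emulates averaging ``trials_per_freq`` trials per frequency with a
    response window of ``window_s``: the per-frequency measured rate is the
    pooled Poisson count at rate (baseline + evoked) divided by the total
    window time, minus the baseline. Unbiased for the evoked rate with
    variance (baseline + evoked) / (trials x window).
    """
    from .tuning import TuningCurve

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    evoked = np.clip(np.asarray(evoked_hz, dtype=float), -baseline_hz, None)
    exposure = trials_per_freq * window_s
    counts = rng.poisson(np.clip((baseline_hz + evoked) * exposure, 0.0, None))
    rates = counts / exposure - baseline_hz
    return TuningCurve(np.asarray(freqs_khz, dtype=float), rates)


def make_trial_table(spec: RecordingSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Randomly ordered tone-presentation schedule for a recording session."""
    combos = [
        (f, i, light)
        for f in spec.freq_grid_khz
        for i in spec.intensities_db
        for light in (False, True)
        for _ in range(spec.trials_per_condition)
    ]
    # drop or keep light trials to honor light_fraction when it is not 0.5
    combos = np.array(combos, dtype=object)
    order = rng.permutation(len(combos))
    rows = []
    for k, idx in enumerate(order):
        f, inten, light = combos[idx]
        rows.append(
            {
                "trial_id": k,
                "onset_s": 1.0 + k * spec.trial_interval_s,
                "freq_khz": float(f),
                "intensity_db": float(inten),
                "duration_s": spec.tone_duration_s,
                "light_on": bool(light),
            }
        )
    return pd.DataFrame(rows)


def default_population(
    n_units: int,
    seed: int | np.random.Generator,
    modulation: Modulation | None = None,
    freq_grid_khz: Sequence[float] = DEFAULT_FREQ_GRID_KHZ,
) -> list[UnitSpec]:
    """A realistic mixed population (~80/13/7% MSN/FS/ChI, varied kernels)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    classes = list(CLASS_PROPORTIONS)
    probs = np.array([CLASS_PROPORTIONS[c] for c in classes])
    log2_grid = np.log2(np.asarray(freq_grid_khz))
    kernel_kinds = ("onset", "sustained", "offset", "suppression")
    kernel_probs = np.array([0.55, 0.25, 0.10, 0.10])
    units = []
    for uid in range(n_units):
        cls = classes[rng.choice(len(classes), p=probs)]
        w_lo, w_hi = CLASS_WIDTH_RANGES_US[cls]
        baseline = {"MSN": (2.0, 6.0), "FS": (8.0, 20.0), "ChI": (4.0, 8.0)}[cls]
        kind = kernel_kinds[rng.choice(4, p=kernel_probs)]
        kernel = ResponseKernel(
            kind=kind,
            latency_s=float(rng.uniform(0.010, 0.030)),
            duration_s=float(rng.uniform(0.020, 0.035)),
        )
        units.append(
            UnitSpec(
                unit_id=uid,
                cell_class=cls,  # type: ignore[arg-type]
                waveform_width_us=float(rng.uniform(w_lo, w_hi)),
                baseline_rate_hz=float(rng.uniform(*baseline)),
                tuning_A_hz=float(rng.uniform(15.0, 40.0)),
                tuning_f0_log2khz=float(
                    rng.uniform(log2_grid[3], log2_grid[-4])
                ),
                tuning_sigma_oct=float(rng.uniform(0.35, 0.9)),
                tuning_B_hz=float(rng.uniform(0.0, 1.5)),
                kernel=kernel,
                modulation=modulation or Modulation(),
            )
        )
    return units


@dataclass(frozen=True)
class RecordingBundle:
    """In-memory synthetic session in the pipeline's table formats."""

    trials: pd.DataFrame      # trial_id, onset_s, freq_khz, intensity_db, duration_s, light_on
    spikes: pd.DataFrame      # unit_id, spike_time_s
    waveforms: pd.DataFrame   # unit_id, sample_index, amplitude_uv
    units: pd.DataFrame       # unit_id, sample_rate_hz, true_* generative fields
    spec: RecordingSpec


def simulate_recording(spec: RecordingSpec) -> RecordingBundle:
    """Full synthetic session: trial schedule, spikes, and waveforms.

    Deterministic given (spec, spec.seed); unit spike streams use per-unit
    substreams so the per-unit analyses do not depend on unit order.
    """
    root = np.random.default_rng(spec.seed)
    trial_rng, wf_rng = root.spawn(2)
    trials = make_trial_table(spec, trial_rng)

    spike_rows, wf_rows, unit_rows = [], [], []
    sample_rate = 32000.0
    for unit in spec.units:
        srng = np.random.default_rng([spec.seed, unit.unit_id, 101])
        spikes = simulate_unit_trials(
            unit, trials, srng, tone_duration_s=spec.tone_duration_s
        )
        spike_rows.append(
            pd.DataFrame({"unit_id": unit.unit_id, "spike_time_s": spikes})
        )
        wf = simulate_waveform(
            unit.waveform_width_us,
            sample_rate,
            np.random.default_rng([spec.seed, unit.unit_id, 202]),
            noise_uv=1.0,
        )
        wf_rows.append(
            pd.DataFrame(
                {
                    "unit_id": unit.unit_id,
                    "sample_index": np.arange(wf.size),
                    "amplitude_uv": wf,
                }
            )
        )
        unit_rows.append(
            {
                "unit_id": unit.unit_id,
                "sample_rate_hz": sample_rate,
                "true_class": unit.cell_class,
                "true_width_us": unit.waveform_width_us,
                "true_kernel": unit.kernel.kind,
                "true_f0_log2khz": unit.tuning_f0_log2khz,
                "true_sigma_oct": unit.tuning_sigma_oct,
                "modulation": unit.modulation.kind,
            }
        )
    return RecordingBundle(
        trials=trials,
        spikes=pd.concat(spike_rows, ignore_index=True),
        waveforms=pd.concat(wf_rows, ignore_index=True),
        units=pd.DataFrame(unit_rows),
        spec=spec,
    )


def with_modulation(units: Sequence[UnitSpec], modulation: Modulation) -> list[UnitSpec]:
    """Copies of ``units`` with the given light-on modulation applied."""
    return [replace(u, modulation=modulation) for u in units]
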