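"""Frequency tuning curves, Gaussian receptive-field fits, and the
offset/divisive-gain decomposition of pathway-silencing effects.

A unit's tuning curve is its mean baseline-subtracted response rate at each
tone frequency, measured in the response window determined from control
(light-off) trials, at the lower of the unit's responsive intensities (60 dB
if responsive there, else 70 dB; units responsive only at 50 dB are
excluded). The curve is smoothed with a five-point Savitzky-Golay filter
(order 2) before the half-peak tuning width is read off; the best frequency
is the raw-curve argmax (ties break to the lowest frequency).

Tuning curves are fitted on the log2-frequency axis with the Gaussian

    R(f) = A * exp(-0.5 * (f - f0)^2 / sigma^2) + B

where B is the baseline response, A the amplitude of the strongest evoked
response, f0 the preferred frequency (log2 kHz) and sigma the tuning width
(octaves). Units are considered tuned when R^2 > 0.4.

Silencing effects are quantified two ways. Population curves are aligned to
each unit's own best frequency per condition (octave offsets) and normalized
to the control best-frequency rate. Per-unit fitted curves are decomposed
under the transform R_light(f) = (R_ctrl(f) - offset) / scale with shared f0
and sigma, giving a subtractive offset and a divisive gain: a pure gain
change leaves the preferred frequency and tuning width untouched, while a
peak-preferential loss shows up at the best frequency but not at the
half-octave shoulders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from scipy.stats import ttest_rel

R2_INCLUSION = 0.4          # tuned-unit criterion on the Gaussian fit
SG_WINDOW = 5               # Savitzky-Golay span (points)
SG_ORDER = 2                # Savitzky-Golay polynomial order
SIGMA_BOUNDS_OCT = (0.05, 5.0)
SIGMA_STARTS_OCT = (0.25, 0.5, 1.0, 2.0)


class NotResponsiveError(ValueError):
    """Unit responsive at neither 60 nor 70 dB: excluded from tuning analysis."""


class InsufficientCoverageError(ValueError):
    """Too few frequencies to build or fit a tuning curve."""


class UndefinedGainError(ValueError):
    """Gain decomposition undefined (non-positive light-on amplitude)."""


@dataclass(frozen=True)
class TuningCurve:
    """Per-frequency mean baseline-subtracted response rates for one unit."""

    freqs_khz: np.ndarray
    rates_hz: np.ndarray
    intensity_db: float | None = None
    smoothed_rates_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_khz, dtype=float)
        r = np.asarray(self.rates_hz, dtype=float)
        if f.shape != r.shape or f.ndim != 1:
            raise ValueError("freqs and rates must be 1-D and aligned")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs_khz", f)
        object.__setattr__(self, "rates_hz", r)

    @property
    def log2_freqs(self) -> np.ndarray:
        return np.log2(self.freqs_khz)


@dataclass(frozen=True)
class GaussianFit:
    """Parameters of the Gaussian tuning fit on the log2-frequency axis."""

    A: float                # peak evoked amplitude (rate units)
    f0: float               # preferred frequency, log2 kHz
    sigma: float            # tuning width parameter, octaves
    B: float                # baseline response
    r_squared: float
    included: bool          # True iff r_squared > 0.4
    converged: bool = True

    @property
    def f0_khz(self) -> float:
        return float(2.0 ** self.f0)

    def predict(self, freqs_khz) -> np.ndarray:
        x = np.log2(np.asarray(freqs_khz, dtype=float))
        return _gauss(x, self.A, self.f0, self.sigma, self.B)


@dataclass(frozen=True)
class ConditionTransform:
    """R_light(f) = (R_ctrl(f) - offset) / scale."""

    offset: float
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass(frozen=True)
class TuningWidth:
    width_oct: float
    truncated: bool         # a flank never fell below half peak (grid edge)


@dataclass(frozen=True)
class AlignedPopulation:
    """Best-frequency-aligned, control-normalized population tuning curves."""

    octave_offsets: np.ndarray
    mean_norm_rates: Mapping[str, np.ndarray]   # condition -> mean per offset
    sem_norm_rates: Mapping[str, np.ndarray]
    n_units: int
    unit_curves: Mapping[str, np.ndarray] = field(repr=False, default=None)


def _gauss(x, A, f0, sigma, B):
    return A * np.exp(-0.5 * (x - f0) ** 2 / sigma**2) + B


def select_analysis_intensity(responsive_by_db: Mapping[float, bool]) -> float:
    """The lower responsive intensity among 60 and 70 dB SPL.

    Returns 60 if the unit responds at 60 dB, else 70 if it responds at
    70 dB. Units responsive at neither (responses at 50 dB alone do not
    qualify) raise :class:`NotResponsiveError`.
    """
    if responsive_by_db.get(60, False):
        return 60.0
    if responsive_by_db.get(70, False):
        return 70.0
    raise NotResponsiveError("unit not responsive at 60 or 70 dB")


def build_tuning_curve(
    spike_times_s: Sequence[float],
    trials,
    window,
    baseline_hz: float,
    intensity_db: float | None = None,
    min_freqs: int = 5,
) -> TuningCurve:
    """Mean baseline-subtracted in-window rate per tone frequency.

    ``trials`` is a DataFrame with columns onset_s and freq_khz (already
    restricted to the analysis intensity and condition of interest);
    ``window`` is the unit's control-condition :class:`ResponseWindow`. For
    each frequency the spike rate inside [onset + start, onset + end] is
    averaged across that frequency's trials, and the baseline mean is
    subtracted.
    """
    spikes = np.sort(np.asarray(spike_times_s, dtype=float))
    freqs = np.sort(trials["freq_khz"].unique())
    if freqs.size < min_freqs:
        raise InsufficientCoverageError(
            f"need >= {min_freqs} frequencies, got {freqs.size}"
        )
    length = window.end_s - window.start_s
    if length <= 0:
        raise ValueError("response window must have positive length")
    rates = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        onsets = trials.loc[trials["freq_khz"] == f, "onset_s"].to_numpy()
        lo = np.searchsorted(spikes, onsets + window.start_s)
        hi = np.searchsorted(spikes, onsets + window.end_s)
        rates[i] = (hi - lo).sum() / (onsets.size * length) - baseline_hz
    return TuningCurve(freqs, rates, intensity_db=intensity_db)


def best_frequency(curve: TuningCurve) -> float:
    """Frequency (kHz) evoking the highest response; ties break low."""
    return float(curve.freqs_khz[int(np.argmax(curve.rates_hz))])


def smooth_curve(curve: TuningCurve) -> TuningCurve:
    """Savitzky-Golay smoothing, window 5, polynomial order 2."""
    if curve.rates_hz.size < SG_WINDOW:
        raise InsufficientCoverageError("need >= 5 points for smoothing")
    smoothed = savgol_filter(curve.rates_hz, SG_WINDOW, SG_ORDER, mode="interp")
    return TuningCurve(
        curve.freqs_khz,
        curve.rates_hz,
        intensity_db=curve.intensity_db,
        smoothed_rates_hz=smoothed,
    )


def tuning_width(curve: TuningCurve) -> TuningWidth:
    """Half-peak width in octaves of the (smoothed, if available) curve.

    Measured between the outermost half-peak crossings flanking the global
    peak, with linear interpolation on the log2-frequency axis. A flank that
    never falls below half peak is cut at the grid edge and flagged.
    """
    rates = (
        curve.smoothed_rates_hz
        if curve.smoothed_rates_hz is not None
        else curve.rates_hz
    )
    rates = np.asarray(rates, dtype=float)
    x = curve.log2_freqs
    peak_i = int(np.argmax(rates))
    peak = rates[peak_i]
    if peak <= 0:
        raise ValueError("tuning width requires a positive peak")
    half = peak / 2.0

    truncated = False
    # left flank: walk outward until the curve drops below half peak
    left = x[0]
    for i in range(peak_i, 0, -1):
        if rates[i - 1] < half <= rates[i]:
            left = x[i - 1] + (half - rates[i - 1]) / (rates[i] - rates[i - 1]) * (
                x[i] - x[i - 1]
            )
            break
    else:
        truncated = True
    # right flank
    right = x[-1]
    for i in range(peak_i, rates.size - 1):
        if rates[i + 1] < half <= rates[i]:
            right = x[i] + (rates[i] - half) / (rates[i] - rates[i + 1]) * (
                x[i + 1] - x[i]
            )
            break
    else:
        truncated = True
    return TuningWidth(width_oct=float(right - left), truncated=truncated)


def fit_gaussian(curve: TuningCurve) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit on the log2-frequency axis.

    Initialization: A = max - min, B = min, f0 = argmax, with a multi-start
    sweep over sigma in {0.25, 0.5, 1, 2} octaves; A is constrained
    non-negative and sigma to (0.05, 5] octaves. R^2 = 1 - SS_res / SS_tot
    on the raw (unsmoothed) rates; the unit is included (tuned) iff
    R^2 > 0.4.
    """
    y = np.asarray(curve.rates_hz, dtype=float)
    x = curve.log2_freqs
    if y.size < 5 or not np.all(np.isfinite(y)):
        raise InsufficientCoverageError("need >= 5 finite rates to fit")

    a0 = float(y.max() - y.min())
    b0 = float(y.min())
    f00 = float(x[int(np.argmax(y))])
    lower = [0.0, x[0] - 2.0, SIGMA_BOUNDS_OCT[0], -np.inf]
    upper = [np.inf, x[-1] + 2.0, SIGMA_BOUNDS_OCT[1], np.inf]

    best_params, best_sse = None, np.inf
    for s0 in SIGMA_STARTS_OCT:
        try:
            params, _ = curve_fit(
                _gauss,
                x,
                y,
                p0=[max(a0, 1e-6), f00, s0, b0],
                bounds=(lower, upper),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - _gauss(x, *params)) ** 2))
        if sse < best_sse:
            best_params, best_sse = params, sse

    if best_params is None:
        return GaussianFit(np.nan, np.nan, np.nan, np.nan, -np.inf, False, False)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - best_sse / ss_tot if ss_tot > 0 else 0.0
    A, f0, sigma, B = (float(v) for v in best_params)
    return GaussianFit(A, f0, sigma, B, r2, included=r2 > R2_INCLUSION)


def decompose_gain(
    control_fit: GaussianFit,
    light_fit: GaussianFit,
    normalize: bool = False,
) -> ConditionTransform:
    """Offset/divisive-gain transform mapping the control fit to light-on.

    Under R_light(f) = (R_ctrl(f) - offset) / scale with shared f0 and
    sigma: scale = A_ctrl / A_light and offset = B_ctrl - scale * B_light.
    With ``normalize=True`` the offset is expressed in units of the control
    fitted peak (A_ctrl + B_ctrl), the scale population curves are quoted
    in; the scale is dimensionless either way.
    """
    if not (control_fit.included and light_fit.included):
        raise ValueError("both fits must pass the inclusion criterion")
    if light_fit.A <= 0:
        raise UndefinedGainError("light-on amplitude must be positive")
    scale = control_fit.A / light_fit.A
    offset = control_fit.B - scale * light_fit.B
    if normalize:
        peak = control_fit.A + control_fit.B
        if peak <= 0:
            raise UndefinedGainError("control fitted peak must be positive")
        offset /= peak
    return ConditionTransform(offset=offset, scale=scale)


def apply_transform(fit: GaussianFit, transform: ConditionTransform) -> GaussianFit:
    """Apply (offset, scale) to a fitted curve: the expected light-on fit."""
    return GaussianFit(
        A=fit.A / transform.scale,
        f0=fit.f0,
        sigma=fit.sigma,
        B=(fit.B - transform.offset) / transform.scale,
        r_squared=fit.r_squared,
        included=fit.included,
    )


def fit_transform_lsq(
    control: TuningCurve, light: TuningCurve
) -> ConditionTransform:
    """Joint least-squares (offset, scale) fit directly on curve samples.

    Fallback for units whose two conditions are not well described by
    Gaussians with shared shape: minimizes
    sum_f (R_light(f) - (R_ctrl(f) - offset)/scale)^2 over offset and scale.
    Linear in (1/scale, offset/scale), solved in closed form.
    """
    x = np.asarray(control.rates_hz, dtype=float)
    y = np.asarray(light.rates_hz, dtype=float)
    if x.shape != y.shape:
        raise ValueError("conditions must share the frequency grid")
    # y = a*x + c with a = 1/scale, c = -offset/scale
    X = np.column_stack([x, np.ones_like(x)])
    (a, c), *_ = np.linalg.lstsq(X, y, rcond=None)
    if a <= 0:
        raise UndefinedGainError("fitted gain is non-positive")
    return ConditionTransform(offset=float(-c / a), scale=float(1.0 / a))


def align_and_normalize(
    curves: Sequence[tuple[TuningCurve, TuningCurve]],
) -> AlignedPopulation:
    """Best-frequency-aligned, control-normalized population tuning curves.

    Each element of ``curves`` is a (control, light_on) pair on a shared
    log-uniform frequency grid. Per unit, each condition is re-indexed by
    octave offset from that condition's own best frequency, and both
    conditions are divided by the unit's control best-frequency rate (units
    with non-positive control peaks are excluded). The control population
    curve is 1.0 at offset 0 by construction.
    """
    if not curves:
        raise ValueError("no units supplied")
    grid = curves[0][0].freqs_khz
    step = float(np.diff(np.log2(grid)).mean())
    n = grid.size
    offsets = step * np.arange(-(n - 1), n)
    per_unit: dict[str, list[np.ndarray]] = {"control": [], "light": []}

    for ctrl, light in curves:
        if ctrl.freqs_khz.shape != grid.shape or not np.allclose(
            ctrl.freqs_khz, grid
        ):
            raise ValueError("all units must share the frequency grid")
        norm = ctrl.rates_hz.max()
        if norm <= 0:
            continue
        for name, cond in (("control", ctrl), ("light", light)):
            bf_i = int(np.argmax(cond.rates_hz))
            row = np.full(offsets.size, np.nan)
            # offset index of grid point j relative to the best frequency
            row[(n - 1) - bf_i : (2 * n - 1) - bf_i] = cond.rates_hz / norm
            per_unit[name].append(row)

    n_units = len(per_unit["control"])
    if n_units == 0:
        raise ValueError("no unit had a positive control peak")
    stacked = {k: np.vstack(v) for k, v in per_unit.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # offsets with no units
        mean = {k: np.nanmean(v, axis=0) for k, v in stacked.items()}
        with np.errstate(invalid="ignore", divide="ignore"):
            sem = {
                k: np.nanstd(v, axis=0, ddof=1)
                / np.sqrt(np.sum(np.isfinite(v), axis=0))
                for k, v in stacked.items()
            }
    return AlignedPopulation(
        octave_offsets=offsets,
        mean_norm_rates=mean,
        sem_norm_rates=sem,
        n_units=n_units,
        unit_curves=stacked,
    )


@dataclass(frozen=True)
class ShoulderComparison:
    """Per-unit normalized rates +/- half an octave from the best frequency."""

    control: np.ndarray
    light: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def mean_difference(self) -> float:
        return float(np.mean(self.light - self.control))


def shoulder_rates(population: AlignedPopulation) -> ShoulderComparison:
    """Paired condition comparison of rates half an octave off the peak.

    For each unit the normalized rates at the +1/2- and -1/2-octave offsets
    from its own best frequency are averaged (per condition) and the
    conditions are compared with a paired t test.
    """
    offs = population.octave_offsets
    sel = np.isclose(np.abs(offs), 0.5, atol=1e-9)
    if not np.any(sel):
        raise ValueError("offset grid does not cover +/- 1/2 octave")
    vals = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # units missing a shoulder
        for name, rows in population.unit_curves.items():
            vals[name] = np.nanmean(rows[:, sel], axis=1)
    keep = np.isfinite(vals["control"]) & np.isfinite(vals["light"])
    ctrl, light = vals["control"][keep], vals["light"][keep]
    if ctrl.size < 2:
        raise ValueError("need >= 2 units with shoulder coverage")
    diffs = light - ctrl
    if np.allclose(diffs, 0):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_rel(light, ctrl)
    return ShoulderComparison(ctrl, light, float(t), float(p))


def peak_rates(population: AlignedPopulation) -> ShoulderComparison:
    """Paired condition comparison of normalized rates at the best frequency."""
    sel = np.isclose(population.octave_offsets, 0.0, atol=1e-9)
    vals = {
        name: rows[:, sel].ravel()
        for name, rows in population.unit_curves.items()
    }
    ctrl, light = vals["control"], vals["light"]
    diffs = light - ctrl
    if np.allclose(diffs, 0):
        t, p = 0.0, 1.0
    else:
        t, p = ttest_rel(light, ctrl)
    return ShoulderComparison(ctrl, light, float(t), float(p))


def population_transform(
    transforms: Sequence[ConditionTransform],
) -> dict[str, float]:
    """Mean +/- SEM of per-unit (offset, scale) across a population."""
    if not transforms:
        raise ValueError("no transforms supplied")
    offsets = np.array([t.offset for t in transforms])
    scales = np.array([t.scale for t in transforms])
    n = len(transforms)
    sem = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "offset_mean": float(offsets.mean()),
        "offset_sem": sem(offsets),
        "scale_mean": float(scales.mean()),
        "scale_sem": sem(scales),
        "n_units": n,
    }
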