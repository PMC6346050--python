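"""PSTH construction, tone-response window detection, and response taxonomy.

The peristimulus time histogram (PSTH) is built with a 3-ms window sliding in
1-ms steps from 100 ms before tone onset to 200 ms after tone end; bins are
indexed by window start time. Baseline statistics (mean, SD) come from the
bins in the 50 ms preceding onset. A unit responds when its PSTH crosses
3 SD above the baseline mean at or after onset (within 200 ms of tone end);
the earliest maximal contiguous suprathreshold run is the response window and
its start is the response latency. Units with no excitatory window whose PSTH
falls more than 2 SD below the baseline mean are suppression responses.

Excitatory windows are labelled by their timing relative to the tone:
windows ending before 50 ms after onset are onset responses; windows ending
at or after 50 ms are sustained; windows starting within 20 ms after tone
end are offset responses (start time decides when a window follows the tone).

The response firing rate is the mean in-window rate minus the baseline mean
(negative for suppression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

ResponseType = Literal["onset", "sustained", "offset", "suppression", "none"]

PSTH_PRE_S = 0.100          # PSTH span before tone onset
PSTH_POST_S = 0.200         # PSTH span after tone end
BASELINE_SPAN_S = 0.050     # baseline window before onset
EXCITE_SD = 3.0             # excitatory threshold, SDs above baseline mean
SUPPRESS_SD = 2.0           # suppression threshold, SDs below baseline mean
ONSET_END_S = 0.050         # onset vs sustained boundary after tone onset
OFFSET_SPAN_S = 0.020       # offset window must start within this of tone end
SD_FLOOR_HZ = 0.1           # keeps the threshold finite on silent baselines

# A window is only accepted if at least this many consecutive bins cross
# threshold. With 3-ms windows sliding by 1 ms, one chance spike cluster
# elevates at most ~3 consecutive bins, so 4 suppresses the multiple-
# comparison false positives a per-bin 3-SD rule incurs over ~300 bins
# while real responses (tens of ms) are unaffected.
DEFAULT_MIN_RUN_BINS = 4


class EmptyInputError(ValueError):
    """Raised when a PSTH is requested with no trials."""


class CoverageError(ValueError):
    """Raised when the PSTH does not cover a required span."""


@dataclass(frozen=True)
class Psth:
    """Trial-averaged firing rate on a sliding-window time axis.

    ``time_axis_s`` holds window *start* times relative to tone onset; the
    window ``[t, t + window_width_s)`` contributes the rate stored at ``t``.
    """

    time_axis_s: np.ndarray
    rates_hz: np.ndarray
    window_width_s: float
    step_s: float
    n_trials: int
    tone_duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_axis_s, dtype=float)
        r = np.asarray(self.rates_hz, dtype=float)
        if t.shape != r.shape:
            raise ValueError("time axis and rates must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(r < -1e-12):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "time_axis_s", t)
        object.__setattr__(self, "rates_hz", r)

    @property
    def tone_end_s(self) -> float:
        return self.tone_duration_s


@dataclass(frozen=True)
class BaselineStats:
    mean_hz: float
    sd_hz: float

    def __post_init__(self) -> None:
        if self.sd_hz < 0:
            raise ValueError("baseline SD must be non-negative")


@dataclass(frozen=True)
class ResponseWindow:
    """A detected threshold-crossing period, [start_s, end_s] from tone onset."""

    start_s: float
    end_s: float
    kind: Literal["excite", "suppress"]


@dataclass(frozen=True)
class ResponseProfile:
    responsive: bool
    response_type: ResponseType
    window: ResponseWindow | None
    latency_s: float | None
    response_rate_hz: float | None


def compute_psth(
    spike_times_s: Sequence[float],
    tone_onsets_s: Sequence[float],
    tone_duration_s: float,
    window_width_s: float = 0.003,
    step_s: float = 0.001,
) -> Psth:
    """Sliding-window PSTH across trials.

    The rate at window start t is (spike count across trials in
    [t, t + width)) / (n_trials x width). Window starts run from
    -100 ms to tone_end + 200 ms - width in steps of ``step_s``, so the
    final window ends exactly 200 ms after tone end.
    """
    onsets = np.asarray(tone_onsets_s, dtype=float)
    if onsets.size == 0:
        raise EmptyInputError("no trials supplied")
    if tone_duration_s <= 0 or window_width_s <= 0 or step_s <= 0:
        raise ValueError("durations and steps must be positive")

    spikes = np.sort(np.asarray(spike_times_s, dtype=float))
    span_end = tone_duration_s + PSTH_POST_S
    n_bins = int(round((span_end - window_width_s - (-PSTH_PRE_S)) / step_s)) + 1
    starts = -PSTH_PRE_S + step_s * np.arange(n_bins)

    counts = np.zeros(n_bins)
    for onset in onsets:
        rel = spikes - onset
        lo = np.searchsorted(rel, starts, side="left")
        hi = np.searchsorted(rel, starts + window_width_s, side="left")
        counts += hi - lo
    rates = counts / (onsets.size * window_width_s)
    return Psth(
        time_axis_s=starts,
        rates_hz=rates,
        window_width_s=window_width_s,
        step_s=step_s,
        n_trials=int(onsets.size),
        tone_duration_s=tone_duration_s,
    )


def baseline_stats(psth: Psth) -> BaselineStats:
    """Mean and sample SD of the PSTH bins starting in [-50 ms, 0)."""
    mask = (psth.time_axis_s >= -BASELINE_SPAN_S - 1e-12) & (psth.time_axis_s < 0)
    if not np.any(mask):
        raise CoverageError("PSTH does not cover the [-50, 0) ms baseline span")
    vals = psth.rates_hz[mask]
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return BaselineStats(mean_hz=float(np.mean(vals)), sd_hz=sd)


def detect_response_window(
    psth: Psth,
    baseline: BaselineStats,
    min_run_bins: int = DEFAULT_MIN_RUN_BINS,
    excite_sd: float = EXCITE_SD,
    suppress_sd: float = SUPPRESS_SD,
) -> ResponseWindow | None:
    """Earliest contiguous threshold-crossing run at or after tone onset.

    Excitatory crossings (rate > mean + 3 SD) are searched first; if none
    exists, suppression crossings (rate < mean - 2 SD) are searched. The
    baseline SD is floored at 0.1 Hz so silent baselines cannot produce a
    zero-width threshold. Candidate windows start at or after onset and
    within 200 ms of tone end. Runs separated by one or more subthreshold
    bins are distinct; only the earliest run of at least ``min_run_bins``
    bins is returned, as [first start, last start + width].
    """
    sd = max(baseline.sd_hz, SD_FLOOR_HZ)
    t = psth.time_axis_s
    candidate = (t >= -1e-12) & (t <= psth.tone_end_s + PSTH_POST_S + 1e-12)

    for kind, mask in (
        ("excite", psth.rates_hz > baseline.mean_hz + excite_sd * sd),
        ("suppress", psth.rates_hz < baseline.mean_hz - suppress_sd * sd),
    ):
        run = _earliest_run(mask & candidate, min_run_bins)
        if run is not None:
            first, last = run
            return ResponseWindow(
                start_s=float(t[first]),
                end_s=float(t[last] + psth.window_width_s),
                kind=kind,  # type: ignore[arg-type]
            )
    return None


def _earliest_run(mask: np.ndarray, min_run: int) -> tuple[int, int] | None:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return None
    # split into maximal contiguous runs of bin indices
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_run:
            return int(idx[s]), int(idx[e])
    return None


def classify_response(
    window: ResponseWindow,
    psth: Psth,
    baseline: BaselineStats,
    tone_duration_s: float | None = None,
) -> ResponseType:
    """Label a detected window as onset, sustained, offset, or suppression.

    Suppression windows keep their label. Excitatory windows starting within
    20 ms after tone end (start >= tone end, strictly before tone end +
    20 ms) are offset responses; otherwise windows ending before 50 ms after
    tone onset are onset responses and all later-ending windows are
    sustained (a window ending exactly at 50 ms is sustained).
    """
    tone_end = psth.tone_end_s if tone_duration_s is None else tone_duration_s
    if window.kind == "suppress":
        return "suppression"
    if tone_end - 1e-12 <= window.start_s < tone_end + OFFSET_SPAN_S - 1e-12:
        return "offset"
    if window.end_s < ONSET_END_S - 1e-12:
        return "onset"
    return "sustained"


def response_rate(psth: Psth, window: ResponseWindow, baseline: BaselineStats) -> float:
    """Mean in-window PSTH rate minus the baseline mean (Hz)."""
    t = psth.time_axis_s
    mask = (t >= window.start_s - 1e-12) & (
        t <= window.end_s - psth.window_width_s + 1e-12
    )
    if not np.any(mask):
        raise ValueError("response window covers no PSTH bins")
    return float(np.mean(psth.rates_hz[mask]) - baseline.mean_hz)


def profile_response(
    psth: Psth,
    baseline: BaselineStats | None = None,
    min_run_bins: int = DEFAULT_MIN_RUN_BINS,
) -> ResponseProfile:
    """Full per-unit response characterization from a PSTH.

    Detects the response window, classifies it, and computes latency (the
    window start) and the baseline-subtracted response rate. Returns an
    unresponsive profile when no bin crosses threshold.
    """
    if baseline is None:
        baseline = baseline_stats(psth)
    window = detect_response_window(psth, baseline, min_run_bins=min_run_bins)
    if window is None:
        return ResponseProfile(False, "none", None, None, None)
    rtype = classify_response(window, psth, baseline)
    return ResponseProfile(
        responsive=True,
        response_type=rtype,
        window=window,
        latency_s=window.start_s,
        response_rate_hz=response_rate(psth, window, baseline),
    )
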