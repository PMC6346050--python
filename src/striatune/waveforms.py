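"""Spike-waveform half-valley width and striatal cell-type classification.

Striatal single units separate into three classes by the duration of the
spike trough at half its depth (the half-valley width): fast-spiking
interneurons (FS) below 100 microseconds, putative medium spiny neurons (MSN)
from 100 to 150 microseconds inclusive, and cholinergic interneurons (ChI)
above 150 microseconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

CellClass = Literal["FS", "MSN", "ChI"]

# half-valley-width boundaries, microseconds; both boundaries belong to MSN
FS_MAX_WIDTH_US = 100.0
CHI_MIN_WIDTH_US = 150.0


class NoValleyError(ValueError):
    """Raised when a waveform has no negative trough below its baseline."""


@dataclass(frozen=True)
class WaveformMetrics:
    """Derived waveform features for one unit."""

    half_valley_width_us: float
    cell_class: CellClass
    trough_index: int
    baseline_uv: float


def half_valley_width(samples, sample_rate_hz: float) -> float:
    """Width (microseconds) of the spike trough at half of its depth.

    The trough is the global minimum of the waveform. Its depth is measured
    from the pre-trough baseline, taken as the mean of all samples up to and
    including the pre-trough maximum (the waveform level before the spike
    deflects downward). The width is the distance between the two half-depth
    crossings bracketing the trough, with linear interpolation between
    samples; a flank that never re-crosses half depth is cut at the waveform
    edge.
    """
    return _measure(samples, sample_rate_hz).half_valley_width_us


def waveform_metrics(samples, sample_rate_hz: float) -> WaveformMetrics:
    """Half-valley width plus the class assignment for one mean waveform."""
    return _measure(samples, sample_rate_hz)


def _measure(samples, sample_rate_hz: float) -> WaveformMetrics:
    y = np.asarray(samples, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("waveform must be a 1-D sequence of at least 3 samples")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")

    trough = int(np.argmin(y))
    if trough == 0 or trough == y.size - 1:
        raise NoValleyError("waveform minimum at an edge: no bracketed trough")
    pre_peak = int(np.argmax(y[:trough]))
    baseline = float(np.mean(y[: pre_peak + 1]))
    depth = baseline - y[trough]
    if depth <= 0:
        raise NoValleyError("waveform never drops below its baseline")
    half_level = baseline - depth / 2.0

    left = _cross_left(y, trough, half_level)
    right = _cross_right(y, trough, half_level)
    width_samples = right - left
    width_us = width_samples / sample_rate_hz * 1e6
    return WaveformMetrics(
        half_valley_width_us=width_us,
        cell_class=classify_unit(width_us),
        trough_index=trough,
        baseline_uv=baseline,
    )


def _cross_left(y: np.ndarray, trough: int, level: float) -> float:
    for i in range(trough, 0, -1):
        if y[i - 1] >= level > y[i]:
            # linear interpolation between samples i-1 and i
            return (i - 1) + (y[i - 1] - level) / (y[i - 1] - y[i])
    return 0.0


def _cross_right(y: np.ndarray, trough: int, level: float) -> float:
    n = len(y)
    for i in range(trough, n - 1):
        if y[i] < level <= y[i + 1]:
            return i + (level - y[i]) / (y[i + 1] - y[i])
    return float(n - 1)


def classify_unit(
    width_us: float,
    fs_max_us: float = FS_MAX_WIDTH_US,
    chi_min_us: float = CHI_MIN_WIDTH_US,
) -> CellClass:
    """Assign a cell class from the half-valley width.

    Strictly below 100 us is FS, strictly above 150 us is ChI, and the
    closed interval [100, 150] us is putative MSN (every positive width
    receives exactly one class).
    """
    if not np.isfinite(width_us) or width_us <= 0:
        raise ValueError(f"half-valley width must be positive, got {width_us}")
    if fs_max_us > chi_min_us:
        raise ValueError("FS boundary must not exceed the ChI boundary")
    if width_us < fs_max_us:
        return "FS"
    if width_us > chi_min_us:
        return "ChI"
    return "MSN"
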