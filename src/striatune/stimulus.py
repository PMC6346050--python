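"""Cloud-of-tones stimulus generation and the evidence-strength statistic.

The task stimulus is a stream of 30-ms overlapping pure tones presented at
100 Hz, drawn from an 18-point log-spaced frequency grid spanning 5-40 kHz
(three octaves, six grid frequencies per octave). On each trial one octave
band -- low (5-10 kHz) or high (20-40 kHz) -- is the target; each tone lands
in the target octave with probability (1 + 2r/100)/3, where r in [0, 100] is
the stimulus strength. At r = 0 the three octaves are equiprobable (chance,
1/3); at r = 100 every tone is a target-octave tone.

The printed form of the probability, "1 + 2r/100/3", is parenthesized here as
(1 + 2r/100)/3 -- the only reading that is bounded in [1/3, 1] over
r in [0, 100] and equals chance at r = 0.

Evidence strength summarizes a trial's tones as
(#high - #low) / (#high + #low); middle-octave tones count toward neither
term. Values -1 and 1 carry full evidence, 0 none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Band = Literal["low", "high"]


class UndefinedEvidenceError(ValueError):
    """Raised when a trial has no low- or high-octave tones."""


@dataclass(frozen=True)
class ToneCloudConfig:
    """Parameters of the cloud-of-tones stimulus.

    Defaults are the task's values: 18 log2-spaced frequencies from 5 to
    40 kHz, 30-ms tones at 100 onsets per second, low band 5-10 kHz and
    high band 20-40 kHz (one octave each).
    """

    freq_grid_khz: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.geomspace(5.0, 40.0, 18))
    )
    tone_duration_s: float = 0.030
    tone_rate_hz: float = 100.0
    low_band_khz: tuple[float, float] = (5.0, 10.0)
    high_band_khz: tuple[float, float] = (20.0, 40.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.freq_grid_khz, dtype=float)
        if grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("freq_grid_khz must be strictly increasing")
        steps = np.diff(np.log2(grid))
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("freq_grid_khz must be uniformly spaced in log2")
        for name, (lo, hi) in (
            ("low_band_khz", self.low_band_khz),
            ("high_band_khz", self.high_band_khz),
        ):
            if not np.isclose(np.log2(hi / lo), 1.0):
                raise ValueError(f"{name} must span exactly one octave")
        if self.low_band_khz[1] > self.high_band_khz[0]:
            raise ValueError("low and high bands must be disjoint")

    def band_of(self, freq_khz: float) -> Literal["low", "mid", "high"]:
        """Octave band of a frequency (band edges inclusive)."""
        if self.low_band_khz[0] <= freq_khz <= self.low_band_khz[1]:
            return "low"
        if self.high_band_khz[0] <= freq_khz <= self.high_band_khz[1]:
            return "high"
        return "mid"

    def band_freqs(self, band: Literal["low", "mid", "high"]) -> np.ndarray:
        grid = np.asarray(self.freq_grid_khz)
        return grid[[self.band_of(f) == band for f in grid]]


@dataclass(frozen=True)
class TrialStimulus:
    """One trial's tone stream."""

    tone_onsets_s: np.ndarray
    tone_freqs_khz: np.ndarray
    target: Band
    r: float
    config: ToneCloudConfig = field(default_factory=ToneCloudConfig)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.tone_onsets_s, dtype=float)
        freqs = np.asarray(self.tone_freqs_khz, dtype=float)
        if onsets.shape != freqs.shape:
            raise ValueError("tone_onsets_s and tone_freqs_khz must align")
        if np.any(np.diff(onsets) < 0):
            raise ValueError("tone onsets must be non-decreasing")
        grid = np.asarray(self.config.freq_grid_khz)
        if freqs.size and not np.all(
            np.isclose(freqs[:, None], grid[None, :], rtol=1e-9).any(axis=1)
        ):
            raise ValueError("every tone frequency must lie on the grid")
        object.__setattr__(self, "tone_onsets_s", onsets)
        object.__setattr__(self, "tone_freqs_khz", freqs)


def target_octave_probability(r: float) -> float:
    """Probability (1 + 2r/100)/3 that a tone is drawn from the target octave."""
    p = (1.0 + 2.0 * r / 100.0) / 3.0
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"target probability {p:.3f} outside [0, 1] for r={r}")
    return p


def generate_tone_cloud(
    config: ToneCloudConfig,
    r: float,
    target: Band,
    duration_s: float,
    seed: int | np.random.Generator,
) -> TrialStimulus:
    """Draw one trial's tone cloud.

    Tone onsets lie on a regular grid at ``tone_rate_hz`` (a deterministic
    overlapping stream; tones outlast the inter-onset interval). Each tone is
    independently assigned to the target octave with probability
    (1 + 2r/100)/3, otherwise uniformly to one of the two non-target octaves,
    and then to a uniformly chosen grid frequency within its octave.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not 0 <= r <= 100:
        raise ValueError(f"r must lie in [0, 100] (target encodes the side), got {r}")
    if target not in ("low", "high"):
        raise ValueError(f"target must be 'low' or 'high', got {target!r}")
    p = target_octave_probability(r)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n_tones = int(round(duration_s * config.tone_rate_hz))
    onsets = np.arange(n_tones) / config.tone_rate_hz

    others = [b for b in ("low", "mid", "high") if b != target]
    in_target = rng.random(n_tones) < p
    other_pick = rng.integers(2, size=n_tones)
    freqs = np.empty(n_tones)
    band_of_tone = np.where(
        in_target, target, np.asarray(others, dtype=object)[other_pick]
    )
    for band in ("low", "mid", "high"):
        mask = band_of_tone == band
        if mask.any():
            choices = config.band_freqs(band)
            freqs[mask] = choices[rng.integers(len(choices), size=int(mask.sum()))]
    return TrialStimulus(onsets, freqs, target=target, r=r, config=config)


def evidence_strength(stimulus: TrialStimulus) -> float:
    """(#high - #low) / (#high + #low) over the trial's tones.

    Middle-octave tones enter neither the numerator nor the denominator.
    Raises :class:`UndefinedEvidenceError` when the trial has no tones in
    either flanking octave.
    """
    bands = [stimulus.config.band_of(f) for f in stimulus.tone_freqs_khz]
    n_high = sum(b == "high" for b in bands)
    n_low = sum(b == "low" for b in bands)
    return evidence_from_counts(n_high, n_low)


def evidence_from_counts(n_high: int, n_low: int) -> float:
    """Evidence strength from explicit high/low tone counts."""
    if n_high < 0 or n_low < 0:
        raise ValueError("tone counts must be non-negative")
    denom = n_high + n_low
    if denom == 0:
        raise UndefinedEvidenceError("no tones in the low or high octave")
    return (n_high - n_low) / denom


def stimuli_to_tables(stimuli: Sequence[TrialStimulus]):
    """Serialize trials to (per-tone, per-trial) DataFrames.

    Per-tone columns: trial_id, onset_s, freq_khz. Per-trial columns:
    trial_id, r, target, evidence_strength.
    """
    import pandas as pd

    tone_rows, trial_rows = [], []
    for tid, stim in enumerate(stimuli):
        for onset, freq in zip(stim.tone_onsets_s, stim.tone_freqs_khz):
            tone_rows.append({"trial_id": tid, "onset_s": onset, "freq_khz": freq})
        try:
            ev = evidence_strength(stim)
        except UndefinedEvidenceError:
            ev = np.nan
        trial_rows.append(
            {"trial_id": tid, "r": stim.r, "target": stim.target, "evidence_strength": ev}
        )
    return pd.DataFrame(tone_rows), pd.DataFrame(trial_rows)
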