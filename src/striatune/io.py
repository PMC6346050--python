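"""Readers/writers for the pipeline's comma-separated table formats.

All on-disk data are plain CSV with headers: spike tables (unit_id,
spike_time_s), trial tables (trial_id, onset_s, freq_khz, intensity_db,
duration_s, light_on), waveform tables (unit_id, sample_index,
amplitude_uv) with a companion units table (unit_id, sample_rate_hz), and
behavior tables (trial_id, r, evidence, choice, correct, reaction_time_s,
reported, session_id, treatment). Times are seconds, frequencies kHz,
sample indices 0-based, intervals half-open [start, end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

SCHEMAS: dict[str, dict[str, type]] = {
    "spikes": {"unit_id": int, "spike_time_s": float},
    "trials": {
        "trial_id": int,
        "onset_s": float,
        "freq_khz": float,
        "intensity_db": float,
        "duration_s": float,
        "light_on": bool,
    },
    "waveforms": {"unit_id": int, "sample_index": int, "amplitude_uv": float},
    "units": {"unit_id": int, "sample_rate_hz": float},
    "behavior": {
        "trial_id": int,
        "r": float,
        "evidence": float,
        "choice": str,
        "correct": bool,
        "reaction_time_s": float,
        "reported": bool,
        "session_id": str,
        "treatment": str,
    },
}


class SchemaError(ValueError):
    """A table is missing required columns or fails a validity check."""


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and schema-validate one CSV table.

    ``kind`` selects the expected schema (one of 'spikes', 'trials',
    'waveforms', 'units', 'behavior'). Missing required columns raise
    :class:`SchemaError` naming them; an empty file returns an empty frame
    with a warning. Timestamp monotonicity is enforced per unit for spike
    tables and globally for trial tables.
    """
    if kind not in SCHEMAS:
        raise KeyError(f"unknown table kind {kind!r}")
    path = Path(path)
    schema = SCHEMAS[kind]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path} is empty; returning empty {kind} table")
        return pd.DataFrame(columns=list(schema))
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing} for {kind} table")
    for col, typ in schema.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[:5]
            raise SchemaError(
                f"{path}: column {col!r} not coercible to {typ.__name__} "
                f"(first bad rows: {list(bad + 2)})"  # +2: header + 1-based
            ) from exc
    _validate(df, kind, path)
    return df


def _validate(df: pd.DataFrame, kind: str, path: Path) -> None:
    if kind == "spikes" and len(df):
        for uid, grp in df.groupby("unit_id"):
            if grp["spike_time_s"].diff().dropna().lt(0).any():
                raise SchemaError(f"{path}: spike times not sorted for unit {uid}")
    if kind == "trials" and len(df):
        if df["onset_s"].diff().dropna().lt(0).any():
            raise SchemaError(f"{path}: trial onsets not monotone")
    if kind == "behavior" and len(df):
        bad = ~df["choice"].isin(["left", "right", "none"])
        if bad.any():
            raise SchemaError(
                f"{path}: unknown choice labels {sorted(df.loc[bad, 'choice'].unique())}"
            )


def write_table(df: pd.DataFrame, path: str | Path, kind: str | None = None) -> Path:
    """Write a table as CSV (validating against a schema when given)."""
    path = Path(path)
    if kind is not None:
        missing = [c for c in SCHEMAS[kind] if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {kind} table missing {missing}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    """Every numeric constant the pipeline applies, in one place."""

    spikes_path: str | None = None
    trials_path: str | None = None
    waveforms_path: str | None = None
    units_path: str | None = None
    behavior_path: str | None = None

    psth_window_s: float = 0.003
    psth_step_s: float = 0.001
    fs_max_width_us: float = 100.0
    chi_min_width_us: float = 150.0
    excite_sd: float = 3.0
    suppress_sd: float = 2.0
    sg_window: int = 5
    sg_order: int = 2
    r2_threshold: float = 0.4
    min_run_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.psth_window_s, self.psth_step_s) <= 0:
            raise ValueError("PSTH window and step must be positive")
        if min(self.fs_max_width_us, self.chi_min_width_us) <= 0:
            raise ValueError("classification thresholds must be positive")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("R^2 threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
        return path
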