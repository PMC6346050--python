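"""End-to-end orchestration: recordings in, per-unit tables and summary out.

The pipeline consumes the four recording tables (trials, spikes, waveforms,
units), classifies each unit by waveform, detects tone responses on control
(light-off) trials, picks the analysis intensity (60 or 70 dB, the lower
responsive one), builds control and light-on tuning curves with the
control-determined response window, fits Gaussians, and quantifies the
light effect via per-unit offset/divisive-gain decomposition plus the
aligned-population peak and shoulder comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import responses, tuning, waveforms
from .io import PipelineConfig


@dataclass
class PipelineResult:
    unit_table: pd.DataFrame
    response_table: pd.DataFrame
    tuning_table: pd.DataFrame
    fit_table: pd.DataFrame
    transform_table: pd.DataFrame
    summary: dict[str, Any] = field(default_factory=dict)
    population: tuning.AlignedPopulation | None = None


def classify_units(
    waveform_df: pd.DataFrame,
    units_df: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Half-valley width and cell class for every unit with a waveform."""
    config = config or PipelineConfig()
    rates = units_df.set_index("unit_id")["sample_rate_hz"]
    rows = []
    for uid, grp in waveform_df.groupby("unit_id"):
        samples = grp.sort_values("sample_index")["amplitude_uv"].to_numpy()
        try:
            width = waveforms.half_valley_width(samples, float(rates.loc[uid]))
            rows.append(
                {
                    "unit_id": uid,
                    "half_valley_width_us": width,
                    "cell_class": waveforms.classify_unit(
                        width, config.fs_max_width_us, config.chi_min_width_us
                    ),
                }
            )
        except waveforms.NoValleyError:
            rows.append(
                {"unit_id": uid, "half_valley_width_us": np.nan, "cell_class": "unclassified"}
            )
    return pd.DataFrame(rows)


def _unit_psth(
    spikes: np.ndarray, trials: pd.DataFrame, config: PipelineConfig
) -> responses.Psth:
    return responses.compute_psth(
        spikes,
        trials["onset_s"].to_numpy(),
        float(trials["duration_s"].iloc[0]),
        window_width_s=config.psth_window_s,
        step_s=config.psth_step_s,
    )


def characterize_unit(
    spikes: np.ndarray, trials: pd.DataFrame, config: PipelineConfig
) -> dict[str, Any]:
    """Responsiveness per intensity (control trials) and the analysis choice.

    Returns responsiveness flags for each tested intensity, the selected
    analysis intensity (60/70-dB rule), and the control response profile,
    window and baseline at that intensity.
    """
    ctrl = trials[~trials["light_on"]]
    profiles: dict[float, responses.ResponseProfile] = {}
    baselines: dict[float, responses.BaselineStats] = {}
    for inten, grp in ctrl.groupby("intensity_db"):
        psth = _unit_psth(spikes, grp, config)
        base = responses.baseline_stats(psth)
        window = responses.detect_response_window(
            psth,
            base,
            min_run_bins=config.min_run_bins,
            excite_sd=config.excite_sd,
            suppress_sd=config.suppress_sd,
        )
        if window is None:
            profiles[float(inten)] = responses.ResponseProfile(
                False, "none", None, None, None
            )
        else:
            profiles[float(inten)] = responses.ResponseProfile(
                True,
                responses.classify_response(window, psth, base),
                window,
                window.start_s,
                responses.response_rate(psth, window, base),
            )
        baselines[float(inten)] = base
    responsive = {i: p.responsive for i, p in profiles.items()}
    try:
        intensity = tuning.select_analysis_intensity(responsive)
    except tuning.NotResponsiveError:
        intensity = None
    return {
        "responsive_by_db": responsive,
        "analysis_intensity_db": intensity,
        "profiles": profiles,
        "baselines": baselines,
    }


def unit_tuning_curves(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    window: responses.ResponseWindow,
    config: PipelineConfig,
    intensity_db: float,
) -> dict[str, tuning.TuningCurve]:
    """Control and light-on tuning curves with the control response window.

    The baseline subtracted from each condition is that condition's own
    pre-tone firing rate, so light effects on spontaneous activity do not
    masquerade as evoked changes.
    """
    out = {}
    for name, mask in (("control", ~trials["light_on"]), ("light", trials["light_on"])):
        cond = trials[mask & (trials["intensity_db"] == intensity_db)]
        if len(cond) == 0:
            continue
        base = responses.baseline_stats(_unit_psth(spikes, cond, config))
        out[name] = tuning.build_tuning_curve(
            spikes, cond, window, base.mean_hz, intensity_db=intensity_db
        )
    return out


def run_pipeline(
    trials: pd.DataFrame,
    spikes: pd.DataFrame,
    waveform_df: pd.DataFrame,
    units_df: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Full analysis over one recording's tables; deterministic given inputs."""
    config = config or PipelineConfig()
    unit_table = classify_units(waveform_df, units_df, config)

    spike_map = {
        uid: grp["spike_time_s"].to_numpy() for uid, grp in spikes.groupby("unit_id")
    }
    response_rows, curve_rows, fit_rows, transform_rows = [], [], [], []
    pairs: list[tuple[tuning.TuningCurve, tuning.TuningCurve]] = []
    transforms: list[tuning.ConditionTransform] = []

    for uid in unit_table["unit_id"]:
        unit_spikes = spike_map.get(uid, np.empty(0))
        try:
            char = characterize_unit(unit_spikes, trials, config)
        except (responses.EmptyInputError, responses.CoverageError) as exc:
            raise type(exc)(f"unit {uid}: {exc}") from exc
        inten = char["analysis_intensity_db"]
        row = {
            "unit_id": uid,
            "analysis_intensity_db": inten,
            "responsive": inten is not None,
        }
        for db, flag in sorted(char["responsive_by_db"].items()):
            row[f"responsive_{int(db)}db"] = flag
        if inten is not None:
            prof = char["profiles"][inten]
            row.update(
                response_type=prof.response_type,
                latency_s=prof.latency_s,
                response_rate_hz=prof.response_rate_hz,
                window_start_s=prof.window.start_s,
                window_end_s=prof.window.end_s,
            )
        else:
            row.update(
                response_type="none",
                latency_s=np.nan,
                response_rate_hz=np.nan,
                window_start_s=np.nan,
                window_end_s=np.nan,
            )
        response_rows.append(row)
        if inten is None:
            continue
        prof = char["profiles"][inten]
        if prof.response_type == "suppression":
            continue  # tuning/gain path covers excitatory responses only

        curves = unit_tuning_curves(unit_spikes, trials, prof.window, config, inten)
        for cond, curve in curves.items():
            for f, r in zip(curve.freqs_khz, curve.rates_hz):
                curve_rows.append(
                    {"unit_id": uid, "condition": cond, "freq_khz": f, "rate_hz": r}
                )
        fits = {}
        for cond, curve in curves.items():
            fit = tuning.fit_gaussian(curve)
            fits[cond] = fit
            fit_rows.append(
                {
                    "unit_id": uid,
                    "condition": cond,
                    "A": fit.A,
                    "f0_log2khz": fit.f0,
                    "sigma_oct": fit.sigma,
                    "B": fit.B,
                    "r2": fit.r_squared,
                    "included": fit.included,
                }
            )
        if "control" in curves and "light" in curves:
            pairs.append((curves["control"], curves["light"]))
            if (
                fits.get("control")
                and fits.get("light")
                and fits["control"].included
                and fits["light"].included
                and fits["light"].A > 0
            ):
                tr = tuning.decompose_gain(
                    fits["control"], fits["light"], normalize=True
                )
                transforms.append(tr)
                transform_rows.append(
                    {"unit_id": uid, "offset": tr.offset, "scale": tr.scale}
                )

    response_table = pd.DataFrame(response_rows)
    summary: dict[str, Any] = {
        "n_units": int(len(unit_table)),
        "n_per_class": unit_table["cell_class"].value_counts().to_dict(),
        "n_responsive": int(response_table["responsive"].sum()) if len(response_table) else 0,
        "n_per_response_type": (
            response_table.loc[response_table["responsive"], "response_type"]
            .value_counts()
            .to_dict()
            if len(response_table)
            else {}
        ),
    }
    fit_table = pd.DataFrame(fit_rows)
    if len(fit_table):
        tuned = fit_table[(fit_table["condition"] == "control") & fit_table["included"]]
        summary["n_tuned"] = int(len(tuned))
    if transforms:
        summary["population_transform"] = tuning.population_transform(transforms)

    population = None
    if len(pairs) >= 2:
        population = tuning.align_and_normalize(pairs)
        peak = tuning.peak_rates(population)
        summary["peak_comparison"] = {
            "t": peak.t_statistic,
            "p": peak.p_value,
            "mean_difference": peak.mean_difference,
        }
        try:
            shoulder = tuning.shoulder_rates(population)
            summary["shoulder_comparison"] = {
                "t": shoulder.t_statistic,
                "p": shoulder.p_value,
                "mean_difference": shoulder.mean_difference,
            }
        except ValueError:
            pass

    return PipelineResult(
        unit_table=unit_table,
        response_table=response_table,
        tuning_table=pd.DataFrame(curve_rows),
        fit_table=pd.DataFrame(fit_rows),
        transform_table=pd.DataFrame(transform_rows),
        summary=summary,
        population=population,
    )
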