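"""Simulate the study's data: three silencing recordings plus behavior.

Writes, under scratch/data/:
  - mgb/     tetrode session with divisive light modulation (scale 1.8,
             offset 0.01 of peak) — the thalamic gain-control model
  - acx/     session with peak-preferential suppression — the cortical
             tuning model
  - dual/    session with full abolition of the evoked component
  - behavior.csv  paired saline/CNO 2AFC sessions for experimental
             (CNO flattens the psychometric slope) and control mice
"""

from pathlib import Path

from striatune import synth
from striatune.io import write_table

OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"
SEED = 7301
N_UNITS = 10
TRIALS_PER_CONDITION = 6

MODULATIONS = {
    "mgb": synth.Modulation(kind="divisive", scale=1.8, offset=0.01),
    "acx": synth.Modulation(kind="peak_subtractive", depth=0.15, half_width_oct=0.5),
    "dual": synth.Modulation(kind="abolition"),
}


def main() -> None:
    for i, (name, modulation) in enumerate(MODULATIONS.items()):
        units = synth.default_population(N_UNITS, seed=SEED + i, modulation=modulation)
        bundle = synth.simulate_recording(
            synth.RecordingSpec(
                units=units,
                intensities_db=(60.0, 70.0),
                trials_per_condition=TRIALS_PER_CONDITION,
                seed=SEED + i,
            )
        )
        out = OUT / name
        write_table(bundle.trials, out / "trials.csv", "trials")
        write_table(bundle.spikes, out / "spikes.csv", "spikes")
        write_table(bundle.waveforms, out / "waveforms.csv", "waveforms")
        write_table(bundle.units, out / "units.csv", "units")
        print(
            f"{name}: {len(bundle.trials)} trials, {N_UNITS} units, "
            f"{len(bundle.spikes)} spikes -> {out}"
        )

    # paired behavior sessions: CNO flattens the slope in experimental mice only
    sessions = []
    for mouse in range(3):
        for treatment, beta1 in (("saline", 0.045), ("cno", 0.022)):
            sessions.append(
                synth.simulate_behavior(
                    0.1,
                    beta1,
                    n_trials=350,
                    nonreport_p=0.05,
                    seed=SEED + 10 * mouse + (treatment == "cno"),
                    session_id=f"hm4di_m{mouse}_{treatment}",
                    treatment=treatment,
                )
            )
    for mouse in range(3):
        for treatment in ("saline", "cno"):
            sessions.append(
                synth.simulate_behavior(
                    0.1,
                    0.045,
                    n_trials=350,
                    nonreport_p=0.05,
                    seed=SEED + 100 + 10 * mouse + (treatment == "cno"),
                    session_id=f"ctrl_m{mouse}_{treatment}",
                    treatment=treatment,
                )
            )
    import pandas as pd

    behavior = pd.concat(sessions, ignore_index=True)
    write_table(behavior, OUT / "behavior.csv", "behavior")
    print(f"behavior: {len(behavior)} trials across {len(sessions)} sessions")


if __name__ == "__main__":
    main()
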