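"""Behavioral effect of pathway silencing in the cloud-of-tones task.

Fits the logistic psychometric model per session, then compares saline vs
CNO sessions per mouse (paired t) on the psychometric slope, non-reported
trials, completed trials, and median reaction time. Writes
results/psychometric_fits.csv and results/behavior_comparisons.csv.

Expected: the slope drops under CNO in hM4Di-expressing mice and is
unchanged in control mice; counts and reaction times are unaffected in
both groups.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from striatune.behavior import compare_sessions, fit_psychometric, session_metrics
from striatune.io import read_table, write_table

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    behavior = read_table(DATA / "behavior.csv", "behavior")
    rows = []
    for sid, sess in behavior.groupby("session_id"):
        group, mouse, treatment = sid.split("_")
        fit = fit_psychometric(sess)
        metrics = session_metrics(sess)
        rows.append(
            {
                "session_id": sid,
                "group": group,
                "mouse": mouse,
                "treatment": treatment,
                "beta0": fit.beta0,
                "beta1": fit.beta1,
                "converged": fit.converged,
                "n_completed": metrics.n_completed,
                "n_nonreport": metrics.n_nonreport,
                "median_rt_s": float(np.median(list(metrics.median_rt_by_strength.values()))),
            }
        )
    fits = pd.DataFrame(rows)
    write_table(fits, ROOT / "psychometric_fits.csv")

    comparisons = []
    for group, grp in fits.groupby("group"):
        wide = grp.pivot(index="mouse", columns="treatment")
        for metric in ("beta1", "n_nonreport", "n_completed", "median_rt_s"):
            cmp = compare_sessions(
                wide[(metric, "saline")].to_numpy(),
                wide[(metric, "cno")].to_numpy(),
            )
            comparisons.append(
                {
                    "group": group,
                    "metric": metric,
                    "mean_saline": wide[(metric, "saline")].mean(),
                    "mean_cno": wide[(metric, "cno")].mean(),
                    "mean_difference": cmp.mean_difference,
                    "t": cmp.t_statistic,
                    "p": cmp.p_value,
                }
            )
            star = "*" if cmp.p_value < 0.05 else " "
            print(
                f"{group:6s} {metric:12s} saline {wide[(metric, 'saline')].mean():8.3f}"
                f"  cno {wide[(metric, 'cno')].mean():8.3f}  p={cmp.p_value:.3f}{star}"
            )
    write_table(pd.DataFrame(comparisons), ROOT / "behavior_comparisons.csv")


if __name__ == "__main__":
    main()
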