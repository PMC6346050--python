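"""Psychometric fitting and session metrics for the cloud-of-tones task.

Mice report whether a tone cloud is drawn mostly from the high or the low
octave by choosing a side port. Performance in a session is summarized by a
two-parameter logistic psychometric model fitted by Bernoulli maximum
likelihood on completed trials:

    log(p / (1 - p)) = beta0 + r * beta1

where p is the fraction of choices toward the port associated with high
frequencies and r is the signed stimulus strength in percent (r > 0 means
the high octave was the target). beta0 measures side bias and beta1 the
psychometric slope. The model carries no lapse parameter.

Session-level metrics count completed and non-reported trials (stimulus
triggered but neither side port chosen) and summarize accuracy and median
reaction time per stimulus-strength level. Saline and CNO (chemogenetic
silencing) sessions are compared per animal with paired t tests.

Which physical port is the high-frequency port is counterbalanced across
animals in practice; this module fixes the convention HIGH_PORT = "right".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ttest_rel

HIGH_PORT = "right"          # choice label counted as "toward high frequencies"
BETA_CAP = 25.0              # cap on |beta0| and |beta1 * 100| under separation


class EmptySessionError(ValueError):
    """Raised when metrics are requested for a session with no trials."""


class InsufficientDataError(ValueError):
    """Raised when a paired comparison has fewer than two pairs."""


@dataclass(frozen=True)
class PsychometricFit:
    beta0: float             # bias (log-odds at r = 0)
    beta1: float             # slope, log-odds per percent stimulus strength
    n_trials: int
    converged: bool

    def predict(self, r) -> np.ndarray:
        """P(choice toward the high port) at stimulus strength r."""
        z = self.beta0 + np.asarray(r, dtype=float) * self.beta1
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SessionMetrics:
    n_completed: int
    n_nonreport: int
    accuracy_by_strength: Mapping[float, float]
    median_rt_by_strength: Mapping[float, float]


@dataclass(frozen=True)
class PairedComparison:
    t_statistic: float
    p_value: float
    mean_difference: float
    n_pairs: int


def _completed(trials: pd.DataFrame) -> pd.DataFrame:
    return trials[trials["reported"] & (trials["choice"] != "none")]


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Maximum-likelihood logistic fit of high-port choice against r.

    ``trials`` must carry columns r (signed percent), choice
    ({left,right,none}) and reported; only completed trials enter the
    likelihood. Perfect separation (e.g. every choice identical, or choices
    perfectly predicted by r) is flagged as non-convergence and the
    estimates are capped rather than left unbounded.
    """
    done = _completed(trials)
    if done["r"].nunique() < 2:
        raise InsufficientDataError("need >= 2 distinct r values with choices")
    y = (done["choice"] == HIGH_PORT).to_numpy(dtype=float)
    X = sm.add_constant(done["r"].to_numpy(dtype=float))

    converged = True
    if y.min() == y.max():
        converged = False
        beta0 = np.sign(y.mean() - 0.5) * BETA_CAP if y.size else 0.0
        return PsychometricFit(float(beta0), 0.0, int(y.size), False)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta0, beta1 = res.params
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
            beta0, beta1 = res.params
            converged = False

    if abs(beta0) > BETA_CAP or abs(beta1) * 100 > BETA_CAP:
        converged = False
        beta0 = float(np.clip(beta0, -BETA_CAP, BETA_CAP))
        beta1 = float(np.clip(beta1, -BETA_CAP / 100, BETA_CAP / 100))
    return PsychometricFit(float(beta0), float(beta1), int(y.size), converged)


def session_metrics(trials: pd.DataFrame, by: str = "r") -> SessionMetrics:
    """Completed/non-report counts plus per-level accuracy and median RT.

    ``by`` selects the grouping variable: the nominal stimulus strength "r"
    (default) or the realized per-trial "evidence". Accuracy and reaction
    times use completed trials only.
    """
    if len(trials) == 0:
        raise EmptySessionError("session has no trials")
    if by not in trials.columns:
        raise KeyError(f"grouping column {by!r} missing from trials")
    done = _completed(trials)
    n_completed = int(len(done))
    n_nonreport = int(len(trials) - n_completed)

    acc = done.groupby(by)["correct"].mean().to_dict()
    rt = done.groupby(by)["reaction_time_s"].median().to_dict()
    return SessionMetrics(
        n_completed=n_completed,
        n_nonreport=n_nonreport,
        accuracy_by_strength={float(k): float(v) for k, v in acc.items()},
        median_rt_by_strength={float(k): float(v) for k, v in rt.items()},
    )


def compare_sessions(
    saline: Sequence[float], cno: Sequence[float]
) -> PairedComparison:
    """Two-sided paired t test of a per-animal metric, saline vs CNO.

    Returns the t statistic, two-sided p value and mean difference
    (CNO - saline). Identical pairs (zero-variance differences) are reported
    as t = 0, p = 1.
    """
    a = np.asarray(saline, dtype=float)
    b = np.asarray(cno, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise InsufficientDataError("need >= 2 pairs")
    diffs = b - a
    if np.allclose(diffs, diffs[0]) and np.isclose(diffs.std(), 0):
        t = 0.0 if np.isclose(diffs[0], 0) else np.inf * np.sign(diffs[0])
        p = 1.0 if t == 0.0 else 0.0
    else:
        t, p = ttest_rel(b, a)
    return PairedComparison(
        t_statistic=float(t),
        p_value=float(p),
        mean_difference=float(diffs.mean()),
        n_pairs=int(a.size),
    )
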