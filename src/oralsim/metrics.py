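"""Personalization metrics and Monte Carlo aggregation.

Three metrics summarize how well a candidate personalizes:

* ``avg_reward`` — the average over users of each user's time-averaged
  reward, (1/N) sum_i (1/T) sum_t R_it: a global performance measure;
* ``pct25_reward`` — the lower 25th percentile of the N per-user
  time-averages (linear interpolation between order statistics): how the
  worst-off quartile of users fares;
* ``checkpoint_rewards`` — the same user-average restricted to the first t0
  decisions, for a grid of t0, tracing learning speed over the study.

``aggregate`` averages each metric across Monte Carlo trials and attaches
the standard error of the mean (sample sd with n-1 denominator over trials,
divided by sqrt(n_trials)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import TrialResult

__all__ = [
    "DEFAULT_CHECKPOINTS",
    "MetricsReport",
    "avg_reward",
    "pct25_reward",
    "checkpoint_rewards",
    "aggregate",
    "summary_table",
    "checkpoint_table",
]

DEFAULT_CHECKPOINTS = (20, 40, 60, 80, 100, 120, 140)

#: percentile estimator; "linear" is the documented default convention
PERCENTILE_METHOD = "linear"


@dataclass(frozen=True)
class MetricsReport:
    """Across-trial mean and standard error of each metric."""

    avg_reward_mean: float
    avg_reward_se: float
    pct25_reward_mean: float
    pct25_reward_se: float
    checkpoint_means: dict[int, float]
    checkpoint_ses: dict[int, float]
    n_trials: int


def avg_reward(result: TrialResult) -> float:
    """Average over users of per-user time-averaged reward."""
    if result.n_users == 0:
        raise ValueError("empty trial result")
    return float(result.user_time_averages().mean())


def pct25_reward(result: TrialResult, method: str = PERCENTILE_METHOD) -> float:
    """Lower 25th percentile of the per-user time-averaged rewards."""
    if result.n_users == 0:
        raise ValueError("empty trial result")
    if result.n_users < 4:
        warnings.warn("pct25_reward with fewer than 4 users is poorly defined")
    return float(
        np.percentile(result.user_time_averages(), 25, method=method)
    )


def checkpoint_rewards(
    result: TrialResult, checkpoints=DEFAULT_CHECKPOINTS
) -> dict[int, float]:
    """Average of users' mean rewards over the first t0 decisions, per t0."""
    T = result.t_per_user
    out: dict[int, float] = {}
    for t0 in checkpoints:
        if not 1 <= t0 <= T:
            raise ValueError(f"checkpoint t0={t0} outside [1, {T}]")
        out[int(t0)] = float(result.rewards[:, :t0].mean(axis=1).mean())
    return out


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    if len(values) < 2:
        return mean, float("nan")
    return mean, float(values.std(ddof=1) / np.sqrt(len(values)))


def aggregate(
    results: list[TrialResult], checkpoints=DEFAULT_CHECKPOINTS
) -> MetricsReport:
    """Across-trial mean and standard error for every metric.

    With a single trial the SEs are reported as NaN (undefined)."""
    if not results:
        raise ValueError("no trial results to aggregate")
    avg = np.array([avg_reward(r) for r in results])
    p25 = np.array([pct25_reward(r) for r in results])
    cps = {t0: np.empty(len(results)) for t0 in checkpoints}
    for i, r in enumerate(results):
        cp = checkpoint_rewards(r, checkpoints)
        for t0 in checkpoints:
            cps[t0][i] = cp[t0]
    avg_m, avg_se = _mean_se(avg)
    p_m, p_se = _mean_se(p25)
    cp_ms, cp_ses = {}, {}
    for t0 in checkpoints:
        cp_ms[int(t0)], cp_ses[int(t0)] = _mean_se(cps[t0])
    return MetricsReport(avg_m, avg_se, p_m, p_se, cp_ms, cp_ses, len(results))


def summary_table(reports: dict[tuple[str, str], MetricsReport]) -> pd.DataFrame:
    """Comparison table: rows = algorithm candidates, columns = environment
    variants, cells = "mean (se)" with machine-readable companions.

    ``reports`` maps (candidate label, variant name) to a MetricsReport.
    """
    rows = []
    for (cand, variant), rep in sorted(reports.items()):
        rows.append(
            {
                "candidate": cand,
                "variant": variant,
                "avg_reward": f"{rep.avg_reward_mean:.3f} ({rep.avg_reward_se:.3f})",
                "avg_reward_mean": rep.avg_reward_mean,
                "avg_reward_se": rep.avg_reward_se,
                "pct25_reward": f"{rep.pct25_reward_mean:.3f} ({rep.pct25_reward_se:.3f})",
                "pct25_reward_mean": rep.pct25_reward_mean,
                "pct25_reward_se": rep.pct25_reward_se,
                "n_trials": rep.n_trials,
            }
        )
    return pd.DataFrame(rows)


def checkpoint_table(reports: dict[tuple[str, str], MetricsReport]) -> pd.DataFrame:
    """Long-format learning-curve table: (candidate, variant, t0, mean, se)."""
    rows = []
    for (cand, variant), rep in sorted(reports.items()):
        for t0, m in rep.checkpoint_means.items():
            rows.append(
                {
                    "candidate": cand,
                    "variant": variant,
                    "t0": t0,
                    "mean": m,
                    "se": rep.checkpoint_ses[t0],
                }
            )
    return pd.DataFrame(rows)
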