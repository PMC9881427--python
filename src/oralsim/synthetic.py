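"""Synthetic brushing-session data with controlled statistical structure.

Generates flat tables of (user, day, session, duration-in-seconds) records
shaped like a small observational oral-health study: two brushing windows per
day over a fixed study length, with heavily zero-inflated durations (a zero
means the user did not brush in that window) and between-user heterogeneity
both in the propensity to skip a session and in how long nonzero sessions
last.

The generative model is deliberately the same family as one of the per-user
base-model classes fit downstream (a hurdle model on the square-root scale):

* each user draws, once, a zero propensity ``p0_u`` from a logit-normal
  distribution centred at ``zero_prob_mean`` (``zero_prob_user_sd`` is the
  standard deviation on the logit scale; at 0 every user shares
  ``zero_prob_mean`` exactly);
* each user draws, once, a target mean nonzero duration
  ``m_u ~ Normal(duration_mean, duration_user_sd)``;
* each session is skipped with probability ``p0_u``; otherwise the duration
  is ``round(x**2)`` with ``x ~ Normal(mu_u, s)`` on the square-root scale,
  where ``s`` is set from ``duration_within_sd`` and ``mu_u`` is chosen so
  that ``E[x**2] = m_u`` (the location is ``sqrt(m_u - s**2)``).

Durations are integer seconds floored at 0 and are *not* truncated at 180:
truncation to the reward scale is a downstream operation.

One root seed drives everything; each user gets an independent substream
derived from the root, so enlarging ``n_users`` never perturbs the records of
earlier users.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "DatasetSummary",
    "generate_brushing_data",
    "summarize_dataset",
    "write_brushing_csv",
    "read_brushing_csv",
    "COLUMNS",
]

#: canonical column order of the brushing-record table
COLUMNS = ["user_id", "day", "session", "duration"]

MORNING, EVENING = 0, 1


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic brushing-data generator.

    Defaults emulate the shape of the prior no-intervention study the test
    bed is modelled on: 32 users, 28 days, two sessions per day, roughly 40%
    of sessions with no brushing, and nonzero durations centred near the
    dentist-recommended two minutes.
    """

    n_users: int = 32
    n_days: int = 28
    zero_prob_mean: float = 0.40
    zero_prob_user_sd: float = 0.7  # sd on the logit scale
    duration_mean: float = 120.0  # mean nonzero duration, seconds
    duration_user_sd: float = 25.0  # between-user sd of mean nonzero duration
    duration_within_sd: float = 40.0  # within-user sd of nonzero duration
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 1 or self.n_days < 1:
            raise ValueError("n_users and n_days must be >= 1")
        if not 0.0 <= self.zero_prob_mean <= 1.0:
            raise ValueError("zero_prob_mean must be a probability in [0, 1]")
        for name in ("zero_prob_user_sd", "duration_user_sd", "duration_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")


@dataclass(frozen=True)
class DatasetSummary:
    """Four summary statistics used throughout for fit checking.

    Variance convention (the statistics are named but not defined by common
    usage, so we fix one): ``between_user_var`` is the sample variance
    (ddof=1) of per-user mean durations, zeros included; ``within_user_var``
    is the mean over users of per-user sample variances (users with a single
    session contribute nothing).
    """

    zero_fraction: float
    mean_nonzero_duration: float
    between_user_var: float
    within_user_var: float


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1 - p)))


def generate_brushing_data(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a complete brushing-record table.

    Returns a DataFrame with one row per (user, day, session):
    ``n_users * n_days * 2`` rows, columns ``user_id, day, session, duration``
    with ``session`` coded 0=morning, 1=evening. Deterministic given
    ``config.seed``; user ``u``'s records depend only on the root seed and
    ``u``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    user_streams = root.spawn(config.n_users)

    s_within = config.duration_within_sd / (2.0 * np.sqrt(config.duration_mean))
    mu_logit = _logit(config.zero_prob_mean)

    n_sess = config.n_days * 2
    frames = []
    for u, ss in enumerate(user_streams):
        rng = np.random.default_rng(ss)
        if config.zero_prob_user_sd > 0:
            p0 = 1.0 / (1.0 + np.exp(-rng.normal(mu_logit, config.zero_prob_user_sd)))
        else:
            p0 = config.zero_prob_mean
        m_u = rng.normal(config.duration_mean, config.duration_user_sd)
        mu_u = np.sqrt(max(m_u - s_within**2, 1.0))

        skip = rng.random(n_sess) < p0
        x = rng.normal(mu_u, s_within, size=n_sess)
        dur = np.rint(x**2).astype(np.int64)
        dur = np.maximum(dur, 0)
        dur[skip] = 0
        frames.append(
            pd.DataFrame(
                {
                    "user_id": u,
                    "day": np.repeat(np.arange(1, config.n_days + 1), 2),
                    "session": np.tile([MORNING, EVENING], config.n_days),
                    "duration": dur,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def summarize_dataset(records: pd.DataFrame) -> DatasetSummary:
    """Compute the zero fraction, mean nonzero duration, and the two variance
    components (see :class:`DatasetSummary` for the convention)."""
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record collection")
    dur = records["duration"].to_numpy(dtype=float)
    zero_fraction = float(np.mean(dur == 0))
    nonzero = dur[dur > 0]
    mean_nonzero = float(nonzero.mean()) if nonzero.size else 0.0

    by_user = records.groupby("user_id")["duration"]
    user_means = by_user.mean().to_numpy(dtype=float)
    between = float(np.var(user_means, ddof=1)) if user_means.size > 1 else 0.0
    user_vars = by_user.var(ddof=1).dropna().to_numpy(dtype=float)
    within = float(user_vars.mean()) if user_vars.size else 0.0
    return DatasetSummary(zero_fraction, mean_nonzero, between, within)


def write_brushing_csv(records: pd.DataFrame, path) -> None:
    """Write records in the canonical CSV dialect (UTF-8, LF, header row)."""
    out = records[COLUMNS]
    if hasattr(path, "write"):
        out.to_csv(path, index=False, lineterminator="\n")
    else:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            out.to_csv(fh, index=False, lineterminator="\n")


def read_brushing_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    session_map: Mapping[object, int] | None = None,
) -> pd.DataFrame:
    """Read a brushing-record CSV, optionally remapping a foreign schema.

    ``column_map`` maps canonical names (``user_id``, ``day``, ``session``,
    ``duration``) to the column names actually present in the file; the
    mapping is user-supplied configuration, never guessed. ``session_map``
    translates arbitrary session labels to 0 (morning) / 1 (evening).
    ``user_id`` values are re-coded to dense integers in order of first
    appearance, so foreign files may use arbitrary identifiers.
    """
    df = pd.read_csv(path)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"columns {missing} not found in {path}")
        df = df.rename(columns={v: k for k, v in column_map.items()})
    absent = [c for c in COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(
            f"missing columns {absent}; supply column_map for foreign schemas"
        )
    df = df[COLUMNS].copy()
    if session_map is not None:
        df["session"] = df["session"].map(session_map)
        if df["session"].isna().any():
            raise ValueError("session_map does not cover all session labels")
    codes, _ = pd.factorize(df["user_id"])
    df["user_id"] = codes
    df = df.astype(
        {"user_id": np.int64, "day": np.int64, "session": np.int64, "duration": np.int64}
    )
    if (df["duration"] < 0).any():
        raise ValueError("durations must be nonnegative")
    return df.reset_index(drop=True)
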