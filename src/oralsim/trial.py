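"""Simulated micro-randomized-style trials of the bandit candidates.

A trial draws ``n_users`` user models from an environment's fitted pool with
replacement, recruits them incrementally (``recruit_per_week`` new users per
simulated week, all starting on the week's first day), groups them into
clusters by entry order, and runs one independent algorithm instance per
cluster over that cluster's pooled history. Each user faces two decision
times per day for ``t_per_user`` total decisions; cluster posteriors are
updated on a weekly cadence relative to the cluster's own start (first
update after 14 cluster-relative decision times), and the selection
probabilities used between updates come from the posterior frozen at the
last update.

Everything is deterministic given the trial seed: user sampling, action
draws, reward draws, and the seeded ZIP posterior approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import bandits
from .bandits import (
    BLRPosterior,
    HistoryBatch,
    ZIPPriorConfig,
    blr_prior,
    blr_treatment_probs,
    blr_update,
    zip_draw_params,
    zip_treatment_probs_from_draws,
    zip_update,
)
from .environment import (
    REWARD_CAP,
    EnvironmentVariant,
    ModelStack,
    _weekend,
    stack_models,
)

__all__ = ["TrialConfig", "TrialResult", "assign_clusters", "run_trial", "run_monte_carlo"]

D_ALG = 4  # algorithm state: [1, time_of_day, prev_day_brushing, weekend]


@dataclass(frozen=True)
class TrialConfig:
    """Configuration of one simulated trial / Monte Carlo sweep."""

    n_users: int = 72
    t_per_user: int = 140
    recruit_per_week: int = 4
    cluster_size: int = 1
    update_cadence_decisions: int = 14
    n_trials: int = 100
    algorithm: str = "blr"
    seed: int = 0
    eta2: float | None = None  # default: the environment's observed reward variance
    prior_scale: float = 25.0
    zip_n_draws: int = 100

    def validate(self) -> None:
        if self.n_users < 1 or self.t_per_user < 2 or self.t_per_user % 2:
            raise ValueError("t_per_user must be even and >= 2; n_users >= 1")
        if self.recruit_per_week < 1 or self.cluster_size < 1 or self.n_trials < 1:
            raise ValueError("recruit_per_week, cluster_size, n_trials must be >= 1")
        if self.update_cadence_decisions < 2 or self.update_cadence_decisions % 2:
            raise ValueError("update_cadence_decisions must be even and >= 2")
        if self.algorithm not in ("blr", "zip"):
            raise ValueError("algorithm must be 'blr' or 'zip'")
        if self.zip_n_draws < 1 or self.prior_scale <= 0:
            raise ValueError("zip_n_draws >= 1 and prior_scale > 0 required")
        if self.eta2 is not None and self.eta2 <= 0:
            raise ValueError("eta2 must be positive when given")


@dataclass
class TrialResult:
    """Complete per-decision log of one simulated trial."""

    rewards: np.ndarray  # (n_users, T) int
    probs: np.ndarray  # (n_users, T)
    actions: np.ndarray  # (n_users, T) int
    features: np.ndarray  # (n_users, T, D_ALG) algorithm-side states
    entry_week: np.ndarray  # (n_users,) 1-based
    cluster_ids: np.ndarray  # (n_users,)
    model_idx: np.ndarray  # (n_users,) index into the environment's pool
    env_name: str
    algorithm: str
    cluster_size: int
    seed: int
    update_events: list[tuple[int, int]] = field(default_factory=list)  # (day, cluster)
    posteriors: list = field(default_factory=list, repr=False)  # final, per cluster

    @property
    def n_users(self) -> int:
        return self.rewards.shape[0]

    @property
    def t_per_user(self) -> int:
        return self.rewards.shape[1]

    def user_time_averages(self) -> np.ndarray:
        return self.rewards.mean(axis=1)

    def to_dataframe(self, trial: int = 0) -> pd.DataFrame:
        """Trajectory log: one row per (user, decision time)."""
        n, T = self.rewards.shape
        df = pd.DataFrame(
            {
                "trial": trial,
                "user_id": np.repeat(np.arange(n), T),
                "cluster_id": np.repeat(self.cluster_ids, T),
                "t": np.tile(np.arange(1, T + 1), n),
                "prob": self.probs.ravel(),
                "action": self.actions.ravel(),
                "reward": self.rewards.ravel(),
            }
        )
        for j, name in enumerate(["f_intercept", "f_time_of_day", "f_prev_day", "f_weekend"]):
            df[name] = self.features[:, :, j].ravel()
        return df


def assign_clusters(entry_order: Sequence[int], k: int) -> np.ndarray:
    """Consecutive blocks of k users by entry order; the last block may be
    smaller. k=1 gives one cluster per user, k>=n one cluster total."""
    if k < 1:
        raise ValueError("cluster size must be >= 1")
    n = len(entry_order)
    return np.arange(n) // k


def _alg_features(session: int, prev_day: np.ndarray, user_day: np.ndarray) -> np.ndarray:
    m = len(user_day)
    return np.column_stack(
        [np.ones(m), np.full(m, float(session)), prev_day, _weekend(user_day)]
    )


def _sample_rewards(
    stack: ModelStack,
    idx: np.ndarray,
    G: np.ndarray,
    actions: np.ndarray,
    db: np.ndarray,
    dn: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    from scipy.special import expit

    from .environment import MODEL_CLASSES, _draw_durations

    a = actions.astype(float)
    p = expit(np.einsum("ij,ij->i", G, stack.W_b[idx]) + a * db[idx])
    lin = np.einsum("ij,ij->i", G, stack.W_n[idx]) + a * dn[idx]
    out = np.zeros(len(idx), dtype=np.int64)
    cls = stack.classes[idx]
    sig = stack.sigma[idx]
    for ci, cname in enumerate(MODEL_CLASSES):
        m = cls == ci
        if m.any():
            out[m] = _draw_durations(cname, p[m], lin[m], sig[m], rng)
    return np.minimum(out, REWARD_CAP)


def run_trial(env: EnvironmentVariant, config: TrialConfig, seed: int) -> TrialResult:
    """Run one complete simulated trial. See the module docstring for the
    schedule; raises if any emitted probability escapes the clip interval."""
    config.validate()
    n, T = config.n_users, config.t_per_user
    days_per_user = T // 2
    cadence_days = config.update_cadence_decisions // 2
    eta2 = config.eta2 if config.eta2 is not None else env.reward_variance
    lo, hi = bandits.PROB_CLIP

    root = np.random.SeedSequence(seed)
    ss_pool, ss_sim, ss_zip = root.spawn(3)
    rng_pool = np.random.default_rng(ss_pool)
    rng_sim = np.random.default_rng(ss_sim)
    zip_seed_base = int(ss_zip.generate_state(1)[0] >> 2)

    # draw the simulated sample from the fitted pool, with replacement
    model_idx = rng_pool.integers(0, len(env.user_pool), size=n)
    models = [env.user_pool[i] for i in model_idx]
    stack = stack_models(models)
    deltas = np.array([env.effects.effect_for(m.user_id) for m in models])
    db_u, dn_u = deltas[:, 0], deltas[:, 1]

    entry_week = np.arange(n) // config.recruit_per_week + 1
    entry_day = 7 * (entry_week - 1)
    cluster_ids = assign_clusters(np.arange(n), config.cluster_size)
    n_clusters = int(cluster_ids.max()) + 1
    cluster_entry = np.array(
        [entry_day[cluster_ids == c].min() for c in range(n_clusters)]
    )
    cluster_last = np.array(
        [entry_day[cluster_ids == c].max() + days_per_user for c in range(n_clusters)]
    )

    rewards = np.zeros((n, T), dtype=np.int64)
    probs = np.zeros((n, T))
    actions = np.zeros((n, T), dtype=np.int64)
    features = np.zeros((n, T, D_ALG))
    R_day = rewards.reshape(n, days_per_user, 2)  # view by (day, session)

    nonstat = env.base == "nonstationary"
    if config.algorithm == "blr":
        prior = blr_prior(D_ALG, eta2, config.prior_scale)
        posteriors = [prior for _ in range(n_clusters)]
    else:
        prior_cfg = ZIPPriorConfig(D_ALG, config.prior_scale)
        posteriors = [zip_update(prior_cfg, HistoryBatch.empty(D_ALG)) for _ in range(n_clusters)]
        cluster_draws = [
            zip_draw_params(posteriors[c], config.zip_n_draws, rng_sim)
            for c in range(n_clusters)
        ]
        warm = [None] * n_clusters

    update_events: list[tuple[int, int]] = []
    max_day = int(entry_day.max()) + days_per_user

    for day in range(1, max_day + 1):
        user_day_all = day - entry_day
        active = (user_day_all >= 1) & (user_day_all <= days_per_user)
        if active.any():
            idx = np.flatnonzero(active)
            ud = user_day_all[idx]
            for session in (0, 1):
                prev = np.zeros(len(idx))
                has_prev = ud >= 2
                if has_prev.any():
                    prev[has_prev] = (
                        R_day[idx[has_prev], ud[has_prev] - 2, :].sum(axis=1) / 360.0
                    )
                F = _alg_features(session, prev, ud)
                if nonstat:
                    G = np.column_stack([F, ud / days_per_user])
                else:
                    G = F

                raw = np.empty(len(idx))
                for c in np.unique(cluster_ids[idx]):
                    sel = cluster_ids[idx] == c
                    if config.algorithm == "blr":
                        raw[sel] = blr_treatment_probs(posteriors[c], F[sel])
                    else:
                        raw[sel] = zip_treatment_probs_from_draws(
                            cluster_draws[c], F[sel]
                        )
                p = np.clip(raw, lo, hi)
                if np.any((p < lo - 1e-9) | (p > hi + 1e-9)) or not np.all(
                    np.isfinite(p)
                ):
                    raise RuntimeError("selection probability escaped the clip interval")
                acts = (rng_sim.random(len(idx)) < p).astype(np.int64)
                r = _sample_rewards(stack, idx, G, acts, db_u, dn_u, rng_sim)

                t_idx = 2 * (ud - 1) + session
                rewards[idx, t_idx] = r
                probs[idx, t_idx] = p
                actions[idx, t_idx] = acts
                features[idx, t_idx, :] = F

        # end-of-day weekly updates, cluster-relative clocks
        for c in range(n_clusters):
            rel = day - cluster_entry[c]
            if rel < cadence_days or rel % cadence_days or day > cluster_last[c]:
                continue
            members = np.flatnonzero(cluster_ids == c)
            rows_f, rows_p, rows_a, rows_r = [], [], [], []
            for u in members:
                n_dec = 2 * int(np.clip(day - entry_day[u], 0, days_per_user))
                if n_dec > 0:
                    rows_f.append(features[u, :n_dec])
                    rows_p.append(probs[u, :n_dec])
                    rows_a.append(actions[u, :n_dec])
                    rows_r.append(rewards[u, :n_dec])
            if not rows_f:
                continue
            batch = HistoryBatch(
                np.vstack(rows_f),
                np.concatenate(rows_p),
                np.concatenate(rows_a),
                np.concatenate(rows_r),
            )
            if config.algorithm == "blr":
                posteriors[c] = blr_update(prior, batch)
            else:
                posteriors[c] = zip_update(
                    prior_cfg,
                    batch,
                    seed=(zip_seed_base + 7919 * c + day) % (2**31),
                    x0=warm[c],
                )
                warm[c] = posteriors[c].map_estimate
                cluster_draws[c] = zip_draw_params(
                    posteriors[c], config.zip_n_draws, rng_sim
                )
            update_events.append((day, int(c)))

    return TrialResult(
        rewards=rewards,
        probs=probs,
        actions=actions,
        features=features,
        entry_week=entry_week,
        cluster_ids=cluster_ids,
        model_idx=model_idx,
        env_name=env.name,
        algorithm=config.algorithm,
        cluster_size=config.cluster_size,
        seed=seed,
        update_events=update_events,
        posteriors=posteriors,
    )


def run_monte_carlo(
    env: EnvironmentVariant, config: TrialConfig
) -> list[TrialResult]:
    """Run ``config.n_trials`` independent trials with per-trial seeds derived
    from the root seed. Per-trial failures are collected and re-raised after
    the sweep."""
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(config.n_trials)
    results: list[TrialResult] = []
    failures: list[tuple[int, Exception]] = []
    for i, child in enumerate(children):
        trial_seed = int(child.generate_state(1)[0] >> 1)
        try:
            results.append(run_trial(env, config, trial_seed))
        except Exception as exc:  # noqa: BLE001 - resurfaced below
            failures.append((i, exc))
    if failures:
        raise RuntimeError(
            f"{len(failures)} of {config.n_trials} trials failed; first: "
            f"trial {failures[0][0]}: {failures[0][1]!r}"
        ) from failures[0][1]
    return results
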