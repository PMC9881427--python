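"""Reward-generating simulation environments built from brushing data.

The environment plays the role of the "user" in the simulated trials: given a
context (time of day, yesterday's brushing, weekend, optionally how far into
the study the user is) and an action (send / don't send an engagement
message), it draws a brushing duration and returns the truncated reward
``min(duration, 180)`` seconds.

Because the source data contains no intervention messages, the environment is
assembled in two steps:

1. **Base models** — for every user, three candidate generative models of
   duration under no action are fit to that user's sessions and the one with
   the lowest RMSE (between observed durations and the model's expected
   duration) is kept:

   * ``zip`` — zero-inflated Poisson with a *latent* intent component:
     ``Z ~ Bernoulli(sigmoid(g·w_b))``, ``duration = Z * Poisson(exp(g·w_n))``,
     fit by maximum likelihood;
   * ``hurdle_sqrt`` — observed Bernoulli "brushed or not" component
     (logistic regression of ``duration > 0`` on g) plus a linear model of
     ``sqrt(duration)`` on g over the nonzero sessions;
   * ``hurdle_log`` — same, with a log transform.

2. **Imputed treatment effects** — an action shifts both linear predictors
   by nonnegative amounts ``delta_b`` (Bernoulli component) and ``delta_n``
   (nonzero component). The population-level sizes are the average, over
   users and non-intercept features, of the absolute fitted weights — the
   heuristic that action effects should be on the order of baseline feature
   effects. Heterogeneous (per-user) sizes are drawn from a normal centred
   at the population sizes with variance equal to the across-user empirical
   variance of per-user mean absolute weights, floored at zero.

Crossing {stationary, nonstationary base} x {population, per-user effects}
yields the four named environment variants (S_Pop, NS_Pop, S_Het, NS_Het).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln

log = logging.getLogger(__name__)

__all__ = [
    "MODEL_CLASSES",
    "VARIANT_NAMES",
    "UserBaseModel",
    "EffectSpec",
    "EnvironmentVariant",
    "FitReport",
    "FitError",
    "build_features",
    "features_from_records",
    "fit_user_model",
    "compute_rmse",
    "select_model",
    "validate_fit",
    "impute_population_effect",
    "impute_heterogeneous_effects",
    "sample_reward",
    "simulate_user_records",
    "build_environment",
    "ModelStack",
    "stack_models",
    "sample_rewards_stacked",
    "observed_reward_variance",
]

#: fixed candidate order; also the tie-break order for model selection
MODEL_CLASSES = ("zip", "hurdle_sqrt", "hurdle_log")

#: variant name -> (base, effect scope)
VARIANT_NAMES = {
    "S_Pop": ("stationary", "population"),
    "NS_Pop": ("nonstationary", "population"),
    "S_Het": ("stationary", "per_user"),
    "NS_Het": ("nonstationary", "per_user"),
}

REWARD_CAP = 180  # seconds; rewards are min(duration, 180)
_LIN_MAX = 8.0  # cap on nonzero-component linear predictors (exp scale)


class FitError(RuntimeError):
    """A base-model fit failed to converge."""


# ---------------------------------------------------------------------------
# features


def _weekend(day) -> np.ndarray:
    """Weekend indicator under the day-1-is-Monday convention."""
    m = np.asarray(day) % 7
    return ((m == 6) | (m == 0)).astype(float)


def build_features(
    history: Mapping[tuple[int, int], float] | None,
    day: int,
    session: int,
    base: str = "stationary",
    study_length: int = 70,
) -> np.ndarray:
    """Environment feature vector g for one decision.

    ``[1, time_of_day, prev_day_brushing, weekend]`` plus, for nonstationary
    bases, ``day_in_study``. ``history`` maps (day, session) to the observed
    reward (truncated duration); ``prev_day_brushing`` is the sum of the
    previous day's two rewards scaled into [0, 1] by 360. Missing history
    defaults to 0 with a logged warning.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    prev = 0.0
    if day > 1:
        h = history or {}
        missing = [(day - 1, s) for s in (0, 1) if (day - 1, s) not in h]
        if missing and history is not None:
            log.warning("missing history for %s; treating as 0", missing)
        prev = sum(min(float(h.get((day - 1, s), 0.0)), REWARD_CAP) for s in (0, 1))
    g = [1.0, float(session), prev / 360.0, float(_weekend(day))]
    if base == "nonstationary":
        g.append(day / study_length)
    elif base != "stationary":
        raise ValueError(f"unknown base {base!r}")
    return np.asarray(g, dtype=float)


def features_from_records(
    records: pd.DataFrame, base: str = "stationary", study_length: int | None = None
) -> np.ndarray:
    """Design matrix for one user's full record table (sorted by day, session).

    Previous-day brushing is computed from the user's own observed rewards
    (durations truncated at 180); day 1 gets 0.
    """
    rec = records.sort_values(["day", "session"]).reset_index(drop=True)
    days = rec["day"].to_numpy()
    if study_length is None:
        study_length = int(days.max())
    reward_by_day = (
        rec.assign(r=np.minimum(rec["duration"], REWARD_CAP))
        .groupby("day")["r"]
        .sum()
    )
    prev = reward_by_day.reindex(days - 1).fillna(0.0).to_numpy() / 360.0
    cols = [
        np.ones(len(rec)),
        rec["session"].to_numpy(dtype=float),
        prev,
        _weekend(days),
    ]
    if base == "nonstationary":
        cols.append(days / study_length)
    elif base != "stationary":
        raise ValueError(f"unknown base {base!r}")
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# base models


@dataclass
class UserBaseModel:
    """A fitted per-user generative model of brushing duration (no action).

    ``w_b`` are the Bernoulli-component weights on g, ``w_n`` the
    nonzero-component weights; ``sigma_n`` is the residual sd on the
    transformed scale (hurdle classes only). ``degenerate`` flags users whose
    data could not identify both components (e.g. all-zero users).
    """

    user_id: int
    model_class: str
    w_b: np.ndarray
    w_n: np.ndarray
    sigma_n: float | None
    rmse: float
    base: str = "stationary"
    study_length: int = 28
    degenerate: bool = False

    def __post_init__(self):
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.model_class!r}")
        self.w_b = np.asarray(self.w_b, dtype=float)
        self.w_n = np.asarray(self.w_n, dtype=float)
        if (self.sigma_n is None) != (self.model_class == "zip"):
            raise ValueError("sigma_n must be present iff the class is a hurdle class")

    @property
    def d_env(self) -> int:
        return len(self.w_b)

    def expected_duration(self, G: np.ndarray) -> np.ndarray:
        """E[duration | g] per row of G (used for RMSE)."""
        G = np.atleast_2d(G)
        p = expit(G @ self.w_b)
        lin = np.minimum(G @ self.w_n, _LIN_MAX)
        if self.model_class == "zip":
            return p * np.exp(lin)
        if self.model_class == "hurdle_sqrt":
            return p * (lin**2 + self.sigma_n**2)
        # lognormal mean correction
        return p * np.exp(lin + self.sigma_n**2 / 2.0)

    def to_dict(self) -> dict:
        return {
            "user_id": self.user_id,
            "model_class": self.model_class,
            "w_b": self.w_b.tolist(),
            "w_n": self.w_n.tolist(),
            "sigma_n": self.sigma_n,
            "rmse": self.rmse,
            "base": self.base,
            "study_length": self.study_length,
            "degenerate": self.degenerate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UserBaseModel":
        return cls(**d)


def _fit_logistic(G: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Logistic regression of z on G; tiny-ridge Newton fallback on failure."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(z.astype(float), G).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(res.params)):
                return np.asarray(res.params, dtype=float)
        except Exception:  # separation / singular designs
            pass
    # penalized fallback keeps the fit finite under (quasi-)separation
    lam = 1e-3

    def nll(w):
        lin = G @ w
        val = np.sum(np.logaddexp(0, lin) - z * lin) + 0.5 * lam * w @ w
        grad = G.T @ (expit(lin) - z) + lam * w
        return val, grad

    res = minimize(nll, np.zeros(G.shape[1]), jac=True, method="L-BFGS-B")
    return np.asarray(res.x, dtype=float)


def _zip_nll_grad(theta: np.ndarray, G: np.ndarray, y: np.ndarray):
    """Negative log-likelihood and gradient of the latent-intent ZIP model.

    P(y=0 | g) = (1-p) + p e^{-lam},  P(y=k>0 | g) = p Pois(k; lam)
    with p = sigmoid(g·w_b), lam = exp(g·w_n).
    """
    d = G.shape[1]
    wb, wn = theta[:d], theta[d:]
    a = G @ wb
    b = np.clip(G @ wn, -30.0, 30.0)
    p = expit(a)
    lam = np.exp(b)
    zero = y == 0

    ll = np.empty_like(a)
    # y>0: log p + y b - lam - log(y!)
    ll[~zero] = (
        np.log(np.maximum(p[~zero], 1e-300))
        + y[~zero] * b[~zero]
        - lam[~zero]
        - gammaln(y[~zero] + 1.0)
    )
    L0 = (1.0 - p[zero]) + p[zero] * np.exp(-lam[zero])
    L0 = np.maximum(L0, 1e-300)
    ll[zero] = np.log(L0)

    # gradients wrt linear predictors
    da = np.empty_like(a)
    db = np.empty_like(a)
    da[~zero] = 1.0 - p[~zero]
    db[~zero] = y[~zero] - lam[~zero]
    pq = p[zero] * (1.0 - p[zero])
    e = np.exp(-lam[zero])
    da[zero] = pq * (e - 1.0) / L0
    db[zero] = -p[zero] * lam[zero] * e / L0

    grad = np.concatenate([-(G.T @ da), -(G.T @ db)])
    return -np.sum(ll), grad


def _fit_zip_mle(
    G: np.ndarray, y: np.ndarray, seed: int, n_restarts: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Latent-intent ZIP maximum likelihood with jittered restarts."""
    d = G.shape[1]
    rng = np.random.default_rng(seed)
    nz = y > 0
    # data-informed start: intercepts at the marginal rates
    start = np.zeros(2 * d)
    frac = np.clip(nz.mean(), 0.05, 0.95)
    start[0] = np.log(frac / (1 - frac))
    start[d] = np.log(max(y[nz].mean(), 1.0)) if nz.any() else 0.0
    starts = [start] + [
        start + 0.1 * rng.standard_normal(2 * d) for _ in range(n_restarts - 1)
    ]
    best = None
    for x0 in starts:
        res = minimize(
            _zip_nll_grad,
            x0,
            args=(G, y),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("zip maximum-likelihood fit failed to converge")
    return best.x[:d].copy(), best.x[d:].copy()


def fit_user_model(
    records: pd.DataFrame,
    model_class: str,
    base: str = "stationary",
    study_length: int | None = None,
    seed: int = 0,
) -> UserBaseModel:
    """Fit one model class to one user's sessions.

    Users without at least two zero and two nonzero sessions are not
    identifiable for both components; they get a degenerate model (Bernoulli
    component saturated toward the observed all-zero / all-nonzero behavior)
    with ``degenerate=True``.
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}")
    rec = records.sort_values(["day", "session"]).reset_index(drop=True)
    if study_length is None:
        study_length = int(rec["day"].max())
    user_id = int(rec["user_id"].iloc[0]) if "user_id" in rec else -1
    G = features_from_records(rec, base=base, study_length=study_length)
    y = rec["duration"].to_numpy(dtype=float)
    d = G.shape[1]
    nz = y > 0
    n_nonzero, n_zero = int(nz.sum()), int((~nz).sum())
    degenerate = n_nonzero < 2 or n_zero < 2

    sigma_n: float | None = None
    if degenerate:
        # saturate the Bernoulli component toward the observed behavior
        w_b = np.zeros(d)
        w_b[0] = -8.0 if n_nonzero < 2 else 8.0
        w_n = np.zeros(d)
        if n_nonzero >= 1:
            if model_class == "zip":
                w_n[0] = np.log(max(y[nz].mean(), 1.0))
            elif model_class == "hurdle_sqrt":
                w_n[0] = np.sqrt(y[nz]).mean()
            else:
                w_n[0] = np.log(np.maximum(y[nz], 1.0)).mean()
        if model_class != "zip":
            resid_sd = 0.0
            if n_nonzero >= 2:
                t = np.sqrt(y[nz]) if model_class == "hurdle_sqrt" else np.log(y[nz])
                resid_sd = float(np.std(t, ddof=1))
            sigma_n = max(resid_sd, 1e-6)
        model = UserBaseModel(
            user_id, model_class, w_b, w_n, sigma_n, np.nan, base, study_length, True
        )
    elif model_class == "zip":
        w_b, w_n = _fit_zip_mle(G, y, seed=seed)
        model = UserBaseModel(
            user_id, "zip", w_b, w_n, None, np.nan, base, study_length
        )
    else:
        w_b = _fit_logistic(G, nz.astype(float))
        t = np.sqrt(y[nz]) if model_class == "hurdle_sqrt" else np.log(y[nz])
        Gn = G[nz]
        w_n, *_ = np.linalg.lstsq(Gn, t, rcond=None)
        resid = t - Gn @ w_n
        dof = max(n_nonzero - d, 1)
        sigma_n = float(np.sqrt(resid @ resid / dof))
        model = UserBaseModel(
            user_id, model_class, w_b, w_n, max(sigma_n, 1e-6), np.nan, base,
            study_length,
        )
    model.rmse = compute_rmse(model, rec)
    return model


def compute_rmse(model: UserBaseModel, records: pd.DataFrame) -> float:
    """RMSE between observed durations and the model's expected duration."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    rec = records.sort_values(["day", "session"]).reset_index(drop=True)
    G = features_from_records(rec, base=model.base, study_length=model.study_length)
    y = rec["duration"].to_numpy(dtype=float)
    yhat = model.expected_duration(G)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def select_model(candidates: Sequence[UserBaseModel]) -> UserBaseModel:
    """Pick the candidate with the lowest RMSE.

    Non-finite RMSEs are excluded with a warning; ties go to the earlier
    class in the fixed order zip > hurdle_sqrt > hurdle_log.
    """
    if len(candidates) != 3:
        raise ValueError("select_model expects exactly three candidates")
    by_class = {m.model_class: m for m in candidates}
    if set(by_class) != set(MODEL_CLASSES):
        raise ValueError("candidates must cover the three model classes exactly once")
    ordered = [by_class[c] for c in MODEL_CLASSES]
    finite = [m for m in ordered if np.isfinite(m.rmse)]
    if not finite:
        raise ValueError("all candidate RMSEs are non-finite")
    if len(finite) < 3:
        dropped = [m.model_class for m in ordered if not np.isfinite(m.rmse)]
        log.warning("excluding candidates with non-finite RMSE: %s", dropped)
    best = min(finite, key=lambda m: m.rmse)
    return best


# ---------------------------------------------------------------------------
# treatment effects


@dataclass
class EffectSpec:
    """Imputed treatment effects: intercept shifts on both linear predictors.

    ``scope='population'`` applies (delta_b, delta_n) to every user;
    ``scope='per_user'`` looks effects up in ``per_user_map``.
    """

    delta_b: float
    delta_n: float
    scope: str = "population"
    per_user_map: dict[int, tuple[float, float]] | None = None

    def __post_init__(self):
        if self.scope not in ("population", "per_user"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "per_user" and not self.per_user_map:
            raise ValueError("per_user scope requires per_user_map")

    def effect_for(self, user_id: int) -> tuple[float, float]:
        if self.scope == "population":
            return (self.delta_b, self.delta_n)
        if user_id not in self.per_user_map:
            raise KeyError(f"no imputed effect for user {user_id}")
        return self.per_user_map[user_id]

    def to_dict(self) -> dict:
        return {
            "delta_b": self.delta_b,
            "delta_n": self.delta_n,
            "scope": self.scope,
            "per_user_map": {str(k): list(v) for k, v in self.per_user_map.items()}
            if self.per_user_map
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        pum = d.get("per_user_map")
        if pum is not None:
            pum = {int(k): tuple(v) for k, v in pum.items()}
        return cls(d["delta_b"], d["delta_n"], d["scope"], pum)


def _mean_abs_noint(w: np.ndarray) -> float:
    if len(w) < 2:
        raise ValueError("need at least one non-intercept weight")
    return float(np.mean(np.abs(w[1:])))


def impute_population_effect(
    user_models: Sequence[UserBaseModel],
) -> tuple[float, float]:
    """Average absolute non-intercept weight, over users and features,
    separately for the Bernoulli and nonzero components."""
    if not user_models:
        raise ValueError("need at least one user model")
    delta_b = float(np.mean([_mean_abs_noint(m.w_b) for m in user_models]))
    delta_n = float(np.mean([_mean_abs_noint(m.w_n) for m in user_models]))
    return delta_b, delta_n


def impute_heterogeneous_effects(
    user_models: Sequence[UserBaseModel],
    population_effect: tuple[float, float],
    seed: int,
    floor_at_zero: bool = True,
) -> EffectSpec:
    """Per-user effects drawn from Normal(population, across-user variance).

    The per-component variance is the across-user empirical (sample) variance
    of each user's mean absolute non-intercept weight. Draws are floored at 0
    by default so that "treatment" never hurts by construction.
    """
    if len(user_models) < 2:
        raise ValueError("need at least two user models to estimate a variance")
    mb = np.array([_mean_abs_noint(m.w_b) for m in user_models])
    mn = np.array([_mean_abs_noint(m.w_n) for m in user_models])
    sd_b = float(np.std(mb, ddof=1))
    sd_n = float(np.std(mn, ddof=1))
    pop_b, pop_n = population_effect
    rng = np.random.default_rng(seed)
    per_user: dict[int, tuple[float, float]] = {}
    for m in sorted(user_models, key=lambda m: m.user_id):
        db = rng.normal(pop_b, sd_b)
        dn = rng.normal(pop_n, sd_n)
        if floor_at_zero:
            db, dn = max(db, 0.0), max(dn, 0.0)
        per_user[m.user_id] = (db, dn)
    return EffectSpec(pop_b, pop_n, scope="per_user", per_user_map=per_user)


# ---------------------------------------------------------------------------
# reward sampling


def _draw_durations(
    model_class: str,
    p: np.ndarray,
    lin_n: np.ndarray,
    sigma: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized duration draws given component linear-predictor values."""
    z = rng.random(p.shape) < p
    if model_class == "zip":
        lam = np.exp(np.minimum(lin_n, _LIN_MAX))
        d = rng.poisson(lam)
    else:
        x = rng.normal(lin_n, sigma)
        if model_class == "hurdle_sqrt":
            d = np.rint(x**2)
        else:
            d = np.rint(np.exp(np.minimum(x, _LIN_MAX)))
    return np.where(z, np.maximum(d, 0), 0).astype(np.int64)


def sample_reward(
    model: UserBaseModel,
    g: np.ndarray,
    action: int,
    effects: EffectSpec | None,
    user_id: int | None = None,
    rng: np.random.Generator | None = None,
) -> int:
    """Draw one truncated reward min(duration, 180) for context g and action."""
    if action not in (0, 1):
        raise ValueError("action must be 0 or 1")
    g = np.asarray(g, dtype=float)
    if len(g) != model.d_env:
        raise ValueError(f"feature length {len(g)} != model d_env {model.d_env}")
    if rng is None:
        rng = np.random.default_rng()
    db = dn = 0.0
    if effects is not None and action == 1:
        db, dn = effects.effect_for(model.user_id if user_id is None else user_id)
    p = expit(g @ model.w_b + action * db)
    lin_n = g @ model.w_n + action * dn
    d = _draw_durations(
        model.model_class,
        np.asarray([p]),
        np.asarray([lin_n]),
        model.sigma_n if model.sigma_n is not None else 0.0,
        rng,
    )[0]
    return int(min(d, REWARD_CAP))


@dataclass
class ModelStack:
    """Per-user model parameters stacked into arrays for vectorized sampling."""

    classes: np.ndarray  # (n,) index into MODEL_CLASSES
    W_b: np.ndarray  # (n, d_env)
    W_n: np.ndarray  # (n, d_env)
    sigma: np.ndarray  # (n,)
    user_ids: np.ndarray  # (n,) pool user id of each entry

    @property
    def n(self) -> int:
        return len(self.classes)

    @property
    def d_env(self) -> int:
        return self.W_b.shape[1]


def stack_models(models: Sequence[UserBaseModel]) -> ModelStack:
    d = models[0].d_env
    if any(m.d_env != d for m in models):
        raise ValueError("inconsistent model dimensions")
    return ModelStack(
        classes=np.array([MODEL_CLASSES.index(m.model_class) for m in models]),
        W_b=np.stack([m.w_b for m in models]),
        W_n=np.stack([m.w_n for m in models]),
        sigma=np.array(
            [m.sigma_n if m.sigma_n is not None else 0.0 for m in models]
        ),
        user_ids=np.array([m.user_id for m in models]),
    )


def sample_rewards_stacked(
    stack: ModelStack,
    G: np.ndarray,
    actions: np.ndarray,
    delta_b: np.ndarray,
    delta_n: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw one truncated reward per row: row i uses stacked model i, context
    G[i], action actions[i] and that model's imputed effects (delta arrays)."""
    a = actions.astype(float)
    p = expit(np.einsum("ij,ij->i", G, stack.W_b) + a * delta_b)
    lin = np.einsum("ij,ij->i", G, stack.W_n) + a * delta_n
    out = np.zeros(stack.n, dtype=np.int64)
    for ci, cname in enumerate(MODEL_CLASSES):
        m = stack.classes == ci
        if not m.any():
            continue
        out[m] = _draw_durations(cname, p[m], lin[m], stack.sigma[m], rng)
    return np.minimum(out, REWARD_CAP)


def simulate_user_records(
    model: UserBaseModel,
    n_days: int,
    rng: np.random.Generator,
    user_id: int = 0,
) -> pd.DataFrame:
    """Roll a model forward sequentially (no action) to a full record table.

    Unlike :func:`validate_fit`, which conditions on an observed feature
    sequence, this generates the previous-day-brushing feature from the
    model's own simulated rewards, so the output is a draw from the model's
    full joint distribution over a study. Used for parameter-recovery checks
    where the model is the oracle.
    """
    rows = []
    prev = 0.0
    sig = model.sigma_n if model.sigma_n is not None else 0.0
    for day in range(1, n_days + 1):
        day_rewards = 0.0
        for session in (0, 1):
            g = [1.0, float(session), prev, float(_weekend(day))]
            if model.base == "nonstationary":
                g.append(day / model.study_length)
            g = np.asarray(g)
            p = expit(g @ model.w_b)
            lin = g @ model.w_n
            d = _draw_durations(
                model.model_class, np.atleast_1d(p), np.atleast_1d(lin), sig, rng
            )[0]
            rows.append((user_id, day, session, int(d)))
            day_rewards += min(int(d), REWARD_CAP)
        prev = day_rewards / 360.0
    return pd.DataFrame(rows, columns=["user_id", "day", "session", "duration"])


# ---------------------------------------------------------------------------
# fit validation


@dataclass(frozen=True)
class FitReport:
    """Simulated-vs-observed fit-check statistics for one user's model."""

    zero_fraction_sim: float
    zero_fraction_obs: float
    mean_sim: float
    mean_obs: float
    between_var_sim: float
    between_var_obs: float
    within_var_sim: float
    within_var_obs: float


def validate_fit(
    model: UserBaseModel, records: pd.DataFrame, n_sim: int, seed: int
) -> FitReport:
    """Posterior-predictive-style check: simulate ``n_sim`` replicates of the
    user's session sequence from the fitted model (no action) and compare
    zero fraction, mean nonzero duration and within-user variance against the
    observed records. Between-user variance needs a pool of users and is
    reported as NaN for a single-user check."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rec = records.sort_values(["day", "session"]).reset_index(drop=True)
    G = features_from_records(rec, base=model.base, study_length=model.study_length)
    y = rec["duration"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    p = expit(G @ model.w_b)
    lin = G @ model.w_n
    sig = model.sigma_n if model.sigma_n is not None else 0.0
    zf, mz, wv = [], [], []
    for _ in range(n_sim):
        d = _draw_durations(model.model_class, p, lin, sig, rng).astype(float)
        zf.append(np.mean(d == 0))
        mz.append(d[d > 0].mean() if (d > 0).any() else 0.0)
        wv.append(np.var(d, ddof=1) if len(d) > 1 else 0.0)
    return FitReport(
        zero_fraction_sim=float(np.mean(zf)),
        zero_fraction_obs=float(np.mean(y == 0)),
        mean_sim=float(np.mean(mz)),
        mean_obs=float(y[y > 0].mean()) if (y > 0).any() else 0.0,
        between_var_sim=float("nan"),
        between_var_obs=float("nan"),
        within_var_sim=float(np.mean(wv)),
        within_var_obs=float(np.var(y, ddof=1)) if len(y) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# environment assembly


@dataclass
class EnvironmentVariant:
    """A fully specified reward-generating environment."""

    name: str
    user_pool: list[UserBaseModel]
    base: str
    effects: EffectSpec
    study_length: int
    reward_variance: float
    seed: int

    def __post_init__(self):
        if self.name not in VARIANT_NAMES:
            raise ValueError(f"unknown variant name {self.name!r}")
        base, scope = VARIANT_NAMES[self.name]
        if base != self.base or scope != self.effects.scope:
            raise ValueError(
                f"variant {self.name} requires base={base}, scope={scope}"
            )
        if not self.user_pool:
            raise ValueError("user_pool must be non-empty")

    @property
    def d_env(self) -> int:
        return self.user_pool[0].d_env

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "base": self.base,
            "study_length": self.study_length,
            "reward_variance": self.reward_variance,
            "seed": self.seed,
            "effects": self.effects.to_dict(),
            "user_pool": [m.to_dict() for m in self.user_pool],
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentVariant":
        return cls(
            name=d["name"],
            user_pool=[UserBaseModel.from_dict(m) for m in d["user_pool"]],
            base=d["base"],
            effects=EffectSpec.from_dict(d["effects"]),
            study_length=d["study_length"],
            reward_variance=d["reward_variance"],
            seed=d["seed"],
        )

    @classmethod
    def from_json(cls, path) -> "EnvironmentVariant":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def observed_reward_variance(records: pd.DataFrame) -> float:
    """Sample variance of truncated rewards min(duration, 180) in the data;
    used as the fixed reward-noise variance eta^2 of the linear bandit."""
    r = np.minimum(records["duration"].to_numpy(dtype=float), REWARD_CAP)
    return float(np.var(r, ddof=1))


def build_environment(
    records: pd.DataFrame, variant_name: str, seed: int
) -> EnvironmentVariant:
    """Fit all three classes per user, select per-user by RMSE, impute the
    variant's effects, and assemble the environment."""
    if variant_name not in VARIANT_NAMES:
        raise ValueError(f"unknown variant name {variant_name!r}")
    base, scope = VARIANT_NAMES[variant_name]
    user_ids = sorted(records["user_id"].unique())
    if len(user_ids) < 2:
        raise ValueError("need at least two users to build an environment")
    study_length = int(records["day"].max())
    root = np.random.SeedSequence(seed)
    fit_seeds = root.generate_state(len(user_ids))
    pool: list[UserBaseModel] = []
    for i, uid in enumerate(user_ids):
        rec_u = records[records["user_id"] == uid]
        fits = [
            fit_user_model(
                rec_u, c, base=base, study_length=study_length,
                seed=int(fit_seeds[i] >> 1),
            )
            for c in MODEL_CLASSES
        ]
        pool.append(select_model(fits))
    pop = impute_population_effect(pool)
    if scope == "population":
        effects = EffectSpec(pop[0], pop[1], scope="population")
    else:
        het_seed = int(root.generate_state(len(user_ids) + 1)[-1] >> 1)
        effects = impute_heterogeneous_effects(pool, pop, seed=het_seed)
    return EnvironmentVariant(
        name=variant_name,
        user_pool=pool,
        base=base,
        effects=effects,
        study_length=study_length,
        reward_variance=observed_reward_variance(records),
        seed=seed,
    )
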