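"""Posterior-sampling contextual-bandit candidates.

Two reward models drive Thompson sampling over the binary "send an
engagement message" action, both with mean-zero Gaussian priors (variance
``prior_scale`` per coordinate, the uninformative default):

* **BLR with action centering** — Bayesian linear regression
  ``R = f·alpha0 + pi f·alpha1 + (a - pi) f·beta + eps``, ``eps ~ N(0, eta^2)``
  where ``pi`` is the logged selection probability. Centering the action makes
  the advantage term ``f·beta`` estimable even when the baseline part of the
  model is wrong. The posterior is conjugate Gaussian (closed form), and the
  Thompson probability of sending P(f·beta > 0) is the analytic normal tail
  Phi(m/s) — equivalent in distribution to literally sampling beta. ``eta^2``
  is a fixed hyperparameter, set from the observed reward variance in the
  data the environment was built from.

* **ZIP reward model** — zero-inflated Poisson with latent intent:
  P(brush) = sigmoid(f·w_b + a f·delta_b), duration | intent ~
  Poisson(exp(f·w_n + a f·delta_n)). The posterior has no closed form and is
  approximated by a Laplace approximation at the penalized MAP; Thompson
  probabilities are Monte Carlo estimates of P(E[R|f,a=1] > E[R|f,a=0])
  under parameter draws from that Gaussian approximation.

All emitted selection probabilities are clipped into [0.35, 0.75] so that the
logged data retains enough exploration for post-study causal and off-policy
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, ndtr

__all__ = [
    "PROB_CLIP",
    "HistoryBatch",
    "BLRPosterior",
    "ZIPPriorConfig",
    "ZIPPosterior",
    "Decision",
    "blr_prior",
    "blr_update",
    "blr_treatment_prob",
    "zip_update",
    "zip_treatment_prob",
    "zip_draw_params",
    "zip_treatment_probs_from_draws",
    "clip_prob",
    "select_action",
]

PROB_CLIP = (0.35, 0.75)
_LIN_MAX = 8.0


@dataclass
class HistoryBatch:
    """Pooled history H of (state features, logged probability, action,
    reward) rows used at update times."""

    f: np.ndarray  # (n, d_alg)
    prob: np.ndarray  # (n,)
    action: np.ndarray  # (n,)
    reward: np.ndarray  # (n,)

    def __post_init__(self):
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        self.prob = np.asarray(self.prob, dtype=float).ravel()
        self.action = np.asarray(self.action, dtype=float).ravel()
        self.reward = np.asarray(self.reward, dtype=float).ravel()
        n = len(self.f) if self.f.size else 0
        if not (len(self.prob) == len(self.action) == len(self.reward) == n):
            raise ValueError("inconsistent batch row counts")

    def __len__(self) -> int:
        return 0 if self.f.size == 0 else len(self.f)

    @classmethod
    def empty(cls, d_alg: int) -> "HistoryBatch":
        return cls(np.empty((0, d_alg)), np.empty(0), np.empty(0), np.empty(0))


# ---------------------------------------------------------------------------
# Bayesian linear regression with action centering


@dataclass
class BLRPosterior:
    """Gaussian posterior over (alpha0, alpha1, beta), stacked in that order."""

    mu: np.ndarray  # (3 d_alg,)
    Sigma: np.ndarray  # (3 d_alg, 3 d_alg)
    eta2: float
    d_alg: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.mu.shape != (3 * self.d_alg,):
            raise ValueError("mu must have length 3*d_alg")
        if self.Sigma.shape != (3 * self.d_alg, 3 * self.d_alg):
            raise ValueError("Sigma must be (3 d_alg) square")

    @property
    def mu_beta(self) -> np.ndarray:
        return self.mu[2 * self.d_alg :]

    @property
    def Sigma_beta(self) -> np.ndarray:
        return self.Sigma[2 * self.d_alg :, 2 * self.d_alg :]


def blr_prior(d_alg: int, eta2: float, prior_scale: float = 25.0) -> BLRPosterior:
    """Mean-zero Gaussian prior with variance ``prior_scale`` per coordinate."""
    if d_alg < 1:
        raise ValueError("d_alg must be >= 1")
    if eta2 <= 0 or prior_scale <= 0:
        raise ValueError("eta2 and prior_scale must be positive")
    k = 3 * d_alg
    return BLRPosterior(np.zeros(k), prior_scale * np.eye(k), float(eta2), d_alg)


def _design(batch: HistoryBatch) -> np.ndarray:
    f, pi, a = batch.f, batch.prob, batch.action
    return np.hstack([f, pi[:, None] * f, (a - pi)[:, None] * f])


def blr_update(prior: BLRPosterior, batch: HistoryBatch) -> BLRPosterior:
    """Conjugate Gaussian update on the action-centered design
    ``x = [f, pi f, (a - pi) f]``."""
    if len(batch) == 0:
        return BLRPosterior(prior.mu.copy(), prior.Sigma.copy(), prior.eta2, prior.d_alg)
    if batch.f.shape[1] != prior.d_alg:
        raise ValueError("batch feature dimension does not match the prior")
    X = _design(batch)
    prec_prior = np.linalg.inv(prior.Sigma)
    prec_post = prec_prior + X.T @ X / prior.eta2
    prec_post = (prec_post + prec_post.T) / 2.0
    Sigma_post = np.linalg.inv(prec_post)
    Sigma_post = (Sigma_post + Sigma_post.T) / 2.0
    mu_post = Sigma_post @ (prec_prior @ prior.mu + X.T @ batch.reward / prior.eta2)
    eig_min = float(np.linalg.eigvalsh(Sigma_post).min())
    if eig_min <= 0:
        Sigma_post = Sigma_post + (1e-10 - eig_min) * np.eye(len(mu_post))
        eig_min = float(np.linalg.eigvalsh(Sigma_post).min())
        if eig_min <= 0:
            raise FloatingPointError(
                f"posterior covariance not PD (min eigenvalue {eig_min:g})"
            )
    return BLRPosterior(mu_post, Sigma_post, prior.eta2, prior.d_alg)


def blr_treatment_prob(posterior: BLRPosterior, f: np.ndarray) -> float:
    """Analytic Thompson probability P(f·beta > 0) under the posterior."""
    f = np.asarray(f, dtype=float)
    m = float(f @ posterior.mu_beta)
    s2 = float(f @ posterior.Sigma_beta @ f)
    if s2 <= 0:
        return 1.0 if m > 0 else (0.0 if m < 0 else 0.5)
    return float(ndtr(m / np.sqrt(s2)))


def blr_treatment_probs(posterior: BLRPosterior, F: np.ndarray) -> np.ndarray:
    """Vectorized :func:`blr_treatment_prob` over rows of F."""
    F = np.atleast_2d(F)
    m = F @ posterior.mu_beta
    s2 = np.einsum("ij,jk,ik->i", F, posterior.Sigma_beta, F)
    out = np.where(m > 0, 1.0, np.where(m < 0, 0.0, 0.5))
    pos = s2 > 0
    out[pos] = ndtr(m[pos] / np.sqrt(s2[pos]))
    return out


# ---------------------------------------------------------------------------
# zero-inflated Poisson reward model, Laplace-approximated posterior


@dataclass(frozen=True)
class ZIPPriorConfig:
    """Prior for the ZIP bandit: theta ~ N(0, prior_scale I) over
    (w_b, delta_b, w_n, delta_n), each block of length d_alg."""

    d_alg: int = 4
    prior_scale: float = 25.0

    @property
    def dim(self) -> int:
        return 4 * self.d_alg


@dataclass
class ZIPPosterior:
    """Laplace approximation: N(map_estimate, laplace_cov)."""

    map_estimate: np.ndarray  # (4 d_alg,)
    laplace_cov: np.ndarray  # (4 d_alg, 4 d_alg)
    d_alg: int

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        d = self.d_alg
        t = self.map_estimate
        return t[:d], t[d : 2 * d], t[2 * d : 3 * d], t[3 * d :]


def _zip_bandit_nll_grad(
    theta: np.ndarray,
    Fb: np.ndarray,
    Fn: np.ndarray,
    y: np.ndarray,
    prior_scale: float,
):
    """Penalized negative log-likelihood (and gradient) of the latent-intent
    ZIP reward model; Fb/Fn are the per-component designs [f, a f]."""
    k = Fb.shape[1]
    wb, wn = theta[:k], theta[k:]
    a = Fb @ wb
    b = np.clip(Fn @ wn, -30.0, 30.0)
    p = expit(a)
    lam = np.exp(b)
    zero = y == 0

    ll = np.empty_like(a)
    ll[~zero] = (
        np.log(np.maximum(p[~zero], 1e-300))
        + y[~zero] * b[~zero]
        - lam[~zero]
        - gammaln(y[~zero] + 1.0)
    )
    L0 = np.maximum((1.0 - p[zero]) + p[zero] * np.exp(-lam[zero]), 1e-300)
    ll[zero] = np.log(L0)

    da = np.empty_like(a)
    db = np.empty_like(a)
    da[~zero] = 1.0 - p[~zero]
    db[~zero] = y[~zero] - lam[~zero]
    e = np.exp(-lam[zero])
    da[zero] = p[zero] * (1.0 - p[zero]) * (e - 1.0) / L0
    db[zero] = -p[zero] * lam[zero] * e / L0

    nll = -np.sum(ll) + 0.5 * theta @ theta / prior_scale
    grad = (
        np.concatenate([-(Fb.T @ da), -(Fn.T @ db)]) + theta / prior_scale
    )
    return nll, grad


def _zip_bandit_hessian(
    theta: np.ndarray,
    Fb: np.ndarray,
    Fn: np.ndarray,
    y: np.ndarray,
    prior_scale: float,
) -> np.ndarray:
    """Analytic Hessian of the penalized NLL at theta."""
    k = Fb.shape[1]
    wb, wn = theta[:k], theta[k:]
    p = expit(Fb @ wb)
    lam = np.exp(np.clip(Fn @ wn, -30.0, 30.0))
    zero = y == 0
    e = np.exp(-lam)
    L0 = np.maximum((1.0 - p) + p * e, 1e-300)
    s_a = np.where(zero, p * (1.0 - p) * (e - 1.0) / L0, 1.0 - p)
    s_b = np.where(zero, -p * lam * e / L0, y - lam)
    d_aa = np.where(zero, s_a * (1.0 - 2.0 * p) - s_a**2, -p * (1.0 - p))
    d_bb = np.where(zero, s_b * (1.0 - lam) - s_b**2, -lam)
    d_ab = np.where(zero, (1.0 - p) * s_b - s_a * s_b, 0.0)
    Haa = Fb.T @ ((-d_aa)[:, None] * Fb)
    Hbb = Fn.T @ ((-d_bb)[:, None] * Fn)
    Hab = Fb.T @ ((-d_ab)[:, None] * Fn)
    H = np.block([[Haa, Hab], [Hab.T, Hbb]])
    return H + np.eye(2 * k) / prior_scale


def _newton_map(
    x0: np.ndarray,
    Fb: np.ndarray,
    Fn: np.ndarray,
    y: np.ndarray,
    prior_scale: float,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, bool]:
    """Damped (ridge-stabilized, backtracking) Newton minimization of the
    penalized NLL. Returns (theta, value, converged)."""
    theta = np.asarray(x0, dtype=float).copy()
    args = (Fb, Fn, y, prior_scale)
    val, g = _zip_bandit_nll_grad(theta, *args)
    for _ in range(max_iter):
        H = _zip_bandit_hessian(theta, *args)
        tau = 0.0
        while True:
            try:
                step = np.linalg.solve(H + tau * np.eye(len(theta)), g)
                if np.all(np.isfinite(step)) and g @ step > 0:
                    break
            except np.linalg.LinAlgError:
                pass
            tau = max(2.0 * tau, 1e-6)
            if tau > 1e8:  # give up on this direction; steepest descent
                step = g / max(np.linalg.norm(g), 1.0)
                break
        t = 1.0
        slope = g @ step
        while t > 1e-10:
            cand = theta - t * step
            v2, g2 = _zip_bandit_nll_grad(cand, *args)
            if np.isfinite(v2) and v2 <= val - 1e-4 * t * slope:
                break
            t /= 2.0
        else:
            return theta, val, False
        improved = val - v2
        theta, val, g = cand, v2, g2
        if np.max(np.abs(g)) < 1e-6 or improved < 1e-9 * (1.0 + abs(val)):
            return theta, val, True
    return theta, val, False


def zip_update(
    prior_config: ZIPPriorConfig,
    batch: HistoryBatch,
    seed: int = 0,
    x0: np.ndarray | None = None,
    n_restarts: int = 3,
) -> ZIPPosterior:
    """Laplace-approximate posterior update for the ZIP reward model.

    MAP by L-BFGS on the penalized likelihood (restarts jittered from zero,
    seeded); covariance is the inverse Hessian at the MAP, ridge-repaired
    with a warning if not positive definite. ``x0`` warm-starts the search
    (e.g. from last week's MAP). An empty batch returns the prior itself.
    """
    d = prior_config.d_alg
    dim = prior_config.dim
    if len(batch) == 0:
        return ZIPPosterior(np.zeros(dim), prior_config.prior_scale * np.eye(dim), d)
    if batch.f.shape[1] != d:
        raise ValueError("batch feature dimension does not match prior_config")
    F = batch.f
    aF = batch.action[:, None] * F
    Fb = np.hstack([F, aF])
    y = batch.reward
    args = (Fb, Fb, y, prior_config.prior_scale)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float))
    starts.append(np.zeros(dim))
    while len(starts) < (1 if x0 is not None else 0) + n_restarts:
        starts.append(0.1 * rng.standard_normal(dim))

    best_x, best_val, any_ok = None, np.inf, False
    for i, s in enumerate(starts):
        xs, vs, ok = _newton_map(s, *args)
        any_ok = any_ok or ok
        if ok and vs < best_val - 1e-9:
            best_x, best_val = xs, vs
        if x0 is not None and i == 0 and ok:
            break  # warm start converged; skip cold restarts
    if best_x is None:
        # fall back to quasi-Newton before declaring failure
        res = minimize(
            _zip_bandit_nll_grad,
            starts[0],
            args=args,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-11, "gtol": 1e-6},
        )
        if not (res.success and np.all(np.isfinite(res.x))):
            raise RuntimeError("ZIP MAP update failed to converge")
        best_x = res.x
    H = _zip_bandit_hessian(best_x, *args)
    # the latent-intent likelihood is non-concave, so the Hessian at the
    # stopping point can be indefinite; floor its eigenvalues at the prior
    # precision so no direction of the Gaussian approximation is ever wider
    # than the prior
    w, V = np.linalg.eigh(H)
    floor = 1.0 / prior_config.prior_scale
    if float(w.min()) < floor:
        import logging

        logging.getLogger(__name__).warning(
            "ZIP Hessian min eigenvalue %.3g below prior precision %.3g; flooring",
            float(w.min()),
            floor,
        )
        w = np.maximum(w, floor)
    cov = (V / w) @ V.T
    cov = (cov + cov.T) / 2.0
    return ZIPPosterior(np.asarray(best_x, dtype=float).copy(), cov, d)


def zip_draw_params(
    posterior: ZIPPosterior, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw parameter vectors theta ~ N(map, cov); rows are draws."""
    cov = posterior.laplace_cov
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal((n_draws, len(posterior.map_estimate)))
    return posterior.map_estimate + z @ L.T


def _zip_means(draws: np.ndarray, f: np.ndarray, action: int) -> np.ndarray:
    """E[R | f, action, theta] for each draw (ZIP mean p * lambda)."""
    d = f.shape[-1]
    wb, db, wn, dn = (
        draws[:, :d],
        draws[:, d : 2 * d],
        draws[:, 2 * d : 3 * d],
        draws[:, 3 * d :],
    )
    lb = wb @ f + action * (db @ f)
    ln = np.minimum(wn @ f + action * (dn @ f), _LIN_MAX)
    return expit(lb) * np.exp(ln)


def zip_treatment_prob(
    posterior: ZIPPosterior, f: np.ndarray, n_draws: int = 1000, seed: int = 0
) -> float:
    """Monte Carlo Thompson probability P(E[R|f,1] > E[R|f,0]) under the
    Laplace posterior; exact ties count 1/2 (so a point mass at zero effect
    yields 0.5)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    f = np.asarray(f, dtype=float)
    rng = np.random.default_rng(seed)
    draws = zip_draw_params(posterior, n_draws, rng)
    m1 = _zip_means(draws, f, 1)
    m0 = _zip_means(draws, f, 0)
    return float(np.mean(m1 > m0) + 0.5 * np.mean(m1 == m0))


def zip_treatment_probs_from_draws(draws: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Vectorized Thompson probabilities from pre-drawn parameters.

    ``draws`` is (n_draws, 4 d_alg); F is (m, d_alg); returns (m,) raw
    probabilities with exact ties counted 1/2.
    """
    F = np.atleast_2d(F)
    d = F.shape[1]
    wb, db, wn, dn = (
        draws[:, :d],
        draws[:, d : 2 * d],
        draws[:, 2 * d : 3 * d],
        draws[:, 3 * d :],
    )
    # (m, n_draws) linear predictors
    lb0 = F @ wb.T
    lb1 = lb0 + F @ db.T
    ln0 = np.minimum(F @ wn.T, _LIN_MAX)
    ln1 = np.minimum(F @ (wn + dn).T, _LIN_MAX)
    m0 = expit(lb0) * np.exp(ln0)
    m1 = expit(lb1) * np.exp(ln1)
    return np.mean(m1 > m0, axis=1) + 0.5 * np.mean(m1 == m0, axis=1)


# ---------------------------------------------------------------------------
# action selection


@dataclass(frozen=True)
class Decision:
    """A logged decision: the clipped selection probability and the action."""

    prob: float
    action: int

    def __post_init__(self):
        lo, hi = PROB_CLIP
        if not lo <= self.prob <= hi:
            raise ValueError(f"prob {self.prob} outside clip interval {PROB_CLIP}")
        if self.action not in (0, 1):
            raise ValueError("action must be 0 or 1")


def clip_prob(p: float) -> float:
    """Clip a raw Thompson probability into [0.35, 0.75]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"raw probability {p} outside [0, 1]")
    lo, hi = PROB_CLIP
    return float(min(hi, max(lo, p)))


def select_action(p_clipped: float, rng: np.random.Generator) -> Decision:
    """Sample the action Bernoulli(p) and log both probability and action."""
    lo, hi = PROB_CLIP
    if not lo - 1e-12 <= p_clipped <= hi + 1e-12:
        raise ValueError(f"p_clipped {p_clipped} outside clip interval {PROB_CLIP}")
    p = float(min(hi, max(lo, p_clipped)))
    return Decision(prob=p, action=int(rng.random() < p))
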