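"""Effort-by-reward discounting model for the internal/external
motivation task.

The task offers physical effort (3-70 button presses) for monetary
reward ($0.25-$2.00). Effort and reward are min-max normalized to
[0, 1] against these printed task ranges (not per-subject ranges, for
cross-subject comparability). The psychometric model is a logistic
sigmoid in the net normalized value of an offer:

    p(accept | e, r) = 1 / (1 + exp(-(r - e - bias) / sigma))

``bias`` is literally a left-right translation of the curve along the
effort axis and indexes motivational tone (higher bias = fewer offers
accepted); ``sigma`` is the inverse steepness and indexes reward
sensitivity — small sigma yields near-binary accept/reject behavior.

In the internal condition subjects self-generate an effort level for
each reward; the likelihood is a logistic density with location
(r - bias) and scale sigma, truncated and renormalized to the
admissible normalized effort interval [0, 1].

Fitting is multi-start MAP over (bias, log sigma) with
weakly-informative priors, plus a Laplace approximation of the model
evidence for model comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "EFFORT_MIN",
    "EFFORT_MAX",
    "REWARD_MIN",
    "REWARD_MAX",
    "TaskDesign",
    "Priors",
    "DiscountFit",
    "normalize_effort",
    "normalize_reward",
    "accept_probability",
    "internal_choice_density",
    "fit_discounting",
    "znormalize",
    "zscore_fit_table",
]

EFFORT_MIN, EFFORT_MAX = 3.0, 70.0
REWARD_MIN, REWARD_MAX = 0.25, 2.00


def normalize_effort(presses) -> np.ndarray:
    return (np.asarray(presses, dtype=np.float64) - EFFORT_MIN) / (EFFORT_MAX - EFFORT_MIN)


def normalize_reward(usd) -> np.ndarray:
    return (np.asarray(usd, dtype=np.float64) - REWARD_MIN) / (REWARD_MAX - REWARD_MIN)


@dataclass(frozen=True)
class TaskDesign:
    """Factorial effort x reward design within the printed task ranges."""

    effort_levels: tuple = tuple(int(round(v)) for v in np.linspace(EFFORT_MIN, EFFORT_MAX, 8))
    reward_levels: tuple = tuple(np.round(np.linspace(REWARD_MIN, REWARD_MAX, 8), 4))
    trials_per_cell: int = 1
    conditions: tuple = ("internal", "external")
    work_fraction: float = 0.3

    def __post_init__(self):
        if len(self.effort_levels) < 2 or len(self.reward_levels) < 2:
            raise ParameterError("at least 2 levels per axis are required")
        if min(self.effort_levels) < EFFORT_MIN or max(self.effort_levels) > EFFORT_MAX:
            raise ParameterError(f"effort levels must lie in [{EFFORT_MIN}, {EFFORT_MAX}]")
        if min(self.reward_levels) < REWARD_MIN or max(self.reward_levels) > REWARD_MAX:
            raise ParameterError(f"reward levels must lie in [{REWARD_MIN}, {REWARD_MAX}]")
        if self.trials_per_cell < 1:
            raise ParameterError("trials_per_cell must be >= 1")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """All (effort, reward) pairs, repeated trials_per_cell times."""
        e, r = np.meshgrid(self.effort_levels, self.reward_levels, indexing="ij")
        e = np.repeat(e.ravel(), self.trials_per_cell)
        r = np.repeat(r.ravel(), self.trials_per_cell)
        return e.astype(np.float64), r.astype(np.float64)


@dataclass(frozen=True)
class Priors:
    """Weakly-informative MAP priors: bias ~ N(0,1), log sigma ~ N(log 0.3, 1)."""

    bias_mean: float = 0.0
    bias_sd: float = 1.0
    log_sigma_mean: float = float(np.log(0.3))
    log_sigma_sd: float = 1.0


@dataclass
class DiscountFit:
    """MAP fit of (bias, sigma) for one subject and condition."""

    condition: str
    bias: float
    sigma: float
    loglik: float
    converged: bool
    n_trials: int
    log_evidence: float = float("nan")
    bias_z: float = float("nan")
    sigma_z: float = float("nan")
    flags: list = field(default_factory=list)


def _check_sigma(sigma):
    if np.any(np.asarray(sigma) <= 0):
        raise ParameterError("sigma must be strictly positive")


def accept_probability(effort_presses, reward_usd, bias: float, sigma: float):
    """P(accept) for an external-condition offer.

    Strictly increasing in reward, decreasing in effort and in bias;
    sigma -> 0 approaches a step function at the indifference line
    r - e = bias.
    """
    _check_sigma(sigma)
    x = (normalize_reward(reward_usd) - normalize_effort(effort_presses) - bias) / sigma
    # keep the probability strictly inside (0, 1) even where expit
    # saturates in float64
    out = np.clip(expit(x), 5e-324, np.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)


def _logistic_logpdf(z):
    az = np.abs(z)
    return -az - 2.0 * np.log1p(np.exp(-az))


def _logistic_cdf(z):
    return expit(z)


def internal_choice_density(chosen_effort_presses, reward_usd, bias: float, sigma: float):
    """Density of a self-generated effort level (internal condition).

    Logistic density with location (r - bias) and scale sigma on the
    normalized effort axis, truncated/renormalized to [0, 1]. The
    density is with respect to normalized effort, so it integrates to 1
    over the admissible interval; its mode sits at the indifference
    point e = r - bias (when interior).
    """
    _check_sigma(sigma)
    e = normalize_effort(chosen_effort_presses)
    m = normalize_reward(reward_usd) - bias
    z = (e - m) / sigma
    mass = _logistic_cdf((1.0 - m) / sigma) - _logistic_cdf((0.0 - m) / sigma)
    mass = np.maximum(mass, 1e-300)
    dens = np.exp(_logistic_logpdf(z)) / sigma / mass
    dens = np.where((e < 0) | (e > 1), 0.0, dens)
    return dens if dens.ndim else float(dens)


def _external_loglik(e, r, accepted, bias, sigma):
    x = (r - e - bias) / sigma
    # log p = -softplus(-x), log(1-p) = -softplus(x)
    sp = np.logaddexp(0.0, -x)
    sn = np.logaddexp(0.0, x)
    return float(np.where(accepted, -sp, -sn).sum())


def _internal_loglik(e, r, bias, sigma):
    m = r - bias
    z = (e - m) / sigma
    mass = _logistic_cdf((1.0 - m) / sigma) - _logistic_cdf((0.0 - m) / sigma)
    return float((_logistic_logpdf(z) - np.log(sigma) - np.log(np.maximum(mass, 1e-300))).sum())


def _neg_log_posterior(theta, e, r, resp, condition, priors):
    bias, log_sigma = theta
    sigma = float(np.exp(np.clip(log_sigma, -12.0, 6.0)))
    if condition == "external":
        ll = _external_loglik(e, r, resp, bias, sigma)
    else:
        ll = _internal_loglik(e, r, bias, sigma)
    lp = (
        -0.5 * ((bias - priors.bias_mean) / priors.bias_sd) ** 2
        - 0.5 * ((log_sigma - priors.log_sigma_mean) / priors.log_sigma_sd) ** 2
    )
    return -(ll + lp)


def _laplace_evidence(fun, theta, h=1e-4):
    """log evidence under a 2-D Laplace approximation at the mode."""
    d = len(theta)
    H = np.zeros((d, d))
    f0 = fun(theta)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej) - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * h * h)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return float("nan")
    return float(-f0 + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet)


def fit_discounting(
    trials: pd.DataFrame,
    condition: str,
    priors: Priors = Priors(),
    n_starts: int = 8,
    seed: int = 0,
) -> DiscountFit:
    """MAP-fit (bias, sigma) to one subject's trials in one condition.

    External trials contribute Bernoulli accept/reject likelihoods;
    internal trials contribute truncated-logistic densities of the
    chosen effort. The best of ``n_starts`` quasi-Newton optimizations
    of the log posterior is returned, with a Laplace-approximate log
    evidence. All-accept / all-reject external data is fitted but
    flagged as boundary data (the bias estimate is then prior-driven).
    """
    if condition not in ("internal", "external"):
        raise ParameterError(f"unknown condition {condition!r}")
    sub = trials[trials["condition"] == condition]
    if len(sub) < 10:
        raise DegenerateInputError(f"need >= 10 trials in condition {condition!r}, got {len(sub)}")
    e = normalize_effort(sub["effort_presses"].to_numpy())
    r = normalize_reward(sub["reward_usd"].to_numpy())
    flags: list[str] = []
    if condition == "external":
        resp = sub["response"].to_numpy().astype(float) > 0.5
        if resp.all() or (~resp).all():
            flags.append("boundary_responses")
            warnings.warn("all responses identical; bias estimate is prior-driven", stacklevel=2)
    else:
        resp = None
        e = normalize_effort(sub["response"].to_numpy())  # chosen efforts

    fun = lambda th: _neg_log_posterior(th, e, r, resp, condition, priors)
    rng = np.random.default_rng(seed)
    starts = [np.array([priors.bias_mean, priors.log_sigma_mean])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.array(
                [
                    rng.normal(priors.bias_mean, priors.bias_sd),
                    rng.normal(priors.log_sigma_mean, priors.log_sigma_sd),
                ]
            )
        )
    best = None
    for th0 in starts:
        res = minimize(fun, th0, method="L-BFGS-B", options={"maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    bias, log_sigma = best.x
    sigma = float(np.exp(np.clip(log_sigma, -12.0, 6.0)))
    grad_ok = bool(np.linalg.norm(best.jac) < 1e-3 * (1 + abs(best.fun)))
    if condition == "external":
        ll = _external_loglik(e, r, resp, bias, sigma)
    else:
        ll = _internal_loglik(e, r, bias, sigma)
    return DiscountFit(
        condition=condition,
        bias=float(bias),
        sigma=sigma,
        loglik=ll,
        converged=bool(best.success) and grad_ok,
        n_trials=int(len(sub)),
        log_evidence=_laplace_evidence(fun, best.x),
        flags=flags,
    )


def znormalize(values) -> np.ndarray:
    """Z-score with the sample (ddof=1) standard deviation."""
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise DegenerateInputError("z-normalization needs >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero spread: z-scores undefined")
    return (x - x.mean()) / sd


def zscore_fit_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Add bias_z / sigma_z columns, z-scored within each condition."""
    out = fits.copy()
    out["bias_z"] = np.nan
    out["sigma_z"] = np.nan
    for cond, idx in out.groupby("condition").groups.items():
        out.loc[idx, "bias_z"] = znormalize(out.loc[idx, "bias"].to_numpy())
        out.loc[idx, "sigma_z"] = znormalize(out.loc[idx, "sigma"].to_numpy())
    return out
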