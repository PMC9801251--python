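"""Univariate Gaussian mixture fitting by expectation-maximization.

This is the classification engine of the pipeline: enhancement
intensities inside the analysis mask are modeled as a finite mixture of
Gaussians (CSF / white matter / neuromelanin-related tissue for k=3,
with a k=4 refinement inside the neuromelanin class). The EM fitter is
written here in full — responsibilities in the log domain, a variance
floor against collapse, a monotone log-likelihood trace, and best-of-n
restarts — so that its behavior is completely specified and auditable;
scikit-learn's mixture module serves only as an independent
cross-check in the test suite.

Initialization
--------------
The first start places component means at quantiles ``linspace(0, 1, k)``
of the data — including the minimum and maximum. Including the extremes
matters: the neuromelanin class can be under 1% of in-brain voxels, so
interior quantiles would seed every component inside the dominant
white-matter mode and EM would never reach the bright tail. Remaining
starts draw k distinct data points as means (seeded). All starts use
equal weights and the pooled sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DegeneracyError, ParameterError

__all__ = ["MixtureModel", "fit_gmm_em"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureModel:
    """A fitted k-component univariate Gaussian mixture.

    Components are sorted by ascending mean. ``loglik_trace`` is the
    total data log-likelihood after each EM iteration of the winning
    start.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: int = 0

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1]) if self.loglik_trace else float("nan")

    def component_log_density(self, x: np.ndarray) -> np.ndarray:
        """log( w_j * N(x | mu_j, var_j) ), shape (n, k)."""
        x = np.asarray(x, dtype=np.float64).ravel()[:, None]
        var = self.variances[None, :]
        out = (
            np.log(np.maximum(self.weights[None, :], 1e-300))
            - 0.5 * (_LOG2PI + np.log(var))
            - 0.5 * (x - self.means[None, :]) ** 2 / var
        )
        return out

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lg = self.component_log_density(x)
        return np.exp(lg - logsumexp(lg, axis=1, keepdims=True))

    def log_likelihood(self, x: np.ndarray) -> float:
        return float(logsumexp(self.component_log_density(x), axis=1).sum())


def _em_single(
    x: np.ndarray,
    means0: np.ndarray,
    var0: float,
    var_floor: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, int, bool]:
    k = means0.size
    n = x.size
    weights = np.full(k, 1.0 / k)
    means = means0.astype(np.float64).copy()
    variances = np.full(k, max(var0, var_floor))
    xcol = x[:, None]

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lg = (
            np.log(np.maximum(weights[None, :], 1e-300))
            - 0.5 * (_LOG2PI + np.log(variances[None, :]))
            - 0.5 * (xcol - means[None, :]) ** 2 / variances[None, :]
        )
        norm = logsumexp(lg, axis=1, keepdims=True)
        ll = float(norm.sum())
        resp = np.exp(lg - norm)

        nk = resp.sum(axis=0)
        safe = nk > 1e-12
        new_means = means.copy()
        new_vars = variances.copy()
        new_means[safe] = (resp[:, safe] * xcol).sum(axis=0) / nk[safe]
        sq = (xcol - new_means[None, :]) ** 2
        new_vars[safe] = (resp[:, safe] * sq[:, safe]).sum(axis=0) / nk[safe]
        weights = nk / n
        means = new_means
        variances = np.maximum(new_vars, var_floor)

        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break

    return weights, means, variances, trace, it, converged


def fit_gmm_em(
    values,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    var_floor_frac: float = 1e-10,
    init_means=None,
) -> MixtureModel:
    """Fit a k-component univariate Gaussian mixture by EM.

    Parameters
    ----------
    values
        1-D sample of intensities; must be finite, with at least k
        distinct values.
    k
        Number of mixture components.
    seed
        Seeds the random restarts (the first start is deterministic).
    n_init
        Number of EM starts; the run with the highest final
        log-likelihood wins.
    tol
        Relative log-likelihood change declaring convergence.
    max_iter
        Iteration cap per start.
    var_floor_frac
        Variance floor as a fraction of the pooled sample variance
        (guards against component collapse on repeated values).
    init_means
        Optional explicit initial means; if given, exactly one EM run
        starts there (used for reference-fitter comparisons).

    Returns
    -------
    MixtureModel
        Components sorted by ascending mean.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0 or not np.isfinite(x).all():
        raise ParameterError("input values must be a non-empty finite sample")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    uniq = np.unique(x)
    if uniq.size < k:
        raise DegeneracyError(f"k={k} exceeds the number of distinct values ({uniq.size})")

    sample_var = float(x.var())
    var_floor = max(var_floor_frac * sample_var, 1e-300)
    var0 = max(sample_var, var_floor)
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    if init_means is not None:
        starts.append(np.asarray(init_means, dtype=np.float64).ravel())
        if starts[0].size != k:
            raise ParameterError("init_means must have length k")
    else:
        q = np.quantile(x, np.linspace(0.0, 1.0, k)) if k > 1 else np.array([x.mean()])
        if np.unique(q).size < k:
            q = np.linspace(uniq[0], uniq[-1], k)
        starts.append(q)
        for _ in range(max(0, n_init - 1)):
            starts.append(rng.choice(uniq, size=k, replace=False).astype(np.float64))

    best = None
    for means0 in starts:
        run = _em_single(x, means0, var0, var_floor, tol, max_iter)
        if best is None or run[3][-1] > best[3][-1]:
            best = run

    weights, means, variances, trace, n_iter, converged = best
    order = np.argsort(means)
    return MixtureModel(
        k=k,
        weights=weights[order],
        means=means[order],
        variances=variances[order],
        loglik_trace=trace,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
    )
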