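"""Gamma-Poisson shrinkage (MGPS) prior fitting and posterior summaries.

The model: for each drug-event cell, the observed count a is Poisson with
mean lambda * E, where E is the expected count under independence and the
reporting-rate ratio lambda follows a two-component gamma mixture prior

    lambda ~ P * Gamma(alpha1, beta1) + (1 - P) * Gamma(alpha2, beta2)

(shape/rate parameterization).  Marginally a is then a mixture of negative
binomials, and the five prior parameters are fitted by maximum marginal
likelihood over all cells {(a_i, E_i)} of a scan via EM:

* E-step: posterior component responsibilities from the two negative
  binomial likelihoods.
* M-step: the mixture weight in closed form; each component's (shape, rate)
  by numerical maximization of its responsibility-weighted negative binomial
  log likelihood, warm-started at the current value so the observed-data log
  likelihood never decreases.

Given the fitted prior, the posterior of lambda for a cell is again a
two-component gamma mixture with components Gamma(alpha_k + a, beta_k + E)
and reweighted mixture probabilities.  EBGM is the posterior geometric mean
exp(E[ln lambda | a]); EBGM05 is the posterior 5th percentile, found by
root-bisection of the mixture CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from scipy.stats import gamma as gamma_dist

__all__ = ["MGPSPrior", "MGPSFit", "fit_prior", "posterior_ebgm"]

#: Conventional starting point for the EM search (skewed null component plus
#: a concentrated component near lambda = 0.5).
DEFAULT_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class MGPSPrior:
    """Two-component gamma mixture prior for the reporting-rate ratio."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not 0.0 < self.p < 1.0:
            raise ValueError("mixture weight p must lie in (0, 1)")

    def mean(self) -> float:
        """Prior mean of lambda."""
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2


@dataclass
class MGPSFit:
    """Result of the EM fit: the prior, the log-likelihood trace, and
    convergence status."""

    prior: MGPSPrior
    loglik_path: list[float]
    converged: bool
    n_iter: int

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1]


def _nb_loglik(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Per-cell log of the negative binomial marginal
    P(a | alpha, beta, E) = C(alpha+a-1, a) (beta/(beta+E))^alpha (E/(beta+E))^a
    valid for real alpha > 0."""
    log_ratio = np.log(beta) - np.log(beta + e)
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * log_ratio
        + a * (np.log(e) - np.log(beta + e))
    )


def _mixture_loglik(a: np.ndarray, e: np.ndarray, prior: MGPSPrior) -> float:
    l1 = _nb_loglik(a, e, prior.alpha1, prior.beta1) + math.log(prior.p)
    l2 = _nb_loglik(a, e, prior.alpha2, prior.beta2) + math.log(1.0 - prior.p)
    return float(np.logaddexp(l1, l2).sum())


def _responsibilities(a: np.ndarray, e: np.ndarray, prior: MGPSPrior) -> np.ndarray:
    l1 = _nb_loglik(a, e, prior.alpha1, prior.beta1) + math.log(prior.p)
    l2 = _nb_loglik(a, e, prior.alpha2, prior.beta2) + math.log(1.0 - prior.p)
    norm = np.logaddexp(l1, l2)
    return np.exp(l1 - norm)


def _maximize_component(
    a: np.ndarray, e: np.ndarray, w: np.ndarray, alpha0: float, beta0: float
) -> tuple[float, float]:
    """Maximize the w-weighted negative binomial log likelihood over
    (alpha, beta), warm-started at the current parameters."""

    def neg(theta: np.ndarray) -> float:
        alpha, beta = np.exp(theta)
        return -float(np.dot(w, _nb_loglik(a, e, alpha, beta)))

    x0 = np.log([alpha0, beta0])
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400})
    # EM guarantee: never accept a step that lowers the weighted likelihood
    if res.fun <= neg(x0):
        alpha, beta = np.exp(res.x)
        return float(alpha), float(beta)
    return alpha0, beta0


# weight bounds keep log(p) finite; a component is considered collapsed when
# p is driven onto a bound
_P_FLOOR = 1e-6


def _em(
    a: np.ndarray,
    e: np.ndarray,
    init: MGPSPrior,
    tol: float,
    max_iter: int,
) -> MGPSFit:
    prior = init
    path = [_mixture_loglik(a, e, prior)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = _responsibilities(a, e, prior)
        p = float(np.clip(z.mean(), _P_FLOOR, 1.0 - _P_FLOOR))
        a1, b1 = _maximize_component(a, e, z, prior.alpha1, prior.beta1)
        a2, b2 = _maximize_component(a, e, 1.0 - z, prior.alpha2, prior.beta2)
        prior = MGPSPrior(a1, b1, a2, b2, p)
        ll = _mixture_loglik(a, e, prior)
        path.append(ll)
        if abs(ll - path[-2]) <= tol * max(1.0, abs(ll)):
            converged = True
            break
    return MGPSFit(prior=prior, loglik_path=path, converged=converged, n_iter=it)


def fit_prior(
    counts,
    expected,
    init: tuple[float, float, float, float, float] = DEFAULT_INIT,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_restarts: int = 5,
    seed: int = 0,
) -> MGPSFit:
    """Fit the five-parameter mixture prior by EM on all cells of a scan.

    ``counts`` and ``expected`` are parallel sequences of a_i and E_i (cells
    with E_i <= 0 are dropped).  ``n_restarts`` additional EM runs start from
    multiplicatively jittered initial values (seeded); the run with the best
    final marginal log likelihood wins.  Convergence: relative log-likelihood
    change below ``tol``.
    """
    a = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if a.shape != e.shape:
        raise ValueError("counts and expected must have equal length")
    keep = e > 0
    a, e = a[keep], e[keep]
    if a.size < 2:
        raise ValueError("need at least 2 cells with positive expected count")
    if not np.any(a > 0):
        raise ValueError("degenerate input: every observed count is zero")

    rng = np.random.default_rng(seed)
    inits = [MGPSPrior(*init)]
    for _ in range(max(0, n_restarts - 1)):
        jitter = np.exp(rng.normal(0.0, 0.3, size=4))
        p0 = float(np.clip(init[4] * math.exp(rng.normal(0.0, 0.3)), 0.05, 0.95))
        inits.append(
            MGPSPrior(
                init[0] * jitter[0],
                init[1] * jitter[1],
                init[2] * jitter[2],
                init[3] * jitter[3],
                p0,
            )
        )
    best: MGPSFit | None = None
    for start in inits:
        fit = _em(a, e, start, tol=tol, max_iter=max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def posterior_ebgm(
    a: int | float,
    e: float,
    prior: MGPSPrior,
    q: float = 0.05,
    rtol: float = 1e-8,
) -> tuple[float, float]:
    """Posterior geometric mean and lower quantile of lambda for one cell.

    The posterior is P'(a) Gamma(alpha1 + a, beta1 + E) +
    (1 - P'(a)) Gamma(alpha2 + a, beta2 + E), with P'(a) the responsibility of
    component 1 given the observed count.  EBGM = exp(E[ln lambda | a]); the
    lower quantile is found by bisection of the mixture CDF to relative
    tolerance ``rtol``.
    """
    if e <= 0:
        raise ValueError("expected count must be positive")
    a_arr = np.asarray([float(a)])
    e_arr = np.asarray([float(e)])
    w1 = float(_responsibilities(a_arr, e_arr, prior)[0])
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    weights = np.array([w1, 1.0 - w1])

    mean_log = float(np.dot(weights, special.digamma(shapes) - np.log(rates)))
    ebgm_val = math.exp(mean_log)

    def cdf(x: float) -> float:
        return float(np.dot(weights, gamma_dist.cdf(x, shapes, scale=1.0 / rates)))

    lo = min(gamma_dist.ppf(q, shapes[0], scale=1.0 / rates[0]),
             gamma_dist.ppf(q, shapes[1], scale=1.0 / rates[1]))
    hi = max(gamma_dist.ppf(q, shapes[0], scale=1.0 / rates[0]),
             gamma_dist.ppf(q, shapes[1], scale=1.0 / rates[1]))
    if hi <= lo:
        return ebgm_val, float(lo)
    quantile = float(
        optimize.brentq(lambda x: cdf(x) - q, lo, hi, rtol=rtol, xtol=1e-300)
    )
    return ebgm_val, quantile
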