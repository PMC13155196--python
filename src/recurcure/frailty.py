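"""Frailty constructions for the joint mixture cure models.

Three subject-level frailty specifications are supported, each governed by a
single heterogeneity parameter ``alpha`` (> 0):

* **clog-log bivariate gamma** — draw ``x ~ Beta(alpha, alpha)`` and
  ``y ~ Gamma(shape 2*alpha, rate alpha)`` independently and set
  ``u1 = x*y`` (latency multiplier) and ``u2 = y/2`` (incidence multiplier).
  Beta-gamma algebra gives the marginals ``u1 ~ Gamma(alpha, alpha)`` and
  ``u2 ~ Gamma(2*alpha, 2*alpha)``, so both have mean 1 while
  ``Var(u1) = 1/alpha`` and ``Var(u2) = 1/(2*alpha)``.  The pair is
  supported on ``0 < u1 < 2*u2`` and the log-frailties
  ``omega1 = log(u1)``, ``omega2 = log(u2)`` are positively correlated,
  ``Corr = sqrt(trigamma(2*alpha)/trigamma(alpha))``.

* **logistic gamma x beta** — with ``a = 1/alpha`` draw
  ``u1 ~ Gamma(shape 2a, rate a)`` and ``u2 ~ Beta(a, a)`` independently and
  set ``omega1 = log(u1*u2)``, ``omega2 = logit(u2)``.  Then
  ``E[e^omega1] = 1`` (identifiability with the baseline hazard),
  ``E[omega2] = 0``, and ``Corr(omega1, omega2) = 1/sqrt(2) = 0.707`` for
  every ``alpha``.  By the same beta-gamma algebra ``u1*u2 ~ Gamma(a, a)``,
  so the marginal of ``omega1`` is log-gamma in closed form, and
  ``-omega2 | omega1`` is exactly log-Gamma(a, rate ``a*e^{omega1}``).

* **identical log-gamma** — a single shared ``u ~ Gamma(alpha, alpha)`` with
  ``omega = log(u)`` entering both model components.

All gamma distributions are parameterised by shape and *rate* (so
``Gamma(alpha, alpha)`` has mean 1).  All samplers take either an integer
seed or a ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, polygamma

__all__ = [
    "CloglogFrailtyPairs",
    "LogisticFrailtyPairs",
    "sample_cloglog_pairs",
    "sample_logistic_pairs",
    "sample_shared_frailty",
    "cloglog_joint_logdensity",
    "cloglog_log_frailty_correlation",
    "logistic_joint_logdensity",
    "logistic_log_frailty_correlation",
    "logistic_marginal_omega1_logdensity",
    "conditional_loggamma_logdensity",
    "shared_loggamma_logdensity",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"alpha must be a positive real, got {alpha!r}")
    return alpha


@dataclass(frozen=True)
class CloglogFrailtyPairs:
    """Arrays of (u1, u2) pairs from the bivariate-gamma construction."""

    u1: np.ndarray
    u2: np.ndarray

    @property
    def omega1(self) -> np.ndarray:
        return np.log(self.u1)

    @property
    def omega2(self) -> np.ndarray:
        return np.log(self.u2)

    @property
    def latency_multiplier(self) -> np.ndarray:
        """e^{omega1}, the hazard multiplier of the latency component."""
        return self.u1


@dataclass(frozen=True)
class LogisticFrailtyPairs:
    """Arrays of (u1, u2) pairs from the gamma x beta construction."""

    u1: np.ndarray
    u2: np.ndarray

    @property
    def omega1(self) -> np.ndarray:
        return np.log(self.u1 * self.u2)

    @property
    def omega2(self) -> np.ndarray:
        return np.log(self.u2) - np.log1p(-self.u2)

    @property
    def latency_multiplier(self) -> np.ndarray:
        return self.u1 * self.u2


def sample_cloglog_pairs(alpha, n, seed=None) -> CloglogFrailtyPairs:
    """Draw ``n`` frailty pairs for the clog-log model.

    ``x ~ Beta(alpha, alpha)``, ``y ~ Gamma(2*alpha, rate alpha)``;
    ``u1 = x*y``, ``u2 = y/2``.  By construction ``u1 < 2*u2`` exactly.
    """
    alpha = _check_alpha(alpha)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    x = rng.beta(alpha, alpha, size=n)
    y = rng.gamma(shape=2 * alpha, scale=1.0 / alpha, size=n)
    return CloglogFrailtyPairs(u1=x * y, u2=y / 2.0)


def cloglog_joint_logdensity(u1, u2, alpha):
    """Log joint density of the clog-log frailty pair.

    f(u1, u2) = 2 alpha^{2 alpha} u1^{alpha-1} (2 u2 - u1)^{alpha-1}
                e^{-2 alpha u2} / Gamma(alpha)^2   on 0 < u1 < 2 u2.

    Points outside the support return ``-inf`` (not an exception).
    """
    alpha = _check_alpha(alpha)
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    inside = (u1 > 0) & (u1 < 2 * u2)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = (
            np.log(2.0)
            + 2 * alpha * np.log(alpha)
            - 2 * gammaln(alpha)
            + (alpha - 1) * (np.log(u1) + np.log(2 * u2 - u1))
            - 2 * alpha * u2
        )
    out = np.where(inside, val, -np.inf)
    return out if out.ndim else float(out)


def cloglog_log_frailty_correlation(alpha) -> float:
    """Corr(log u1, log u2) = sqrt(trigamma(2 alpha) / trigamma(alpha)).

    Strictly positive for all alpha > 0; tends to sqrt(1/2) as alpha grows
    (trigamma(z) ~ 1/z).
    """
    alpha = _check_alpha(alpha)
    return float(np.sqrt(polygamma(1, 2 * alpha) / polygamma(1, alpha)))


def sample_logistic_pairs(alpha, n, seed=None) -> LogisticFrailtyPairs:
    """Draw ``n`` frailty pairs for the logistic model.

    With a = 1/alpha: ``u1 ~ Gamma(shape 2a, rate a)`` (mean 2),
    ``u2 ~ Beta(a, a)`` (mean 1/2); independent.  ``E[u1*u2] = 1``.
    """
    alpha = _check_alpha(alpha)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    a = 1.0 / alpha
    u1 = rng.gamma(shape=2 * a, scale=alpha, size=n)
    u2 = rng.beta(a, a, size=n)
    # guard the open-interval support against floating underflow
    eps = np.finfo(float).tiny
    u2 = np.clip(u2, eps, 1.0 - 1e-16)
    u1 = np.maximum(u1, eps)
    return LogisticFrailtyPairs(u1=u1, u2=u2)


def logistic_joint_logdensity(omega1, omega2, alpha):
    """Log joint density of (omega1, omega2) for the logistic construction.

    With a = 1/alpha:
      f = a^{2a} exp(2a omega1 - a omega2)
          exp(-a e^{omega1} (1 + e^{-omega2})) / (Gamma(2a) B(a, a)).
    """
    alpha = _check_alpha(alpha)
    a = 1.0 / alpha
    omega1 = np.asarray(omega1, dtype=float)
    omega2 = np.asarray(omega2, dtype=float)
    val = (
        2 * a * np.log(a)
        + 2 * a * omega1
        - a * omega2
        - a * np.exp(omega1) * (1.0 + np.exp(-omega2))
        - gammaln(2 * a)
        - betaln(a, a)
    )
    return val if val.ndim else float(val)


def logistic_log_frailty_correlation(alpha) -> float:
    """Corr(omega1, omega2) = psi'(a) / sqrt(psi'(a) * 2 psi'(a)) = 1/sqrt(2)."""
    alpha = _check_alpha(alpha)
    a = 1.0 / alpha
    t = polygamma(1, a)
    return float(t / np.sqrt(t * 2 * t))


def logistic_marginal_omega1_logdensity(omega1, alpha):
    """Exact marginal of omega1: e^{omega1} = u1*u2 ~ Gamma(a, rate a), a=1/alpha."""
    alpha = _check_alpha(alpha)
    return shared_loggamma_logdensity(omega1, 1.0 / alpha)


def conditional_loggamma_logdensity(omega2, omega1, alpha):
    """Log conditional density f(omega2 | omega1) of the logistic pair.

    Exactly log-gamma: with a = 1/alpha, ``-omega2 | omega1`` is the log of a
    Gamma(shape a, rate a e^{omega1}) variable, i.e.

      log f = a log a + a (omega1 - omega2) - a e^{omega1 - omega2} - log Gamma(a).
    """
    alpha = _check_alpha(alpha)
    a = 1.0 / alpha
    omega1 = np.asarray(omega1, dtype=float)
    omega2 = np.asarray(omega2, dtype=float)
    w = omega1 - omega2
    val = a * np.log(a) + a * w - a * np.exp(w) - gammaln(a)
    return val if val.ndim else float(val)


def shared_loggamma_logdensity(omega, alpha):
    """Univariate log-gamma density of omega = log(u), u ~ Gamma(alpha, alpha).

    f(omega) = alpha^alpha e^{alpha omega} e^{-alpha e^omega} / Gamma(alpha).
    """
    alpha = _check_alpha(alpha)
    omega = np.asarray(omega, dtype=float)
    val = alpha * np.log(alpha) + alpha * omega - alpha * np.exp(omega) - gammaln(alpha)
    return val if val.ndim else float(val)


def sample_shared_frailty(alpha, n, seed=None) -> np.ndarray:
    """Draw ``n`` shared frailties u ~ Gamma(alpha, rate alpha)."""
    alpha = _check_alpha(alpha)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    return np.maximum(rng.gamma(shape=alpha, scale=1.0 / alpha, size=n),
                      np.finfo(float).tiny)
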