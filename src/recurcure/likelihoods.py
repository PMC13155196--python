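"""Likelihood components of the joint frailty mixture cure models.

The complete-data log-likelihood (cure statuses U and frailties observed)
splits into three blocks that the EM algorithm maximises in turn:

    l_gamma : sum U log pi + (1-U) log(1-pi)            (incidence)
    l_beta  : event terms log f1(t) plus, for censored non-cured records,
              the survival term -Lambda0 e^{Z'beta} m   (latency; m = e^{omega1})
    l_alpha : sum_i log f(frailty_i; alpha)             (frailty)

The E-step replaces the latent quantities by posterior expectations given
the observed data, approximated with K Monte Carlo draws per subject; the
`EStepSummaries` container carries both the draws and the reduced
sufficient statistics the M-steps need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .frailty import (
    CloglogFrailtyPairs,
    LogisticFrailtyPairs,
    cloglog_joint_logdensity,
    conditional_loggamma_logdensity,
    logistic_joint_logdensity,
    logistic_marginal_omega1_logdensity,
    shared_loggamma_logdensity,
)
from .hazards import log_noncure_probability, noncure_probability

__all__ = [
    "EStepSummaries",
    "complete_data_loglik",
    "posterior_noncure",
    "mc_expected_incidence_loglik",
    "expected_latency_loglik",
    "expected_frailty_loglik_cloglog",
    "logistic_censored_approx_loglik",
    "logistic_approx_error_bound",
    "logistic_stage1_loglik",
    "logistic_stage2_loglik",
    "shared_frailty_alpha_loglik",
]


@dataclass
class EStepSummaries:
    """Posterior quantities from one Monte Carlo E-step.

    Per record: ``Ubar`` (posterior non-cure probability, 1 for events) and
    ``EUm`` (posterior mean of U times the latency multiplier m = e^{omega1}).
    Per subject: the sufficient statistics of the M-steps.  ``u1_draws`` /
    ``u2_draws`` are the K retained frailty coordinates per subject;
    ``omega2_draws`` the matching incidence log-frailties;
    ``Ubar_cens_draws`` the per-draw posterior non-cure of censored records
    (rows ``cens_rows``), evaluated at the E-step parameters.
    """

    Ubar: np.ndarray
    EUm: np.ndarray
    Em: np.ndarray
    Elogm: np.ndarray
    u1_draws: np.ndarray
    u2_draws: np.ndarray
    omega2_draws: np.ndarray
    cens_rows: np.ndarray
    Ubar_cens_draws: np.ndarray
    # clog-log / identical sufficient statistics
    Eu2: Optional[np.ndarray] = None
    Elogu1: Optional[np.ndarray] = None
    Elog2u2mu1: Optional[np.ndarray] = None
    Eu: Optional[np.ndarray] = None
    Elogu: Optional[np.ndarray] = None
    # logistic sufficient statistics
    Eomega1: Optional[np.ndarray] = None
    Eomega2: Optional[np.ndarray] = None
    Ee_w1_minus_w2: Optional[np.ndarray] = None
    Eu1: Optional[np.ndarray] = None
    # per-draw log(2 u2 - u1), kept for the alpha-block Louis information
    log2u2mu1_draws: Optional[np.ndarray] = None
    accept_rate: float = float("nan")

    @property
    def K(self) -> int:
        return self.u1_draws.shape[0]


# ---------------------------------------------------------------------------
# complete-data likelihood and the posterior cure status
# ---------------------------------------------------------------------------

def _frailty_coords(pairs, link):
    """(omega1, omega2, multiplier, log prior density) for any link."""
    if link == "cloglog":
        w1, w2 = pairs.omega1, pairs.omega2
        m = pairs.u1
        return w1, w2, m
    if link == "logistic":
        w1, w2 = pairs.omega1, pairs.omega2
        return w1, w2, pairs.u1 * pairs.u2
    if link == "identical":
        u = np.asarray(pairs, dtype=float)
        w = np.log(u)
        return w, w, u
    raise ValueError(f"unknown link {link!r}")


def _frailty_logprior(pairs, link, alpha):
    if link == "cloglog":
        return cloglog_joint_logdensity(pairs.u1, pairs.u2, alpha)
    if link == "logistic":
        return logistic_joint_logdensity(pairs.omega1, pairs.omega2, alpha)
    if link == "identical":
        u = np.asarray(pairs, dtype=float)
        return shared_loggamma_logdensity(np.log(u), alpha)
    raise ValueError(f"unknown link {link!r}")


def complete_data_loglik(data, U, pairs, params) -> float:
    """Log-likelihood with cure statuses U and frailties treated as observed.

    Per record: U log pi + (1-U) log(1-pi), plus log f1(t) for events and
    U * log S1(t) for censored records (a cured record survives with
    probability one).  Per subject: the log frailty density.  Returns -inf
    (never raises) when a record's U contradicts a degenerate pi.
    """
    U = np.asarray(U)
    if np.any((data.delta == 1) & (U == 0)):
        raise ValueError("U must be 1 wherever delta = 1")
    link = params.link
    w1, w2, m = _frailty_coords(pairs, link)
    eta = data.V @ params.gamma + w2[data.subject]
    logpi = log_noncure_probability(link, eta)
    pi = noncure_probability(link, eta)
    with np.errstate(divide="ignore"):
        log1mpi = np.log1p(-pi)
    cum = params.baseline.cumulative(data.gap)
    rate = np.exp(data.Z @ params.beta) * m[data.subject]
    ev = data.delta == 1
    with np.errstate(divide="ignore"):
        log_haz = np.log(params.baseline.hazard_at(data.gap) * rate)
    total = np.sum(np.where(U == 1, logpi, log1mpi))
    total += np.sum(log_haz[ev] - (cum * rate)[ev])
    cens = ~ev
    total += np.sum(np.where(U[cens] == 1, -(cum * rate)[cens], 0.0))
    total += np.sum(_frailty_logprior(pairs, link, params.alpha))
    return float(total)


def posterior_noncure(delta, pi, S1):
    """P(U = 1 | observed record, frailty).

    delta = 1 implies U = 1.  For a censored record this is the Bayes
    posterior under the mixture survival 1 - pi (1 - S1):

        Ubar = pi S1 / (1 - pi (1 - S1)).
    """
    delta = np.asarray(delta)
    pi = np.asarray(pi, dtype=float)
    S1 = np.asarray(S1, dtype=float)
    denom = 1.0 - pi * (1.0 - S1)
    with np.errstate(divide="ignore", invalid="ignore"):
        post = np.where(denom > 0, pi * S1 / np.maximum(denom, 1e-300), 1.0)
    out = np.where(delta == 1, 1.0, post)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# expected incidence block (MC approximation)
# ---------------------------------------------------------------------------

def mc_expected_incidence_loglik(data, summaries, gamma, link="cloglog",
                                 mode="double_weighted") -> float:
    """Monte Carlo expectation of the incidence log-likelihood l_gamma.

    mode="double_weighted": per draw k,
        sum (1-Ubar) log(1-pi^k) + sum Ubar log pi^k
        + sum delta log pi^k - sum (1-delta) pi^k,
    with Ubar the draw-averaged posterior non-cure (so uncensored records
    are double-weighted, and censored records carry a first-order
    -pi^k survival term).

    mode="binomial": the complete-data binomial form
        (1/K) sum_k sum_records  Ubar^k log pi^k + (1 - Ubar^k) log(1-pi^k)
    with the per-draw posterior Ubar^k (1 for events).
    """
    if summaries.K < 1:
        raise ValueError("summaries must contain at least one draw")
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    eta = data.V @ gamma + summaries.omega2_draws[:, data.subject]  # (K, n_rec)
    logpi = log_noncure_probability(link, eta)
    pi = noncure_probability(link, eta)
    with np.errstate(divide="ignore"):
        log1mpi = np.log1p(-pi)
    K = summaries.K
    if mode == "binomial":
        w = np.ones_like(eta)
        w[:, summaries.cens_rows] = summaries.Ubar_cens_draws
        val = np.sum(w * logpi + (1.0 - w) * log1mpi) / K
        return float(val)
    if mode == "double_weighted":
        ubar = summaries.Ubar  # draw-averaged
        delta = data.delta
        val = (
            np.sum((1.0 - ubar) * log1mpi)
            + np.sum(ubar * logpi)
            + np.sum(delta * logpi)
            - np.sum((1 - delta) * pi)
        ) / K
        return float(val)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# expected latency block
# ---------------------------------------------------------------------------

def expected_latency_loglik(data, summaries, beta, baseline,
                            mode="events_only") -> float:
    """Expectation of the latency log-likelihood l_beta.

    mode="events_only": only event records contribute,
        sum_ev [log lambda0(t) + Z'beta - Lambda0(t) e^{Z'beta} E[m] + E[log m]].
    mode="extended": adds the censored records' posterior-weighted
    cumulative-hazard terms  - sum_cens Lambda0(t) e^{Z'beta} E[U m].
    Returns -inf (flagged via errstate) if an event sits at a gap time with
    zero baseline mass.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ev = data.delta == 1
    zb = data.Z @ beta
    cum = baseline.cumulative(data.gap)
    with np.errstate(divide="ignore"):
        loglam = np.log(baseline.hazard_at(data.gap[ev]))
    Em_rec = summaries.Em[data.subject]
    val = (
        np.sum(loglam)
        + np.sum(zb[ev])
        - np.sum(cum[ev] * np.exp(zb[ev]) * Em_rec[ev])
        + np.sum(summaries.Elogm[data.subject[ev]])
    )
    if mode == "extended":
        cens = ~ev
        val -= np.sum(cum[cens] * np.exp(zb[cens]) * summaries.EUm[cens])
    elif mode != "events_only":
        raise ValueError(f"unknown mode {mode!r}")
    return float(val)


# ---------------------------------------------------------------------------
# expected frailty blocks
# ---------------------------------------------------------------------------

def expected_frailty_loglik_cloglog(Elogu1, Elog2u2mu1, Eu2, alpha) -> float:
    """sum_i E[log f(u1_i, u2_i; alpha)] for the bivariate-gamma frailty.

    = N (log 2 + 2 alpha log alpha - 2 log Gamma(alpha))
      + (alpha - 1) sum (E[log u1] + E[log(2 u2 - u1)]) - 2 alpha sum E[u2].
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    Elogu1 = np.asarray(Elogu1, dtype=float)
    N = Elogu1.shape[0]
    s_log = float(np.sum(Elogu1) + np.sum(Elog2u2mu1))
    s_u2 = float(np.sum(Eu2))
    return (
        N * (np.log(2.0) + 2 * alpha * np.log(alpha) - 2 * gammaln(alpha))
        + (alpha - 1) * s_log
        - 2 * alpha * s_u2
    )


def shared_frailty_alpha_loglik(Eu, Elogu, alpha) -> float:
    """sum_i E[log f(u_i; alpha)] for the shared gamma frailty.

    = N alpha log alpha - alpha sum E[u] + (alpha - 1) sum E[log u]
      - N log Gamma(alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    Eu = np.asarray(Eu, dtype=float)
    N = Eu.shape[0]
    return float(
        N * alpha * np.log(alpha)
        - alpha * np.sum(Eu)
        + (alpha - 1) * np.sum(Elogu)
        - N * gammaln(alpha)
    )


# ---------------------------------------------------------------------------
# logistic-model two-stage objectives (fixed frailty pairs)
# ---------------------------------------------------------------------------

def _logistic_terms(data, gamma, beta, baseline, pairs):
    w1 = pairs.omega1
    w2 = pairs.omega2
    m = pairs.u1 * pairs.u2
    eta = data.V @ np.atleast_1d(np.asarray(gamma, dtype=float)) + w2[data.subject]
    pi = noncure_probability("logistic", eta)
    rate = np.exp(data.Z @ np.atleast_1d(np.asarray(beta, dtype=float))) * m[data.subject]
    cum = baseline.cumulative(data.gap)
    S1 = np.exp(-cum * rate)
    return pi, S1, rate, cum, w1, w2


def logistic_censored_approx_loglik(data, gamma, beta, baseline, pairs,
                                    exact=False) -> float:
    """Conditional log-likelihood of the logistic model given frailty pairs.

    Event records contribute log S1 + log lambda1; censored records use the
    first-order approximation log(1 - pi (1 - S1)) ~ -pi (1 - S1) (or the
    exact log1p form when ``exact=True``).
    """
    pi, S1, rate, cum, _, _ = _logistic_terms(data, gamma, beta, baseline, pairs)
    ev = data.delta == 1
    with np.errstate(divide="ignore"):
        loglam = np.log(baseline.hazard_at(data.gap[ev]) * rate[ev])
    val = float(np.sum(-cum[ev] * rate[ev] + loglam))
    x = pi[~ev] * (1.0 - S1[~ev])
    if exact:
        val += float(np.sum(np.log1p(-np.minimum(x, 1 - 1e-16))))
    else:
        val += float(np.sum(-x))
    return val


def logistic_approx_error_bound(pi, S1):
    """Per-record bound |log(1-x) + x| <= x^2 / (2 (1-x)), x = pi (1 - S1)."""
    x = np.asarray(pi, dtype=float) * (1.0 - np.asarray(S1, dtype=float))
    return x ** 2 / (2.0 * np.maximum(1.0 - x, 1e-300))


def logistic_stage1_loglik(data, beta, alpha, baseline, pairs) -> float:
    """Stage-1 objective: event terms plus the conditional log-gamma prior.

    sum_ev (log S1 + log lambda1) + sum_i log f(omega2_i | omega1_i; alpha).
    """
    pi, S1, rate, cum, w1, w2 = _logistic_terms(
        data, np.zeros(data.q), beta, baseline, pairs)
    ev = data.delta == 1
    with np.errstate(divide="ignore"):
        loglam = np.log(baseline.hazard_at(data.gap[ev]) * rate[ev])
    val = float(np.sum(-cum[ev] * rate[ev] + loglam))
    val += float(np.sum(conditional_loggamma_logdensity(w2, w1, alpha)))
    return val


def logistic_stage2_loglik(data, gamma, frozen_beta, frozen_alpha, baseline,
                           pairs) -> float:
    """Stage-2 objective, first-order form: censored survival terms
    -pi (1 - S1) at S1 frozen at (beta0, alpha0), plus the gamma-free
    marginal log f(omega1).

    This form carries no event contribution in gamma and is therefore
    monotone decreasing in pi; `fit_logistic` augments it with the exact
    event terms sum_ev log pi (see docs/methods.md).
    """
    pi, S1, _, _, w1, _ = _logistic_terms(data, gamma, frozen_beta, baseline, pairs)
    cens = data.delta == 0
    val = float(np.sum(-pi[cens] * (1.0 - S1[cens])))
    val += float(np.sum(logistic_marginal_omega1_logdensity(w1, frozen_alpha)))
    return val
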