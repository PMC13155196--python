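"""Model core: cure-incidence links, conditional/marginal gap-time laws, and
the nonparametric baseline hazard.

The latency component is a proportional-hazards model for the gap time of a
non-cured record,

    lambda(t | U=1, omega1) = lambda0(t) * exp(Z'beta + omega1),

and the incidence component models the probability of being non-cured after
each recurrence through a link applied to eta = V'gamma + omega2:

    clog-log:  pi = exp(-exp(eta))
    logistic:  pi = exp(eta) / (1 + exp(eta))

Marginally on the latent cure status U, the overall survival of a gap is the
mixture  S(t) = 1 - pi + pi * exp(-Lambda0(t) e^{Z'beta + omega1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit

__all__ = [
    "StepBaseline",
    "WeibullBaseline",
    "ModelParams",
    "noncure_probability",
    "log_noncure_probability",
    "conditional_hazard",
    "conditional_survival",
    "conditional_density",
    "marginal_survival",
    "marginal_density",
    "breslow_baseline_update",
    "breslow_from_scores",
]

LINKS = ("cloglog", "logistic", "identical")


# ---------------------------------------------------------------------------
# baseline hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepBaseline:
    """Nonparametric step cumulative baseline hazard.

    ``times`` is a strictly increasing grid of event gap-times and
    ``increments`` the hazard mass dLambda0 placed at each; Lambda0(t) is the
    running sum of increments at times <= t, with Lambda0(0) = 0.
    """

    times: np.ndarray
    increments: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.increments, dtype=float)
        if t.ndim != 1 or d.shape != t.shape:
            raise ValueError("times and increments must be 1-D of equal length")
        if t.size and (np.any(np.diff(t) <= 0) or np.any(t <= 0)):
            raise ValueError("times must be positive and strictly increasing")
        if np.any(d < 0):
            raise ValueError("increments must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "increments", d)
        object.__setattr__(self, "_cum", np.concatenate(([0.0], np.cumsum(d))))

    def cumulative(self, t):
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        out = self._cum[idx]
        return out if out.ndim else float(out)

    def hazard_at(self, t):
        """Increment mass at t (0 off the grid)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        idx_c = np.clip(idx, 0, max(self.times.size - 1, 0))
        if self.times.size == 0:
            out = np.zeros_like(t)
        else:
            match = self.times[idx_c] == t
            out = np.where(match, self.increments[idx_c], 0.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class WeibullBaseline:
    """Weibull baseline: hazard mu*scale*t^{mu-1}, Lambda0(t) = scale*t^mu."""

    scale: float
    shape: float

    def __post_init__(self):
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError("scale and shape must be positive")

    def cumulative(self, t):
        t = np.asarray(t, dtype=float)
        out = self.scale * t ** self.shape
        return out if out.ndim else float(out)

    def hazard_at(self, t):
        t = np.asarray(t, dtype=float)
        out = self.shape * self.scale * t ** (self.shape - 1.0)
        return out if out.ndim else float(out)


@dataclass
class ModelParams:
    """Parameters of a joint frailty mixture cure model."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha: float
    baseline: object
    link: str = "cloglog"

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}")


# ---------------------------------------------------------------------------
# incidence links
# ---------------------------------------------------------------------------

def noncure_probability(link, eta):
    """P(U = 1 | omega2) for linear predictor eta = V'gamma + omega2.

    Overflow-safe for |eta| up to ~700.  The "identical" model shares the
    clog-log link.
    """
    eta = np.asarray(eta, dtype=float)
    if link in ("cloglog", "identical"):
        out = np.exp(-np.exp(np.minimum(eta, 700.0)))
    elif link == "logistic":
        out = expit(eta)
    else:
        raise ValueError(f"unknown link {link!r}")
    return out if out.ndim else float(out)


def log_noncure_probability(link, eta):
    """log P(U = 1 | omega2), computed in log space."""
    eta = np.asarray(eta, dtype=float)
    if link in ("cloglog", "identical"):
        out = -np.exp(np.minimum(eta, 700.0))
    elif link == "logistic":
        out = log_expit(eta)
    else:
        raise ValueError(f"unknown link {link!r}")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# conditional (non-cured) gap-time law
# ---------------------------------------------------------------------------

def conditional_hazard(t, zbeta, omega1, baseline):
    """lambda0(t) * exp(Z'beta + omega1)."""
    return baseline.hazard_at(t) * np.exp(np.asarray(zbeta) + np.asarray(omega1))


def conditional_survival(t, zbeta, omega1, baseline):
    """S1(t) = exp(-Lambda0(t) * exp(Z'beta + omega1)); S1(0) = 1."""
    return np.exp(-baseline.cumulative(t) * np.exp(np.asarray(zbeta) + np.asarray(omega1)))


def conditional_density(t, zbeta, omega1, baseline):
    """f1(t) = S1(t) * lambda(t): the density of a non-cured gap time."""
    return conditional_survival(t, zbeta, omega1, baseline) * conditional_hazard(
        t, zbeta, omega1, baseline
    )


# ---------------------------------------------------------------------------
# marginal (mixture) law
# ---------------------------------------------------------------------------

def marginal_survival(t, pi, zbeta, omega1, baseline):
    """S(t) = 1 - pi + pi * S1(t); plateau at 1 - pi as t grows."""
    pi = np.asarray(pi, dtype=float)
    return 1.0 - pi + pi * conditional_survival(t, zbeta, omega1, baseline)


def marginal_density(t, pi, zbeta, omega1, baseline):
    """f(t) = pi * f1(t); a defective density with total mass pi."""
    pi = np.asarray(pi, dtype=float)
    return pi * conditional_density(t, zbeta, omega1, baseline)


# ---------------------------------------------------------------------------
# Breslow-type profile estimator of the baseline
# ---------------------------------------------------------------------------

def breslow_from_scores(gap, delta, scores) -> StepBaseline:
    """Nonparametric baseline update from per-record risk scores.

    At each distinct event gap-time t_(k):
        dLambda0(t_(k)) = d_k / sum_{records: gap >= t_(k)} scores_r
    with d_k the event count at t_(k) (Breslow tie convention: one shared
    risk set).  Risk sets are formed on the gap-time scale, treating gaps as
    exchangeable given the frailty.
    """
    gap = np.asarray(gap, dtype=float)
    delta = np.asarray(delta)
    scores = np.asarray(scores, dtype=float)
    ev = delta == 1
    if not np.any(ev):
        raise ValueError("baseline update requires at least one event")
    times, counts = np.unique(gap[ev], return_counts=True)
    order = np.argsort(gap, kind="stable")
    sorted_gap = gap[order]
    # cumulative score of records with gap >= t: suffix sums over sorted gaps
    suffix = np.cumsum(scores[order][::-1])[::-1]
    idx = np.searchsorted(sorted_gap, times, side="left")
    denom = suffix[idx]
    return StepBaseline(times=times, increments=counts / denom)


def breslow_baseline_update(data, beta, Eu1, Ubar) -> StepBaseline:
    """Posterior-weighted Breslow update for the cumulative baseline hazard.

    Censored records enter risk sets weighted by their posterior non-cure
    probability ``Ubar`` (events have weight 1); every record is additionally
    scaled by exp(Z'beta) and its subject's posterior mean frailty
    multiplier ``Eu1``.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    Eu1 = np.asarray(Eu1, dtype=float)
    Ubar = np.asarray(Ubar, dtype=float)
    w = np.where(data.delta == 1, 1.0, Ubar)
    scores = w * np.exp(data.Z @ beta) * Eu1[data.subject]
    return breslow_from_scores(data.gap, data.delta, scores)
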