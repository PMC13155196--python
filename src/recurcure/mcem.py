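"""Monte Carlo EM estimation for the joint frailty mixture cure models.

One generic driver serves the three model variants:

* ``fit_cloglog``  — clog-log incidence with the correlated bivariate-gamma
  frailty pair (u1, u2);
* ``fit_identical`` — clog-log incidence with a single shared gamma frailty;
* ``fit_logistic`` — logistic incidence with the gamma x beta frailty pair,
  estimated by the two-stage alternation (latency + frailty shape first,
  incidence coefficients second).

Each outer iteration draws K frailty samples per subject from the posterior
given that subject's records (Metropolis-within-Gibbs with independence
proposals from the prior conditionals, warm-started across iterations),
reduces them to sufficient statistics, and maximises the three likelihood
blocks in turn: Newton-Raphson for gamma, a Breslow/Newton alternation for
(baseline, beta), and bounded scalar search on log alpha.  Standard errors
come from the Louis identity
    I = E[-B_c] - E[S_c S_c'] + S_m S_m'
estimated over the retained draws, and the observed-data log-likelihood for
the AIC is a Monte Carlo importance-sampling estimate with fresh draws from
the frailty prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, expit, gammaln, log_expit, logsumexp, polygamma

from .data import RecurrentData
from .frailty import (
    sample_cloglog_pairs,
    sample_logistic_pairs,
    sample_shared_frailty,
)
from .hazards import (
    ModelParams,
    StepBaseline,
    breslow_from_scores,
    log_noncure_probability,
    noncure_probability,
)
from .likelihoods import (
    EStepSummaries,
    expected_frailty_loglik_cloglog,
    expected_latency_loglik,
    posterior_noncure,
    shared_frailty_alpha_loglik,
)

__all__ = [
    "MCEMConfig",
    "FitResult",
    "fit_cloglog",
    "fit_identical",
    "fit_logistic",
    "estep_draw_frailties",
    "mstep_gamma",
    "mstep_beta",
    "mstep_alpha_cloglog",
    "mstep_alpha_shared",
    "mstep_alpha_logistic",
    "louis_information",
    "observed_data_loglik",
    "default_init",
]

_ALPHA_LOG_BOUNDS = (np.log(1e-3), np.log(1e3))


@dataclass
class MCEMConfig:
    """Tuning knobs of the MCEM run.

    ``mcss`` is the Monte Carlo sample size K per E-step; ``burnin`` the
    discarded sweeps of the first E-step chain and ``warm_burnin`` of the
    warm-started chains of later iterations; ``tol`` the convergence
    tolerance on the maximum absolute change of (beta, gamma, log alpha)
    over two successive iterations.  ``tail_avg`` final iterates are
    averaged when the strict criterion never triggers (Monte Carlo jitter at
    moderate K routinely exceeds ``tol``).  ``incidence_mode`` / ``latency_mode``
    select the printed forms of the expected incidence / latency objectives
    or their exact complete-data counterparts ("binomial" / "extended").
    """

    mcss: int = 1000
    burnin: int = 200
    warm_burnin: int = 30
    thin: int = 1
    tol: float = 1e-3
    max_iter: int = 200
    tail_avg: int = 10
    seed: int = 0
    incidence_mode: str = "double_weighted"
    latency_mode: str = "events_only"
    loglik_draws: int = 500
    stage2_events: bool = True
    stage2_exact: bool = True

    def __post_init__(self):
        if self.mcss < 1:
            raise ValueError("mcss must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitResult:
    """Result of one MCEM fit."""

    params: ModelParams
    se_gamma: np.ndarray
    se_beta: np.ndarray
    se_alpha: float
    loglik: float
    aic: float
    n_iter: int
    converged: bool
    trace: pd.DataFrame
    accept_rate: float
    config: MCEMConfig
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# posterior target (per-subject unnormalised log posterior, data part only)
# ---------------------------------------------------------------------------

def _zero_tail_mask(data, baseline):
    """Censored records beyond the last baseline event time (zero-tail)."""
    if isinstance(baseline, StepBaseline) and baseline.times.size:
        return (data.delta == 0) & (data.gap > baseline.times[-1])
    return np.zeros(data.n_records, dtype=bool)

class _PosteriorTarget:
    """Caches per-record quantities so each Metropolis sweep is a handful of
    vectorised operations over subjects and censored records.

    Censored gaps beyond the last observed event time carry the zero-tail
    constraint S1 = 0 (the semiparametric mixture cure convention): their
    survival contribution is 1 - pi regardless of the latency frailty,
    implemented here as an effectively infinite cumulative hazard.
    """

    def __init__(self, data: RecurrentData, params: ModelParams):
        link = params.link
        zb = data.Z @ params.beta
        cum = params.baseline.cumulative(data.gap)
        ev = data.delta == 1
        tail = np.asarray(_zero_tail_mask(data, params.baseline))
        cum = np.where(tail, np.inf, cum)
        rho = cum * np.exp(zb)
        eta0 = data.V @ params.gamma
        subj = data.subject
        N = data.n_subjects
        self.link = link
        self.N = N
        self.n1 = np.bincount(subj[ev], minlength=N).astype(float)
        self.A = np.bincount(subj[ev], weights=rho[ev], minlength=N)
        self.subj_c = subj[~ev]
        self.rho_c = rho[~ev]
        self.eta_c = eta0[~ev]
        if link in ("cloglog", "identical"):
            c = np.exp(np.minimum(eta0, 700.0))
            self.B = np.bincount(subj[ev], weights=c[ev], minlength=N)
            self.c_c = c[~ev]
        else:
            self.subj_e = subj[ev]
            self.eta_e = eta0[ev]

    def _cens_part(self, pi_c, s1_c):
        x = np.minimum(pi_c * (1.0 - s1_c), 1.0 - 1e-16)
        return np.bincount(self.subj_c, weights=np.log1p(-x), minlength=self.N)

    def cloglog(self, u1, u2):
        t = self.n1 * np.log(u1) - self.A * u1 - self.B * u2
        if self.subj_c.size:
            pi = np.exp(-self.c_c * u2[self.subj_c])
            s1 = np.exp(-self.rho_c * u1[self.subj_c])
            t = t + self._cens_part(pi, s1)
        return t

    def logistic(self, u1, u2):
        m = u1 * u2
        w2 = np.log(u2) - np.log1p(-u2)
        t = self.n1 * np.log(m) - self.A * m
        if self.subj_e.size:
            t = t + np.bincount(
                self.subj_e,
                weights=log_expit(self.eta_e + w2[self.subj_e]),
                minlength=self.N,
            )
        if self.subj_c.size:
            pi = expit(self.eta_c + w2[self.subj_c])
            s1 = np.exp(-self.rho_c * m[self.subj_c])
            t = t + self._cens_part(pi, s1)
        return t

    def identical(self, u):
        t = self.n1 * np.log(u) - (self.A + self.B) * u
        if self.subj_c.size:
            pi = np.exp(-self.c_c * u[self.subj_c])
            s1 = np.exp(-self.rho_c * u[self.subj_c])
            t = t + self._cens_part(pi, s1)
        return t


# ---------------------------------------------------------------------------
# E-step samplers
# ---------------------------------------------------------------------------

def _chain_cloglog(tgt, alpha, cfg, rng, state, nburn):
    """Metropolis-within-Gibbs on the (x, y) construction coordinates.

    Independence proposals from the prior conditionals; one state is
    retained after every accepted-or-rejected coordinate update once past
    burn-in (two retained draws per full sweep), so K retained draws cost
    K/2 sweeps after nburn burn-in sweeps.
    """
    N = tgt.N
    K = cfg.mcss
    if state is None:
        pr = sample_cloglog_pairs(alpha, N, rng)
        y = 2.0 * pr.u2
        x = np.clip(pr.u1 / y, 1e-16, 1.0 - 1e-16)
    else:
        x, y = state
    cur = tgt.cloglog(x * y, y / 2.0)
    keep_x = np.empty((K, N))
    keep_y = np.empty((K, N))
    n_acc = 0
    n_prop = 0
    k = 0
    total_updates = 2 * nburn + K * cfg.thin
    upd = 0
    while k < K:
        xp = np.clip(rng.beta(alpha, alpha, size=N), 1e-16, 1.0 - 1e-16)
        prop = tgt.cloglog(xp * y, y / 2.0)
        acc = np.log(rng.random(N)) < prop - cur
        x = np.where(acc, xp, x)
        cur = np.where(acc, prop, cur)
        n_acc += int(acc.sum())
        upd += 1
        if upd > 2 * nburn and (upd - 2 * nburn) % cfg.thin == 0 and k < K:
            keep_x[k] = x
            keep_y[k] = y
            k += 1

        yp = np.maximum(rng.gamma(2 * alpha, 1.0 / alpha, size=N), 1e-300)
        prop = tgt.cloglog(x * yp, yp / 2.0)
        acc2 = np.log(rng.random(N)) < prop - cur
        y = np.where(acc2, yp, y)
        cur = np.where(acc2, prop, cur)
        n_acc += int(acc2.sum())
        n_prop += 2 * N
        upd += 1
        if upd > 2 * nburn and (upd - 2 * nburn) % cfg.thin == 0 and k < K:
            keep_x[k] = x
            keep_y[k] = y
            k += 1
    return keep_x, keep_y, (x, y), n_acc / max(n_prop, 1)


def _chain_logistic(tgt, alpha, cfg, rng, state, nburn):
    N = tgt.N
    K = cfg.mcss
    a = 1.0 / alpha
    if state is None:
        pr = sample_logistic_pairs(alpha, N, rng)
        u1, u2 = pr.u1.copy(), pr.u2.copy()
    else:
        u1, u2 = state
    cur = tgt.logistic(u1, u2)
    keep1 = np.empty((K, N))
    keep2 = np.empty((K, N))
    n_acc = 0
    n_prop = 0
    k = 0
    upd = 0
    while k < K:
        p1 = np.maximum(rng.gamma(2 * a, alpha, size=N), 1e-300)
        prop = tgt.logistic(p1, u2)
        acc = np.log(rng.random(N)) < prop - cur
        u1 = np.where(acc, p1, u1)
        cur = np.where(acc, prop, cur)
        n_acc += int(acc.sum())
        upd += 1
        if upd > 2 * nburn and (upd - 2 * nburn) % cfg.thin == 0 and k < K:
            keep1[k] = u1
            keep2[k] = u2
            k += 1

        p2 = np.clip(rng.beta(a, a, size=N), 1e-16, 1.0 - 1e-16)
        prop = tgt.logistic(u1, p2)
        acc2 = np.log(rng.random(N)) < prop - cur
        u2 = np.where(acc2, p2, u2)
        cur = np.where(acc2, prop, cur)
        n_acc += int(acc2.sum())
        n_prop += 2 * N
        upd += 1
        if upd > 2 * nburn and (upd - 2 * nburn) % cfg.thin == 0 and k < K:
            keep1[k] = u1
            keep2[k] = u2
            k += 1
    return keep1, keep2, (u1, u2), n_acc / max(n_prop, 1)


def _chain_identical(tgt, alpha, cfg, rng, state, nburn):
    N = tgt.N
    K = cfg.mcss
    u = sample_shared_frailty(alpha, N, rng) if state is None else state
    cur = tgt.identical(u)
    keep = np.empty((K, N))
    n_acc = 0
    n_prop = 0
    total = nburn + K * cfg.thin
    for sweep in range(total):
        up = sample_shared_frailty(alpha, N, rng)
        prop = tgt.identical(up)
        acc = np.log(rng.random(N)) < prop - cur
        u = np.where(acc, up, u)
        cur = np.where(acc, prop, cur)
        n_acc += int(acc.sum())
        n_prop += N
        k = sweep - nburn
        if k >= 0 and k % cfg.thin == 0:
            keep[k // cfg.thin] = u
    return keep, u, n_acc / max(n_prop, 1)


def estep_draw_frailties(data, params, config, rng, state=None, first=True):
    """One Monte Carlo E-step: K posterior frailty draws per subject plus the
    reduced summaries the M-steps consume.

    Returns ``(EStepSummaries, chain_state)``.  The chain is
    Metropolis-within-Gibbs with independence proposals from the prior
    conditionals (exact in the no-data limit); ``state`` warm-starts it.
    """
    tgt = _PosteriorTarget(data, params)
    nburn = config.burnin if (state is None or first) else config.warm_burnin
    link = params.link
    cens = data.delta == 0
    cens_rows = np.flatnonzero(cens)
    subj_c = data.subject[cens]
    rho_c = tgt.rho_c
    if link == "cloglog":
        kx, ky, new_state, rate = _chain_cloglog(
            tgt, params.alpha, config, rng, state, nburn)
        u1d = kx * ky
        u2d = ky / 2.0
        md = u1d
        omega2d = np.log(u2d)
        log2u2mu1 = np.log(ky) + np.log1p(-kx)
        pi_k = np.exp(-tgt.c_c * u2d[:, subj_c])
    elif link == "logistic":
        u1d, u2d, new_state, rate = _chain_logistic(
            tgt, params.alpha, config, rng, state, nburn)
        md = u1d * u2d
        omega2d = np.log(u2d) - np.log1p(-u2d)
        log2u2mu1 = None
        pi_k = expit(tgt.eta_c + omega2d[:, subj_c])
    elif link == "identical":
        ud, new_state, rate = _chain_identical(
            tgt, params.alpha, config, rng, state, nburn)
        u1d = ud
        u2d = ud
        md = ud
        omega2d = np.log(ud)
        log2u2mu1 = None
        pi_k = np.exp(-tgt.c_c * ud[:, subj_c])
    else:
        raise ValueError(f"unknown link {link!r}")

    if rate < 0.01:
        warnings.warn(
            f"E-step acceptance rate {rate:.3%} is below 1%; posterior "
            "summaries may be unreliable at this parameter value.",
            UserWarning,
        )

    s1_k = np.exp(-rho_c * md[:, subj_c])
    denom = np.maximum(1.0 - pi_k * (1.0 - s1_k), 1e-300)
    ub_k = pi_k * s1_k / denom  # (K, n_cens)

    n_rec = data.n_records
    Em = md.mean(axis=0)
    Elogm = np.log(md).mean(axis=0)
    Ubar = np.ones(n_rec)
    EUm = Em[data.subject].copy()
    if cens_rows.size:
        Ubar[cens_rows] = ub_k.mean(axis=0)
        EUm[cens_rows] = (ub_k * md[:, subj_c]).mean(axis=0)

    summ = EStepSummaries(
        Ubar=Ubar,
        EUm=EUm,
        Em=Em,
        Elogm=Elogm,
        u1_draws=u1d,
        u2_draws=u2d,
        omega2_draws=omega2d,
        cens_rows=cens_rows,
        Ubar_cens_draws=ub_k,
        accept_rate=rate,
    )
    if link == "cloglog":
        summ.Eu2 = u2d.mean(axis=0)
        summ.Elogu1 = Elogm
        summ.Elog2u2mu1 = log2u2mu1.mean(axis=0)
        summ.log2u2mu1_draws = log2u2mu1
    elif link == "identical":
        summ.Eu = Em
        summ.Elogu = Elogm
    else:
        summ.Eomega1 = Elogm
        summ.Eomega2 = omega2d.mean(axis=0)
        summ.Ee_w1_minus_w2 = (u1d * (1.0 - u2d)).mean(axis=0)
        summ.Eu1 = u1d.mean(axis=0)
    return summ, new_state


# ---------------------------------------------------------------------------
# M-step: incidence coefficients (clog-log / identical)
# ---------------------------------------------------------------------------

def _cloglog_cens_terms(w):
    """Stable pieces of the clog-log incidence objective, w = exp(eta).

    pi = exp(-w); 1 - pi = -expm1(-w) avoids overflow for large w.
    """
    pi = np.exp(-w)
    one_m_pi = np.maximum(-np.expm1(-w), 1e-300)
    with np.errstate(divide="ignore"):
        log1mpi = np.log(one_m_pi)
    logpi = -w
    g1 = w * pi / one_m_pi            # d log(1-pi)/deta
    h1 = g1 * (1.0 - w - g1)          # second derivative
    return logpi, log1mpi, g1, h1


def mstep_gamma(data, summaries, gamma0, link="cloglog", mode="double_weighted",
                max_newton=40, grad_tol=1e-7):
    """Newton-Raphson maximiser of the MC expected incidence log-likelihood.

    Specialised fast path for the clog-log link (also used by the identical
    model): event records reduce to the sufficient statistic E[u2] so only
    censored records need per-draw evaluation.  Step-halving enforces
    ascent relative to ``gamma0``.
    """
    if link != "cloglog":
        raise ValueError("mstep_gamma implements the clog-log incidence link")
    gamma = np.array(gamma0, dtype=float)
    V = data.V
    ev = data.delta == 1
    Vev = V[ev]
    cens_rows = summaries.cens_rows
    Vc = V[cens_rows]
    subj_c = data.subject[cens_rows]
    u2c = summaries.u2_draws[:, subj_c]               # (K, n_cens)
    K = summaries.K
    if mode == "binomial":
        wk = summaries.Ubar_cens_draws                # per-draw posterior
        ev_coef = 1.0
    elif mode == "double_weighted":
        wk = np.broadcast_to(summaries.Ubar[cens_rows], u2c.shape)
        ev_coef = 2.0                                 # Ubar + delta for events
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # events: sum delta * coef * log pi = -coef * sum exp(eta0) * E[u2]
    Eu2_ev = summaries.u2_draws.mean(axis=0)[data.subject[ev]]

    def value_grad_hess(g, need_vgh=True):
        eta_ev = Vev @ g
        ce = np.exp(np.minimum(eta_ev, 700.0))
        val = -ev_coef * float(np.sum(ce * Eu2_ev))
        grad = -ev_coef * Vev.T @ (ce * Eu2_ev)
        hterm = -ev_coef * (ce * Eu2_ev)
        if cens_rows.size:
            eta_c = Vc @ g
            w = np.exp(np.minimum(eta_c, 700.0)) * u2c   # (K, n_cens)
            logpi, log1mpi, g1, h1 = _cloglog_cens_terms(w)
            val += float(np.sum(wk * logpi + (1.0 - wk) * log1mpi)) / K
            geta = (wk * (-w) + (1.0 - wk) * g1)
            heta = (wk * (-w) + (1.0 - wk) * h1)
            if mode == "double_weighted":
                pi = np.exp(-w)
                val += float(np.sum(-pi)) / K
                geta = geta + pi * w
                heta = heta + pi * w * (1.0 - w)
            gc = geta.mean(axis=0)
            hc = heta.mean(axis=0)
            grad = grad + Vc.T @ gc
            hfull = np.concatenate([hterm, hc])
            Vfull = np.vstack([Vev, Vc])
        else:
            hfull = hterm
            Vfull = Vev
        H = Vfull.T @ (hfull[:, None] * Vfull)
        return val, grad, H

    val0, grad, H = value_grad_hess(gamma)
    best = val0
    for _ in range(max_newton):
        if np.max(np.abs(grad)) < grad_tol * max(1.0, data.n_records / 100.0):
            break
        Hr = H - 1e-10 * np.eye(H.shape[0])
        try:
            step = np.linalg.solve(Hr, grad)
        except np.linalg.LinAlgError:
            warnings.warn("singular incidence Hessian; ridge-regularised step",
                          UserWarning)
            step = np.linalg.solve(Hr - 1e-4 * np.eye(H.shape[0]), grad)
        new = gamma - step
        valn, gradn, Hn = value_grad_hess(new)
        halves = 0
        while not np.isfinite(valn) or valn < best - 1e-12:
            step *= 0.5
            new = gamma - step
            valn, gradn, Hn = value_grad_hess(new)
            halves += 1
            if halves > 40:
                return gamma
        if abs(valn - best) < 1e-12 and np.max(np.abs(step)) < 1e-10:
            break
        gamma, best, grad, H = new, valn, gradn, Hn
    return gamma


# ---------------------------------------------------------------------------
# M-step: latency coefficients + baseline
# ---------------------------------------------------------------------------

def mstep_beta(data, summaries, beta0, mode="events_only", inner=25):
    """Alternate the posterior-weighted Breslow baseline update with Newton
    steps on the expected latency log-likelihood until stabilisation.

    mode="events_only" keeps only event records in the beta objective (the
    baseline risk sets always include censored records at posterior weight
    E[U m]); mode="extended" adds the censored cumulative-hazard terms,
    making the alternation the exact profile EM update.
    """
    beta = np.array(beta0, dtype=float)
    Z = data.Z
    ev = data.delta == 1
    Zev = Z[ev]
    EUm = summaries.EUm  # events already hold E[m]
    w_obj = EUm if mode == "extended" else np.where(ev, EUm, 0.0)
    if mode not in ("events_only", "extended"):
        raise ValueError(f"unknown mode {mode!r}")
    sum_Zev = Zev.sum(axis=0)
    baseline = None
    for cycle in range(inner):
        scores = EUm * np.exp(Z @ beta)
        baseline = breslow_from_scores(data.gap, data.delta, scores)
        cum = baseline.cumulative(data.gap)
        prev = beta.copy()
        for _ in range(30):
            r = cum * np.exp(Z @ beta) * w_obj
            grad = sum_Zev - Z.T @ r
            H = -(Z.T @ (r[:, None] * Z))
            try:
                step = np.linalg.solve(H - 1e-12 * np.eye(H.shape[0]), grad)
            except np.linalg.LinAlgError:
                step = -grad
            beta = beta - step
            if np.max(np.abs(step)) < 1e-11:
                break
        if np.max(np.abs(beta - prev)) < 1e-9 and cycle > 0:
            break
    scores = EUm * np.exp(Z @ beta)
    baseline = breslow_from_scores(data.gap, data.delta, scores)
    return beta, baseline


# ---------------------------------------------------------------------------
# M-step: frailty heterogeneity
# ---------------------------------------------------------------------------

def _maximize_scalar_logscale(f):
    res = minimize_scalar(
        lambda la: -f(float(np.exp(la))),
        bounds=_ALPHA_LOG_BOUNDS,
        method="bounded",
        options={"xatol": 1e-9},
    )
    out = float(np.exp(res.x))
    lo, hi = np.exp(_ALPHA_LOG_BOUNDS[0]), np.exp(_ALPHA_LOG_BOUNDS[1])
    if out < lo * 1.01 or out > hi * 0.99:
        warnings.warn(
            f"alpha maximiser {out:.4g} at the search boundary; clipped.",
            UserWarning,
        )
    return out


def mstep_alpha_cloglog(summaries):
    """Maximise the expected bivariate-gamma frailty block over alpha."""
    return _maximize_scalar_logscale(
        lambda a: expected_frailty_loglik_cloglog(
            summaries.Elogu1, summaries.Elog2u2mu1, summaries.Eu2, a)
    )


def mstep_alpha_shared(summaries):
    """Maximise the expected shared-gamma frailty block over alpha."""
    return _maximize_scalar_logscale(
        lambda a: shared_frailty_alpha_loglik(summaries.Eu, summaries.Elogu, a)
    )


def mstep_alpha_logistic(summaries):
    """Maximise the expected joint frailty log-density over alpha.

    The two stage objectives carry the frailty prior split as
    f(w2|w1) + f(w1) = f(w1, w2); the joint is the exact EM update (the
    conditional part alone has no ascent guarantee and can drift toward
    homogeneity).  In terms of a = 1/alpha, using e^{w1}(1+e^{-w2}) = u1:

        N (2a log a - log Gamma(2a) - log B(a, a))
        + a (2 sum E[w1] - sum E[w2] - sum E[u1]).
    """
    N = summaries.Eomega1.shape[0]
    C = float(np.sum(2.0 * summaries.Eomega1 - summaries.Eomega2
                     - summaries.Eu1))

    def obj(a):
        return N * (2 * a * np.log(a) - gammaln(2 * a) - betaln_aa(a)) + a * C

    a_hat = _maximize_scalar_logscale(obj)
    return 1.0 / a_hat


def betaln_aa(a):
    return 2.0 * gammaln(a) - gammaln(2 * a)


# ---------------------------------------------------------------------------
# Louis information
# ---------------------------------------------------------------------------

def _link_eta_derivs(link, eta):
    """(dlogpi, dlog1mpi, d2logpi, d2log1mpi) w.r.t. eta."""
    if link in ("cloglog", "identical"):
        w = np.exp(np.minimum(eta, 700.0))
        _, _, g1, h1 = _cloglog_cens_terms(w)
        return -w, g1, -w, h1
    if link == "logistic":
        pi = expit(eta)
        return 1.0 - pi, -pi, -pi * (1.0 - pi), -pi * (1.0 - pi)
    raise ValueError(f"unknown link {link!r}")


def louis_information(data, summaries, params, block):
    """Observed information for one parameter block by the Louis identity.

    I = E[-B_c] - E[S_c S_c'] + S_m S_m', with complete-data score S_c and
    Hessian B_c Rao-Blackwellised over the latent cure statuses (Bernoulli
    given each frailty draw) and averaged over the K retained draws.  With a
    single degenerate draw and no censoring the identity collapses to the
    complete-data observed information.
    """
    K = summaries.K
    link = params.link
    subj = data.subject
    cens_rows = summaries.cens_rows
    if block == "gamma":
        inc_link = "cloglog" if link in ("cloglog", "identical") else "logistic"
        eta = data.V @ params.gamma + summaries.omega2_draws[:, subj]
        gp, gq, hp, hq = _link_eta_derivs(inc_link, eta)
        w = np.ones_like(eta)
        if cens_rows.size:
            w[:, cens_rows] = summaries.Ubar_cens_draws
        sc = w * gp + (1.0 - w) * gq               # (K, n_rec)
        S = sc @ data.V                            # per-draw scores (K, q)
        hbar = (w * hp + (1.0 - w) * hq).mean(axis=0)
        EB = data.V.T @ (hbar[:, None] * data.V)
        vbar = (w * (1.0 - w) * (gp - gq) ** 2).mean(axis=0)
        EScSc = (S.T @ S) / K + data.V.T @ (vbar[:, None] * data.V)
        Sm = S.mean(axis=0)
        return -EB - EScSc + np.outer(Sm, Sm)

    if block == "beta":
        m = _latency_multiplier_draws(summaries, link)
        cum = params.baseline.cumulative(data.gap)
        base = cum * np.exp(data.Z @ params.beta)
        a = base * m[:, subj]                      # (K, n_rec)
        w = np.ones_like(a)
        if cens_rows.size:
            w[:, cens_rows] = summaries.Ubar_cens_draws
        aw = a * w
        sum_Zev = data.Z[data.delta == 1].sum(axis=0)
        S = sum_Zev[None, :] - aw @ data.Z
        abar = aw.mean(axis=0)
        EB = -(data.Z.T @ (abar[:, None] * data.Z))
        vbar = (w * (1.0 - w) * a ** 2).mean(axis=0)
        EScSc = (S.T @ S) / K + data.Z.T @ (vbar[:, None] * data.Z)
        Sm = S.mean(axis=0)
        return -EB - EScSc + np.outer(Sm, Sm)

    if block == "alpha":
        al = params.alpha
        N = data.n_subjects
        if link == "cloglog":
            s_k = (
                N * (2 * np.log(al) + 2 - 2 * digamma(al))
                + np.sum(np.log(summaries.u1_draws)
                         + summaries.log2u2mu1_draws
                         - 2 * summaries.u2_draws, axis=1)
            )
            B = N * (2.0 / al - 2 * polygamma(1, al))
        elif link == "identical":
            s_k = (
                N * (np.log(al) + 1 - digamma(al))
                + np.sum(np.log(summaries.u1_draws) - summaries.u1_draws, axis=1)
            )
            B = N * (1.0 / al - polygamma(1, al))
        else:  # logistic (joint frailty density), chain rule through a = 1/alpha
            a_par = 1.0 / al
            w1 = np.log(summaries.u1_draws * summaries.u2_draws)
            w2 = (np.log(summaries.u2_draws)
                  - np.log1p(-summaries.u2_draws))
            term = np.sum(2.0 * w1 - w2 - summaries.u1_draws, axis=1)
            s_a = N * (2 * np.log(a_par) + 2 - 2 * digamma(a_par)) + term
            B_a = N * (2.0 / a_par - 2 * polygamma(1, a_par))
            s_k = -(a_par ** 2) * s_a
            B_k = 2 * a_par ** 3 * s_a + a_par ** 4 * B_a
            B = float(np.mean(B_k))
            var_s = float(np.var(s_k))
            return np.array([[-B - var_s]])
        var_s = float(np.var(s_k)) if K > 1 else 0.0
        return np.array([[-B - var_s]])

    raise ValueError(f"unknown block {block!r}")


def _latency_multiplier_draws(summaries, link):
    if link == "logistic":
        return summaries.u1_draws * summaries.u2_draws
    return summaries.u1_draws


def _se_from_information(I):
    """sqrt of the diagonal of the inverse; pseudo-inverse on failure."""
    flag = False
    try:
        cov = np.linalg.inv(I)
        d = np.diag(cov)
        if np.any(d < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(I)
        d = np.abs(np.diag(cov))
        flag = True
    return np.sqrt(np.abs(d)), flag


# ---------------------------------------------------------------------------
# observed-data log-likelihood (MC importance sampling from the prior)
# ---------------------------------------------------------------------------

def observed_data_loglik(data, params, n_draws, rng):
    """Monte Carlo estimate of the observed-data log-likelihood.

    Integrates each subject's contribution over the frailty prior with
    ``n_draws`` fresh importance draws (exact mixture survival for censored
    records, pi * f1 for events), combined with log-sum-exp.
    """
    link = params.link
    N = data.n_subjects
    if link == "cloglog":
        pr = sample_cloglog_pairs(params.alpha, n_draws * N, rng)
        u1 = pr.u1.reshape(n_draws, N)
        u2 = pr.u2.reshape(n_draws, N)
        m = u1
        omega2 = np.log(u2)
        inc_link = "cloglog"
    elif link == "logistic":
        pr = sample_logistic_pairs(params.alpha, n_draws * N, rng)
        u1 = pr.u1.reshape(n_draws, N)
        u2 = pr.u2.reshape(n_draws, N)
        m = u1 * u2
        omega2 = np.log(u2) - np.log1p(-u2)
        inc_link = "logistic"
    elif link == "identical":
        u = sample_shared_frailty(params.alpha, n_draws * N, rng).reshape(n_draws, N)
        m = u
        omega2 = np.log(u)
        inc_link = "cloglog"
    else:
        raise ValueError(f"unknown link {link!r}")

    subj = data.subject
    eta = data.V @ params.gamma + omega2[:, subj]
    logpi = log_noncure_probability(inc_link, eta)
    pi = noncure_probability(inc_link, eta)
    cum = np.where(_zero_tail_mask(data, params.baseline), np.inf,
                   params.baseline.cumulative(data.gap))
    zb = np.exp(data.Z @ params.beta)
    base = cum * zb
    ev = data.delta == 1
    with np.errstate(divide="ignore"):
        log_dlam = np.log(params.baseline.hazard_at(data.gap) * zb)
    mm = m[:, subj]
    contrib = np.empty_like(eta)
    contrib[:, ev] = (
        logpi[:, ev] + log_dlam[ev][None, :] + np.log(mm[:, ev])
        - base[ev][None, :] * mm[:, ev]
    )
    cens = ~ev
    s1 = np.exp(-base[cens][None, :] * mm[:, cens])
    x = np.minimum(pi[:, cens] * (1.0 - s1), 1.0 - 1e-16)
    contrib[:, cens] = np.log1p(-x)

    per_subject = np.add.reduceat(contrib, data.subject_starts, axis=1)
    ll = logsumexp(per_subject, axis=0) - np.log(n_draws)
    return float(np.sum(ll))


# ---------------------------------------------------------------------------
# initial values
# ---------------------------------------------------------------------------

def default_init(data, link="cloglog"):
    """Cheap consistent starting values.

    beta from a no-frailty proportional-hazards fit on all records; gamma
    from a no-frailty cure-status GLM with the event indicator as response
    proxy; alpha = 1; baseline from the matching Breslow update.
    """
    N = data.n_subjects
    n_rec = data.n_records
    cens_rows = np.flatnonzero(data.delta == 0)
    ones = np.ones((1, N))
    init_summ = EStepSummaries(
        Ubar=data.delta.astype(float).copy(),
        EUm=np.ones(n_rec),
        Em=np.ones(N),
        Elogm=np.zeros(N),
        u1_draws=ones,
        u2_draws=ones,
        omega2_draws=np.zeros((1, N)),
        cens_rows=cens_rows,
        Ubar_cens_draws=np.zeros((1, cens_rows.size)),
    )
    beta, baseline = mstep_beta(data, init_summ, np.zeros(data.p),
                                mode="extended")
    if link == "logistic":
        gamma = _logistic_glm_init(data)
    else:
        gamma = mstep_gamma(data, init_summ, np.zeros(data.q),
                            mode="binomial")
    return ModelParams(beta=beta, gamma=gamma, alpha=1.0,
                       baseline=baseline, link=link)


def _logistic_glm_init(data):
    """Logistic GLM of the event indicator on V (Newton, no frailty)."""
    y = data.delta.astype(float)
    V = data.V
    g = np.zeros(data.q)
    for _ in range(50):
        pi = expit(V @ g)
        grad = V.T @ (y - pi)
        H = -(V.T @ ((pi * (1 - pi))[:, None] * V))
        step = np.linalg.solve(H - 1e-10 * np.eye(data.q), grad)
        g = g - step
        if np.max(np.abs(step)) < 1e-10:
            break
    return g


# ---------------------------------------------------------------------------
# stage-2 incidence update for the logistic model
# ---------------------------------------------------------------------------

def _mstep_gamma_logistic_stage2(data, summaries, gamma0, beta, baseline, cfg):
    """Maximise the stage-2 objective over gamma at frozen (beta, alpha).

    Censored records contribute the first-order survival terms
    -pi (1 - S1^0) (or the exact log1p form with ``stage2_exact``); with
    ``stage2_events`` the exact event contribution sum_ev E[log pi] is
    retained, without which the printed objective is unbounded in gamma.
    """
    subj = data.subject
    ev = data.delta == 1
    cens_rows = summaries.cens_rows
    m = _latency_multiplier_draws(summaries, "logistic")
    cum = np.where(_zero_tail_mask(data, baseline), np.inf,
                   baseline.cumulative(data.gap))
    base = cum * np.exp(data.Z @ beta)
    s1c = np.exp(-base[cens_rows] * m[:, subj[cens_rows]])     # (K, n_cens)
    one_m_s1 = 1.0 - s1c
    w2c = summaries.omega2_draws[:, subj[cens_rows]]
    w2e = summaries.omega2_draws[:, subj[ev]]
    Vc = data.V[cens_rows]
    Ve = data.V[ev]
    K = summaries.K

    def negobj_and_grad(g):
        eta_c = Vc @ g + w2c
        pi = expit(eta_c)
        if cfg.stage2_exact:
            x = np.minimum(pi * one_m_s1, 1 - 1e-16)
            val = float(np.sum(np.log1p(-x))) / K
            gw = -(pi * (1 - pi) * one_m_s1) / np.maximum(1.0 - x, 1e-300)
        else:
            val = float(np.sum(-pi * one_m_s1)) / K
            gw = -pi * (1 - pi) * one_m_s1
        grad = Vc.T @ gw.mean(axis=0)
        if cfg.stage2_events and ev.any():
            eta_e = Ve @ g + w2e
            val += float(np.sum(log_expit(eta_e))) / K
            grad = grad + Ve.T @ (1.0 - expit(eta_e)).mean(axis=0)
        return -val, -grad

    res = minimize(negobj_and_grad, gamma0, jac=True, method="BFGS",
                   options={"maxiter": 80, "gtol": 1e-7})
    v_new = -res.fun
    v_old = -negobj_and_grad(np.asarray(gamma0, dtype=float))[0]
    return res.x if v_new >= v_old else np.asarray(gamma0, dtype=float)


# ---------------------------------------------------------------------------
# generic fit driver
# ---------------------------------------------------------------------------

def _fit(data, init, config, link):
    cfg = config or MCEMConfig()
    if not np.any(data.delta == 1):
        raise ValueError("estimation requires at least one observed event")
    rng = np.random.default_rng(cfg.seed)
    params = init if init is not None else default_init(data, link)
    params = replace(params, link=link) if params.link != link else params

    state = None
    hist = []
    converged = False
    prev_delta = np.inf
    n_iter = 0
    summ = None
    for it in range(cfg.max_iter):
        n_iter = it + 1
        summ, state = estep_draw_frailties(
            data, params, cfg, rng, state=state, first=(it == 0))
        if link == "logistic":
            beta, baseline = mstep_beta(data, summ, params.beta,
                                        mode=cfg.latency_mode)
            alpha = mstep_alpha_logistic(summ)
            gamma = _mstep_gamma_logistic_stage2(
                data, summ, params.gamma, beta, baseline, cfg)
        else:
            gamma = mstep_gamma(data, summ, params.gamma,
                                mode=cfg.incidence_mode)
            beta, baseline = mstep_beta(data, summ, params.beta,
                                        mode=cfg.latency_mode)
            if link == "cloglog":
                alpha = mstep_alpha_cloglog(summ)
            else:
                alpha = mstep_alpha_shared(summ)
        new = np.concatenate([gamma, beta, [np.log(alpha)]])
        old = np.concatenate([params.gamma, params.beta, [np.log(params.alpha)]])
        delta = float(np.max(np.abs(new - old)))
        hist.append(np.concatenate([gamma, beta, [alpha]]))
        params = ModelParams(beta=beta, gamma=gamma, alpha=alpha,
                             baseline=baseline, link=link)
        if delta < cfg.tol and prev_delta < cfg.tol:
            converged = True
            break
        prev_delta = delta

    hist_arr = np.asarray(hist)
    if not converged and len(hist) > 1:
        tail = hist_arr[-min(cfg.tail_avg, len(hist)):]
        avg = tail.mean(axis=0)
        q = data.q
        p = data.p
        params = ModelParams(beta=avg[q:q + p], gamma=avg[:q],
                             alpha=float(avg[-1]),
                             baseline=params.baseline, link=link)

    # final E-step at the reported parameters: Louis SEs, consistent baseline
    summ, state = estep_draw_frailties(data, params, cfg, rng,
                                       state=state, first=False)
    scores = summ.EUm * np.exp(data.Z @ params.beta)
    baseline = breslow_from_scores(data.gap, data.delta, scores)
    params = replace(params, baseline=baseline)

    flags = {}
    Ig = louis_information(data, summ, params, "gamma")
    se_g, f1 = _se_from_information(Ig)
    Ib = louis_information(data, summ, params, "beta")
    se_b, f2 = _se_from_information(Ib)
    Ia = louis_information(data, summ, params, "alpha")
    se_a, f3 = _se_from_information(Ia)
    flags["information_pseudo_inverse"] = bool(f1 or f2 or f3)

    ll = observed_data_loglik(data, params, cfg.loglik_draws, rng)
    n_par = data.p + data.q + 1
    aic = -2.0 * ll + 2.0 * n_par

    cols = ([f"gamma_{n}" for n in (data.v_names or range(data.q))]
            + [f"beta_{n}" for n in (data.z_names or range(data.p))]
            + ["alpha"])
    trace = pd.DataFrame(hist_arr, columns=cols)
    return FitResult(
        params=params,
        se_gamma=se_g,
        se_beta=se_b,
        se_alpha=float(se_a[0]),
        loglik=ll,
        aic=aic,
        n_iter=n_iter,
        converged=converged,
        trace=trace,
        accept_rate=summ.accept_rate,
        config=cfg,
        flags=flags,
    )


def fit_cloglog(data, init=None, config=None) -> FitResult:
    """MCEM fit of the clog-log dependent-frailty mixture cure model."""
    return _fit(data, init, config, "cloglog")


def fit_identical(data, init=None, config=None) -> FitResult:
    """MCEM fit of the shared (identical) frailty mixture cure model."""
    return _fit(data, init, config, "identical")


def fit_logistic(data, init=None, config=None) -> FitResult:
    """Two-stage iterative fit of the logistic-link dependent-frailty model."""
    return _fit(data, init, config, "logistic")
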