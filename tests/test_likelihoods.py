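"""Likelihood components against brute-force, hand-summed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recurcure.frailty import (
    CloglogFrailtyPairs,
    LogisticFrailtyPairs,
    cloglog_joint_logdensity,
    sample_cloglog_pairs,
    sample_shared_frailty,
    shared_loggamma_logdensity,
)
from recurcure.hazards import (
    ModelParams,
    WeibullBaseline,
    conditional_density,
    conditional_survival,
    noncure_probability,
)
from recurcure.likelihoods import (
    EStepSummaries,
    complete_data_loglik,
    expected_frailty_loglik_cloglog,
    expected_latency_loglik,
    logistic_approx_error_bound,
    logistic_censored_approx_loglik,
    logistic_stage1_loglik,
    logistic_stage2_loglik,
    mc_expected_incidence_loglik,
    posterior_noncure,
    shared_frailty_alpha_loglik,
)
from tests.conftest import make_data


def build_summaries(data, u1_draws, u2_draws, omega2_draws, ub_cens_draws):
    """Assemble an EStepSummaries container directly from draws."""
    cens_rows = np.flatnonzero(data.delta == 0)
    Em = u1_draws.mean(axis=0)
    Ubar = np.ones(data.n_records)
    EUm = Em[data.subject].copy()
    if cens_rows.size:
        Ubar[cens_rows] = ub_cens_draws.mean(axis=0)
        EUm[cens_rows] = (ub_cens_draws
                          * u1_draws[:, data.subject[cens_rows]]).mean(axis=0)
    with np.errstate(invalid="ignore"):
        elog2 = np.log(2 * u2_draws - u1_draws).mean(axis=0)
    return EStepSummaries(
        Ubar=Ubar, EUm=EUm, Em=Em, Elogm=np.log(u1_draws).mean(axis=0),
        u1_draws=u1_draws, u2_draws=u2_draws, omega2_draws=omega2_draws,
        cens_rows=cens_rows, Ubar_cens_draws=ub_cens_draws,
        Eu2=u2_draws.mean(axis=0), Elogu1=np.log(u1_draws).mean(axis=0),
        Elog2u2mu1=elog2,
    )


class TestCompleteDataLoglik:
    def test_term_by_term_oracle(self, tiny_data, weibull_params):
        data, params = tiny_data, weibull_params
        pairs = CloglogFrailtyPairs(u1=np.array([0.8, 1.4]),
                                    u2=np.array([0.9, 1.1]))
        U = np.array([1, 1, 1, 1, 0])
        got = complete_data_loglik(data, U, pairs, params)
        # brute force, record by record
        expected = 0.0
        for r in range(data.n_records):
            i = data.subject[r]
            eta = data.V[r] @ params.gamma + np.log(pairs.u2[i])
            pi = np.exp(-np.exp(eta))
            zb = data.Z[r] @ params.beta
            w1 = np.log(pairs.u1[i])
            expected += np.log(pi) if U[r] == 1 else np.log1p(-pi)
            if data.delta[r] == 1:
                expected += np.log(
                    conditional_density(data.gap[r], zb, w1, params.baseline))
            elif U[r] == 1:
                expected += np.log(
                    conditional_survival(data.gap[r], zb, w1, params.baseline))
        expected += cloglog_joint_logdensity(pairs.u1, pairs.u2,
                                             params.alpha).sum()
        assert got == pytest.approx(expected, abs=1e-10)

    def test_cured_censored_branch(self, weibull_params):
        data = make_data(gap=[1.0], delta=[0], z=[0.0], v=[0.0], subject=[1])
        pairs = CloglogFrailtyPairs(u1=np.array([1.0]), u2=np.array([1.0]))
        got = complete_data_loglik(data, np.array([0]), pairs, weibull_params)
        eta = weibull_params.gamma[0]
        expected = (np.log1p(-np.exp(-np.exp(eta)))
                    + cloglog_joint_logdensity(1.0, 1.0, weibull_params.alpha))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_subject_relabelling(self, weibull_params):
        gap = [0.5, 1.2, 2.0, 0.8, 3.0]
        delta = [1, 1, 0, 1, 0]
        z = [1.0, 1.0, 1.0, 0.0, 0.0]
        v = [0.0, 0.0, 0.0, 1.0, 1.0]
        d1 = make_data(gap, delta, z, v, subject=[1, 1, 1, 2, 2])
        d2 = make_data(gap[3:] + gap[:3], delta[3:] + delta[:3],
                       z[3:] + z[:3], v[3:] + v[:3],
                       subject=[1, 1, 2, 2, 2])
        p1 = CloglogFrailtyPairs(u1=np.array([0.8, 1.4]),
                                 u2=np.array([0.9, 1.1]))
        p2 = CloglogFrailtyPairs(u1=np.array([1.4, 0.8]),
                                 u2=np.array([1.1, 0.9]))
        U = np.array([1, 1, 1, 1, 0])
        U2 = np.array([1, 0, 1, 1, 1])
        assert complete_data_loglik(d1, U, p1, weibull_params) == pytest.approx(
            complete_data_loglik(d2, U2, p2, weibull_params), abs=1e-10)

    def test_event_with_U_zero_rejected(self, tiny_data, weibull_params):
        pairs = CloglogFrailtyPairs(u1=np.ones(2), u2=np.ones(2))
        with pytest.raises(ValueError):
            complete_data_loglik(tiny_data, np.zeros(5, dtype=int), pairs,
                                 weibull_params)


class TestPosteriorNoncure:
    def test_event_is_always_one(self):
        assert posterior_noncure(1, 0.01, 0.5) == 1.0

    def test_no_information_at_time_zero(self):
        assert posterior_noncure(0, 0.37, 1.0) == pytest.approx(0.37)

    def test_bayes_two_component_oracle(self):
        # pi = 0.4, S1 = 0.25: 0.1 / 0.7, versus explicit enumeration
        got = posterior_noncure(0, 0.4, 0.25)
        num = 0.4 * 0.25
        den = 0.6 * 1.0 + 0.4 * 0.25
        assert got == pytest.approx(num / den, abs=1e-12)
        assert got == pytest.approx(1 / 7, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6),
           st.floats(min_value=0, max_value=1),
           st.floats(min_value=0, max_value=1))
    def test_monotone_in_survival(self, pi, s_lo, s_hi):
        # longer event-free time -> smaller S1 -> smaller posterior non-cure
        lo, hi = sorted((s_lo, s_hi))
        assert (posterior_noncure(0, pi, lo)
                <= posterior_noncure(0, pi, hi) + 1e-12)


class TestExpectedIncidence:
    def _single_cens(self):
        data = make_data(gap=[1.0], delta=[0], z=[0.0], v=[1.0], subject=[1])
        u2 = np.array([[0.7]])
        summ = build_summaries(data, np.array([[1.0]]), u2, np.log(u2),
                               np.array([[0.5]]))
        return data, summ

    def test_hand_value_single_record(self):
        data, summ = self._single_cens()
        gamma = np.array([0.2, -0.4])
        eta = 0.2 - 0.4 + np.log(0.7)
        pi = np.exp(-np.exp(eta))
        printed = (0.5 * np.log1p(-pi) + 0.5 * np.log(pi) - pi)
        assert mc_expected_incidence_loglik(
            data, summ, gamma, mode="double_weighted") == pytest.approx(printed)
        binom = 0.5 * np.log(pi) + 0.5 * np.log1p(-pi)
        assert mc_expected_incidence_loglik(
            data, summ, gamma, mode="binomial") == pytest.approx(binom)

    def test_modes_differ_by_event_double_count(self):
        data = make_data(gap=[0.5, 0.8], delta=[1, 1], z=[0, 0], v=[1, 0],
                         subject=[1, 2])
        K = 4
        rng = np.random.default_rng(3)
        u2 = rng.gamma(2, 0.5, size=(K, 2))
        summ = build_summaries(data, np.ones((K, 2)), u2, np.log(u2),
                               np.zeros((K, 0)))
        gamma = np.array([0.1, 0.3])
        eta = data.V @ gamma + np.log(u2)[:, data.subject]
        extra = np.sum(-np.exp(eta)) / K   # sum_k sum_delta log pi^k / K
        printed = mc_expected_incidence_loglik(data, summ, gamma,
                                               mode="double_weighted")
        binom = mc_expected_incidence_loglik(data, summ, gamma,
                                             mode="binomial")
        assert printed - binom == pytest.approx(extra, abs=1e-10)

    def test_linearity_in_draws(self, small_cure_dataset):
        data = small_cure_dataset.data
        K = 6
        rng = np.random.default_rng(5)
        pr = sample_cloglog_pairs(1.2, K * data.n_subjects, rng)
        u1 = pr.u1.reshape(K, -1)
        u2 = pr.u2.reshape(K, -1)
        ncens = (data.delta == 0).sum()
        ub = rng.uniform(0, 1, size=(K, ncens))
        summ = build_summaries(data, u1, u2, np.log(u2), ub)
        gamma = np.array([0.4, -0.6])
        full = mc_expected_incidence_loglik(data, summ, gamma, mode="binomial")
        singles = []
        for k in range(K):
            s1 = build_summaries(data, u1[[k]], u2[[k]], np.log(u2[[k]]),
                                 ub[[k]])
            singles.append(mc_expected_incidence_loglik(
                data, s1, gamma, mode="binomial"))
        assert full == pytest.approx(np.mean(singles), abs=1e-8)

    def test_mc_variance_scales_inverse_K(self, tiny_data):
        data = tiny_data
        gamma = np.array([0.2, 0.1])
        rng = np.random.default_rng(8)
        var = {}
        for K in (10, 1000):
            vals = []
            for _ in range(60):
                pr = sample_cloglog_pairs(1.0, K * 2, rng)
                u1 = pr.u1.reshape(K, 2)
                u2 = pr.u2.reshape(K, 2)
                ub = np.full((K, 2), 0.5)
                summ = build_summaries(data, u1, u2, np.log(u2), ub)
                vals.append(mc_expected_incidence_loglik(
                    data, summ, gamma, mode="binomial"))
            var[K] = np.var(vals)
        ratio = var[10] / var[1000]
        assert 25 < ratio < 400  # ~100, with slack for estimation noise


class TestExpectedLatency:
    def test_hand_oracle_single_event(self):
        data = make_data(gap=[1.0], delta=[1], z=[1.0], v=[0.0], subject=[1])
        base = WeibullBaseline(scale=1.0, shape=1.5)
        summ = build_summaries(data, np.array([[1.0]]), np.array([[1.0]]),
                               np.zeros((1, 1)), np.zeros((1, 0)))
        beta = np.array([0.5])
        got = expected_latency_loglik(data, summ, beta, base)
        expected = np.log(1.5) + 0.5 - 1.0 * np.exp(0.5) + 0.0
        assert got == pytest.approx(expected, abs=1e-12)

    def test_unit_frailty_reduces_to_cox_objective(self, nocure_dataset):
        data = nocure_dataset.data
        N = data.n_subjects
        summ = build_summaries(data, np.ones((1, N)), np.ones((1, N)),
                               np.zeros((1, N)),
                               np.ones((1, (data.delta == 0).sum())))
        base = WeibullBaseline(scale=1.0, shape=1.5)
        beta = np.array([-0.8])
        got = expected_latency_loglik(data, summ, beta, base, mode="extended")
        ev = data.delta == 1
        cum = base.cumulative(data.gap)
        zb = data.Z @ beta
        expected = (np.sum(np.log(base.hazard_at(data.gap[ev]))) +
                    np.sum(zb[ev]) - np.sum(cum * np.exp(zb)))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_beta_zero_ignores_covariates(self, tiny_data):
        data = tiny_data
        base = WeibullBaseline(scale=1.0, shape=1.5)
        summ = build_summaries(data, np.ones((1, 2)), np.ones((1, 2)),
                               np.zeros((1, 2)), np.full((1, 2), 0.3))
        v1 = expected_latency_loglik(data, summ, np.zeros(1), base)
        shuffled = make_data(gap=data.gap.tolist(),
                             delta=data.delta.tolist(),
                             z=[0.0, 1.0, 0.0, 1.0, 1.0],
                             v=data.V[:, 1].tolist(),
                             subject=data.subject_labels.tolist())
        v2 = expected_latency_loglik(shuffled, summ, np.zeros(1), base)
        assert v1 == pytest.approx(v2)


class TestExpectedFrailtyBlocks:
    def test_cloglog_draw_average_oracle(self):
        rng = np.random.default_rng(11)
        K, N, alpha = 7, 40, 1.3
        pr = sample_cloglog_pairs(1.5, K * N, rng)
        u1 = pr.u1.reshape(K, N)
        u2 = pr.u2.reshape(K, N)
        val = expected_frailty_loglik_cloglog(
            np.log(u1).mean(axis=0),
            np.log(2 * u2 - u1).mean(axis=0),
            u2.mean(axis=0), alpha)
        direct = cloglog_joint_logdensity(u1, u2, alpha).sum(axis=1).mean()
        assert val == pytest.approx(direct, abs=1e-9)

    def test_maximizer_recovers_generating_alpha(self):
        from scipy.optimize import minimize_scalar
        pr = sample_cloglog_pairs(1.5, 2 * 10 ** 5, seed=12)
        u1 = pr.u1[None, :]
        u2 = pr.u2[None, :]
        res = minimize_scalar(
            lambda la: -expected_frailty_loglik_cloglog(
                np.log(u1).mean(0), np.log(2 * u2 - u1).mean(0),
                u2.mean(0), np.exp(la)),
            bounds=(-3, 3), method="bounded")
        assert np.exp(res.x) == pytest.approx(1.5, abs=0.02)

    def test_concave_in_alpha(self):
        pr = sample_cloglog_pairs(1.5, 5000, seed=13)
        u1, u2 = pr.u1[None, :], pr.u2[None, :]
        args = (np.log(u1).mean(0), np.log(2 * u2 - u1).mean(0), u2.mean(0))
        grid = np.linspace(0.2, 50.0, 60)
        vals = np.array([expected_frailty_loglik_cloglog(*args, a)
                         for a in grid])
        second = np.diff(vals, 2)
        assert np.all(second < 0)

    def test_shared_draw_average_oracle(self):
        # the printed block is the gamma density of u (it differs from the
        # log-gamma density of omega = log u by an alpha-free Jacobian term)
        from scipy import stats as sps
        rng = np.random.default_rng(14)
        K, N, alpha = 5, 30, 2.2
        u = sample_shared_frailty(1.5, K * N, rng).reshape(K, N)
        val = shared_frailty_alpha_loglik(u.mean(axis=0),
                                          np.log(u).mean(axis=0), alpha)
        direct = sps.gamma.logpdf(u, alpha, scale=1 / alpha).sum(axis=1).mean()
        assert val == pytest.approx(direct, abs=1e-9)
        # and the omega-scale version differs by exactly sum E[log u]
        omega_version = shared_loggamma_logdensity(
            np.log(u), alpha).sum(axis=1).mean()
        assert val == pytest.approx(
            omega_version - np.log(u).mean(axis=0).sum(), abs=1e-9)

    def test_shared_alpha_one_value(self):
        Eu = np.array([0.5, 1.5, 2.0])
        Elogu = np.array([-0.1, 0.2, 0.4])
        assert shared_frailty_alpha_loglik(Eu, Elogu, 1.0) == pytest.approx(
            -Eu.sum())

    def test_shared_maximizer_recovery(self):
        from scipy.optimize import minimize_scalar
        u = sample_shared_frailty(1.5, 2 * 10 ** 5, seed=15)
        res = minimize_scalar(
            lambda la: -shared_frailty_alpha_loglik(
                np.array([u.mean()]) * np.ones(1),
                np.array([np.log(u).mean()]), np.exp(la)),
            bounds=(-3, 3), method="bounded")
        assert np.exp(res.x) == pytest.approx(1.5, abs=0.03)


class TestLogisticStageObjectives:
    def _setup(self):
        data = make_data(gap=[0.5, 1.5, 0.9, 2.0], delta=[1, 0, 1, 0],
                         z=[1, 1, 0, 0], v=[1, 1, 0, 0], subject=[1, 1, 2, 2])
        pairs = LogisticFrailtyPairs(u1=np.array([1.6, 2.2]),
                                     u2=np.array([0.4, 0.6]))
        base = WeibullBaseline(scale=1.0, shape=1.5)
        return data, pairs, base

    def test_no_cure_censored_terms_vanish(self):
        data, pairs, base = self._setup()
        # gamma -> -inf makes pi -> 0; censored contribution -> 0
        lo = logistic_censored_approx_loglik(
            data, np.array([-40.0, 0.0]), np.array([0.2]), base, pairs)
        ev_only = logistic_censored_approx_loglik(
            data, np.array([-40.0, 0.0]), np.array([0.2]), base, pairs,
            exact=True)
        assert lo == pytest.approx(ev_only, abs=1e-10)

    def test_approximation_within_stated_bound(self):
        data, pairs, base = self._setup()
        g = np.array([0.3, 0.5])
        b = np.array([0.2])
        approx = logistic_censored_approx_loglik(data, g, b, base, pairs)
        exact = logistic_censored_approx_loglik(data, g, b, base, pairs,
                                                exact=True)
        eta = data.V @ g + pairs.omega2[data.subject]
        pi = noncure_probability("logistic", eta)
        m = pairs.u1 * pairs.u2
        S1 = np.exp(-base.cumulative(data.gap)
                    * np.exp(data.Z @ b) * m[data.subject])
        bound = logistic_approx_error_bound(pi, S1)[data.delta == 0].sum()
        assert abs(approx - exact) <= bound + 1e-12

    def test_event_terms_are_conditional_density_logs(self):
        data, pairs, base = self._setup()
        g = np.array([0.3, 0.5])
        b = np.array([0.2])
        val = logistic_censored_approx_loglik(
            data, np.array([-40.0, 0.0]), b, base, pairs)
        m = pairs.u1 * pairs.u2
        ev = data.delta == 1
        expect = sum(
            np.log(conditional_density(data.gap[r], data.Z[r] @ b,
                                       np.log(m[data.subject[r]]), base))
            for r in np.flatnonzero(ev))
        assert val == pytest.approx(expect, abs=1e-10)

    def test_stage1_equals_event_terms_plus_conditional_prior(self):
        from recurcure.frailty import conditional_loggamma_logdensity
        data, pairs, base = self._setup()
        b, alpha = np.array([0.2]), 0.8
        got = logistic_stage1_loglik(data, b, alpha, base, pairs)
        ev_terms = logistic_censored_approx_loglik(
            data, np.array([-40.0, 0.0]), b, base, pairs)
        prior = conditional_loggamma_logdensity(
            pairs.omega2, pairs.omega1, alpha).sum()
        assert got == pytest.approx(ev_terms + prior, abs=1e-10)

    def test_stage2_hand_oracle_and_monotonicity(self):
        from recurcure.frailty import logistic_marginal_omega1_logdensity
        data, pairs, base = self._setup()
        b0, a0 = np.array([0.2]), 0.8
        g = np.array([0.1, -0.2])
        got = logistic_stage2_loglik(data, g, b0, a0, base, pairs)
        eta = data.V @ g + pairs.omega2[data.subject]
        pi = noncure_probability("logistic", eta)
        m = pairs.u1 * pairs.u2
        S1 = np.exp(-base.cumulative(data.gap)
                    * np.exp(data.Z @ b0) * m[data.subject])
        cens = data.delta == 0
        expect = (np.sum(-pi[cens] * (1 - S1[cens]))
                  + logistic_marginal_omega1_logdensity(
                      pairs.omega1, a0).sum())
        assert got == pytest.approx(expect, abs=1e-10)
        # printed form is monotone decreasing in pi (larger gamma0 -> lower)
        lower = logistic_stage2_loglik(data, g + np.array([1.0, 0.0]),
                                       b0, a0, base, pairs)
        assert lower < got

    def test_stage2_all_events_depends_only_on_prior(self):
        from recurcure.frailty import logistic_marginal_omega1_logdensity
        data = make_data(gap=[0.5, 0.9], delta=[1, 1], z=[1, 0], v=[1, 0],
                         subject=[1, 2])
        pairs = LogisticFrailtyPairs(u1=np.array([1.6, 2.2]),
                                     u2=np.array([0.4, 0.6]))
        base = WeibullBaseline(scale=1.0, shape=1.5)
        got = logistic_stage2_loglik(data, np.array([3.0, -1.0]),
                                     np.array([0.2]), 0.8, base, pairs)
        assert got == pytest.approx(
            logistic_marginal_omega1_logdensity(pairs.omega1, 0.8).sum())
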