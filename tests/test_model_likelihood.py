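"""Linear predictors, transition probabilities, and the marginal likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import logsumexp

import mcistates as m
from mcistates.model import (
    ModelParams,
    PairData,
    QuadratureRule,
    _fe_nll_grad,
    _gh_nll_grad,
    _laplace_nll_grad,
    _log_prior,
    _loglik_by_subject,
    _marginal_by_subject,
)
from mcistates.states import State

X0 = {c: 0.0 for c in m.model.NORMAL_COVARIATES}


class TestLinearPredictors:
    def test_all_zero_parameters_give_zero_logits(self):
        params = ModelParams.zeros()
        eta = m.linear_predictors(X0, State.NORMAL, params, u=0.0)
        assert (eta == 0).all()
        assert len(eta) == 6

    def test_age_coefficient_maps_rr_to_logit(self):
        # one year above the centring age with RR 1.12 for clinical MCI
        params = ModelParams.zeros()
        params.beta_normal[1, 2] = math.log(1.12)  # age row, MCI_CC column
        x = dict(X0, age_c=1.0)
        eta = m.linear_predictors(x, State.NORMAL, params)
        assert eta[State.MCI_CC] == pytest.approx(0.1133, abs=5e-4)
        assert eta[State.AMCI_TB] == 0.0

    def test_shared_effect_shifts_every_nonreference_logit(self):
        params = ModelParams.zeros()
        eta = m.linear_predictors(X0, State.NORMAL, params, u=0.7)
        assert eta[State.NORMAL] == 0.0
        assert (eta.drop(State.NORMAL) == 0.7).all()

    def test_cc_base_has_three_categories_and_no_prior_indicators(self):
        params = ModelParams.zeros()
        eta = m.linear_predictors(X0, State.MCI_CC, params)
        assert list(eta.index) == [State.MCI_CC, State.DEMENTIA, State.DEATH]

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError, match="base"):
            m.linear_predictors(X0, State.DEMENTIA, ModelParams.zeros())


class TestTransitionProbs:
    def test_uniform_under_null_parameters(self):
        p = m.transition_probs(X0, State.NORMAL, ModelParams.zeros())
        np.testing.assert_allclose(p.to_numpy(), 1.0 / 6.0)

    def test_matches_direct_exp_normalisation(self):
        params = ModelParams.zeros()
        params.beta_normal[0] = [0.0, math.log(2.0), -1.0, 0.5, -0.3]
        p = m.transition_probs(X0, State.NORMAL, params)
        eta = np.concatenate([[0.0], params.beta_normal[0]])
        np.testing.assert_allclose(p.to_numpy(), np.exp(eta) / np.exp(eta).sum(), atol=1e-14)

    @given(
        betas=st.lists(st.floats(-5, 5), min_size=5, max_size=5),
        u=st.floats(-3, 3),
        age=st.floats(-15, 15),
    )
    def test_probabilities_sum_to_one(self, betas, u, age):
        params = ModelParams.zeros(sigma_u=0.0)
        params.beta_normal[0] = betas
        params.beta_normal[1] = np.linspace(-0.2, 0.2, 5)
        x = dict(X0, age_c=age)
        for base in (State.NORMAL, State.MCI_CC):
            p = m.transition_probs(x, base, params, u)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert (p >= 0).all()

    def test_shift_invariance_of_softmax(self):
        params = ModelParams.zeros()
        params.beta_normal[0] = [1.0, -1.0, 0.5, 0.2, -0.5]
        p1 = m.transition_probs(X0, State.NORMAL, params, u=0.0)
        p2 = m.transition_probs(X0, State.NORMAL, params, u=2.5)
        # u shifts all non-reference logits: equivalent to reweighting vs base only
        assert p1.sum() == pytest.approx(1.0) and p2.sum() == pytest.approx(1.0)


def _toy_pairs(seed=5, n_subjects=3):
    spec = m.CohortSpec(seed=seed, n_subjects=n_subjects, params=m.default_true_params(0.5))
    return m.build_pairs(m.simulate_cohort(spec))


class TestSubjectLoglik:
    def test_single_pair_uniform_model(self):
        pairs = pd.DataFrame(
            [{"subject": 0, "prior": State.NORMAL, "current": State.AMCI_TB,
              "base": State.NORMAL, "interval": 1.0, **X0}]
        )
        ll = m.subject_loglik(pairs, ModelParams.zeros(), u=0.0)
        assert ll == pytest.approx(math.log(1.0 / 6.0))

    def test_markov_factorisation_equals_brute_force_product(self):
        params = m.default_true_params(0.5)
        spec = m.CohortSpec(seed=21, n_subjects=30, params=params)
        trajs = m.simulate_cohort(spec)
        traj = max(trajs, key=lambda t: t.n_visits)
        pairs = m.build_pairs([traj])
        u = 0.37
        ll = m.subject_loglik(pairs, params, u)
        brute = 0.0  # explicit per-pair product via the single-pair API
        for _, row in pairs.iterrows():
            x = {c: row[c] for c in m.model.NORMAL_COVARIATES}
            p = m.transition_probs(x, State(row["base"]), params, u)
            brute += math.log(p[State(row["current"])])
        assert ll == pytest.approx(brute, abs=1e-12)

    def test_two_subjects_rejected(self):
        pairs = pd.DataFrame(
            [
                {"subject": 0, "prior": State.NORMAL, "current": State.NORMAL,
                 "base": State.NORMAL, "interval": 1.0, **X0},
                {"subject": 1, "prior": State.NORMAL, "current": State.NORMAL,
                 "base": State.NORMAL, "interval": 1.0, **X0},
            ]
        )
        with pytest.raises(ValueError, match="single subject"):
            m.subject_loglik(pairs, ModelParams.zeros(), 0.0)

    def test_structurally_impossible_pair_rejected(self):
        pairs = pd.DataFrame(
            [{"subject": 0, "prior": State.MCI_CC, "current": State.NORMAL,
              "base": State.MCI_CC, "interval": 1.0, **X0}]
        )
        with pytest.raises(ValueError, match="impossible"):
            m.subject_loglik(pairs, ModelParams.zeros(), 0.0)


class TestMarginalLoglik:
    def test_sigma_zero_collapses_to_fixed_effects_for_any_rule(self):
        pairs = _toy_pairs(seed=5, n_subjects=10)
        params = m.default_true_params(0.0)
        fe = sum(
            m.subject_loglik(pairs[pairs["subject"] == s], params, 0.0)
            for s in pairs["subject"].unique()
        )
        for rule in (QuadratureRule(1, True), QuadratureRule(7, False), QuadratureRule(15, True)):
            assert m.marginal_loglik(pairs, params, rule) == pytest.approx(fe, abs=1e-10)

    def test_gauss_hermite_matches_dense_trapezoid_integration(self):
        pairs = _toy_pairs(seed=5, n_subjects=3)
        params = m.default_true_params(0.5)
        data = PairData.from_pairs(pairs)
        per_gh, _ = _marginal_by_subject(data, params, QuadratureRule(20, adaptive=False))

        grid = np.linspace(-8 * params.sigma_u, 8 * params.sigma_u, 10001)
        dense = np.array(
            [
                _loglik_by_subject(data, params, np.full(data.n_subjects, ui))
                + _log_prior(np.full(data.n_subjects, ui), params.sigma_u)
                for ui in grid
            ]
        )
        log_trap = logsumexp(dense, axis=0) + math.log(grid[1] - grid[0])
        np.testing.assert_allclose(per_gh, log_trap, atol=1e-6)

    def test_one_point_adaptive_close_to_twenty_point(self):
        """Quantifies the error of the Laplace-style 1-point approximation."""
        pairs = _toy_pairs(seed=8, n_subjects=60)
        params = m.default_true_params(0.5)
        ll1 = m.marginal_loglik(pairs, params, QuadratureRule(1, adaptive=True))
        ll20 = m.marginal_loglik(pairs, params, QuadratureRule(20, adaptive=True))
        assert abs(ll1 - ll20) / abs(ll20) < 0.005

    def test_quadrature_is_cauchy_in_node_count(self):
        pairs = _toy_pairs(seed=5, n_subjects=3)
        params = m.default_true_params(0.5)
        values = [m.marginal_loglik(pairs, params, QuadratureRule(q, False)) for q in range(1, 31)]
        diffs = np.abs(np.diff(values))
        assert diffs[-1] < 1e-6
        assert max(diffs[-5:]) < 1e-6
        # broadly decreasing: each late difference far below the early ones
        assert max(diffs[-10:]) < max(diffs[:5]) + 1e-12


def _perturbed_theta(template, sigma=0.4, seed=0):
    rng = np.random.default_rng(seed)
    n_beta = template.beta_normal.size + template.beta_cc.size
    return np.append(rng.normal(0.0, 0.2, n_beta), math.log(sigma))


@pytest.fixture(scope="module")
def data():
    return PairData.from_pairs(_toy_pairs(seed=11, n_subjects=40))


class TestAnalyticGradients:
    """The closed-form scores must match central finite differences."""

    def test_fixed_effects_score(self, data):
        template = ModelParams.zeros()
        theta = _perturbed_theta(template)[:-1]
        _, g = _fe_nll_grad(theta, data, template)
        for j in range(0, len(theta), 7):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            num = (_fe_nll_grad(tp, data, template)[0] - _fe_nll_grad(tm, data, template)[0]) / (2 * h)
            assert g[j] == pytest.approx(num, abs=1e-5 * (1 + abs(num)))

    def test_laplace_score_including_mode_dependence(self, data):
        template = ModelParams.zeros()
        theta = _perturbed_theta(template)
        _, g = _laplace_nll_grad(theta, data, template, {})
        for j in list(range(0, len(theta), 6)) + [len(theta) - 1]:
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            num = (
                _laplace_nll_grad(tp, data, template, {})[0]
                - _laplace_nll_grad(tm, data, template, {})[0]
            ) / (2 * h)
            assert g[j] == pytest.approx(num, abs=2e-5 * (1 + abs(num)))

    def test_gauss_hermite_score(self, data):
        template = ModelParams.zeros()
        theta = _perturbed_theta(template)
        rule = QuadratureRule(9, adaptive=False)
        _, g = _gh_nll_grad(theta, data, template, rule)
        for j in [0, 5, 17, 33, 50, len(theta) - 1]:
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            num = (
                _gh_nll_grad(tp, data, template, rule)[0] - _gh_nll_grad(tm, data, template, rule)[0]
            ) / (2 * h)
            assert g[j] == pytest.approx(num, abs=2e-5 * (1 + abs(num)))
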