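"""Latent-class membership, likelihood, estimation, and inference."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import latentrules as lr
from latentrules.mixture import _loglik_parts, _segment_draws

from conftest import make_panel


def two_seg_spec(attrs=("a0", "a1")):
    return lr.ModelSpec(
        segments=(lr.SegmentSpec("RRM", attrs), lr.SegmentSpec("RUM", attrs)),
        membership_covariates=("intercept", "female"))


# ---------------------------------------------------------------------------
# membership probabilities


def test_membership_uniform_when_gamma_zero():
    z = np.ones((4, 2))
    spec = two_seg_spec()
    P = lr.membership_probabilities(z, {1: np.zeros(2)}, spec)
    np.testing.assert_allclose(P, 0.5, atol=1e-12)


def test_membership_hand_logistic():
    """Constant 0.892, female coefficient 0.869: male -> P(non-base) = expit(0.892)."""
    spec = two_seg_spec()
    z = np.array([[1.0, 0.0], [1.0, 1.0]])  # male, female
    P = lr.membership_probabilities(z, {1: np.array([0.892, 0.869])}, spec)
    assert P[0, 1] == pytest.approx(expit(0.892))
    assert P[0, 1] == pytest.approx(0.709, abs=5e-4)
    assert P[1, 1] == pytest.approx(expit(0.892 + 0.869))
    np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)


def test_membership_single_segment_is_one():
    spec = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", ("a0",)),))
    P = lr.membership_probabilities(np.ones((3, 1)), {}, spec)
    np.testing.assert_array_equal(P, 1.0)


# ---------------------------------------------------------------------------
# unconditional log-likelihood


def test_null_model_loglik_closed_form():
    C = 7
    panel = make_panel(C=C, K=5, I=3, M=2, seed=0)
    spec = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", ("a0", "a1")),))
    params = lr.ParameterSet(gamma={}, beta=[np.zeros(2)], log_spread=[np.array([])])
    LL = lr.unconditional_loglik(panel, spec, params)
    assert LL == pytest.approx(-5 * C * math.log(3), rel=1e-12)


def test_mixture_collapses_with_identical_segments():
    panel = make_panel(C=5, K=3, I=3, M=2, seed=1)
    beta = np.array([0.7, -0.4])
    one = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", ("a0", "a1")),))
    LL1 = lr.unconditional_loglik(
        panel, one, lr.ParameterSet(gamma={}, beta=[beta], log_spread=[np.array([])]))
    two = two_seg_spec()
    # identical RUM kernels in both segments (rule field differs but use RUM twice)
    two_rum = lr.ModelSpec(
        segments=(lr.SegmentSpec("RUM", ("a0", "a1")), lr.SegmentSpec("RUM", ("a0", "a1"))),
        membership_covariates=("intercept", "female"))
    params = lr.ParameterSet(gamma={1: np.array([1.3, -0.6])},
                             beta=[beta, beta], log_spread=[np.array([])] * 2)
    LL2 = lr.unconditional_loglik(panel, two_rum, params)
    assert LL2 == pytest.approx(LL1, rel=1e-12)


def test_loglik_matches_bruteforce_enumeration():
    """Explicit loop over segments and scenarios on a 3-respondent fixture."""
    panel = make_panel(C=3, K=2, I=3, M=2, seed=2)
    spec = two_seg_spec()
    params = lr.ParameterSet(
        gamma={1: np.array([0.3, -0.8])},
        beta=[np.array([-1.0, 0.5]), np.array([0.7, -0.2])],
        log_spread=[np.array([])] * 2)
    LL = lr.unconditional_loglik(panel, spec, params)

    expected = 0.0
    for c in range(3):
        pcs = lr.membership_probabilities(panel.z[c:c + 1], params.gamma, spec)[0]
        tot = 0.0
        for s, seg in enumerate(spec.segments):
            lc = 1.0
            for k in range(2):
                if seg.rule == "RRM":
                    p = lr.rrm_probabilities(lr.rrm_regret(panel, params.beta[s],
                                                           seg.attributes))
                else:
                    p = lr.mnl_probabilities(lr.rum_utilities(panel, params.beta[s],
                                                              seg.attributes))
                lc *= p[c, k, panel.chosen[c, k]]
            tot += pcs[s] * lc
        expected += math.log(tot)
    assert LL == pytest.approx(expected, abs=1e-10)


def test_analytic_gradient_matches_finite_differences():
    panel = make_panel(C=6, K=3, I=3, M=2, seed=3)
    spec = lr.ModelSpec(
        segments=(lr.SegmentSpec("RRM", ("a0", "a1")),
                  lr.SegmentSpec("RUM", ("a0", "a1"), random_attributes=("a1",))),
        membership_covariates=("intercept", "female"))
    layout = lr.ParameterLayout(spec)
    rng = np.random.default_rng(4)
    draws = _segment_draws(panel, spec, 20, 5)
    for _ in range(3):
        vec = rng.normal(scale=0.5, size=layout.n_params)
        _, g, _, _ = _loglik_parts(panel, spec, layout.unflatten(vec), draws, True)
        fd = np.zeros_like(vec)
        for j in range(vec.size):
            h = 1e-6 * (1 + abs(vec[j]))
            vp, vm = vec.copy(), vec.copy()
            vp[j] += h
            vm[j] -= h
            fd[j] = (_loglik_parts(panel, spec, layout.unflatten(vp), draws, False)[0]
                     - _loglik_parts(panel, spec, layout.unflatten(vm), draws, False)[0]) / (2 * h)
        np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-8)


# ---------------------------------------------------------------------------
# posteriors and shares


def test_posterior_bayes_arithmetic():
    """Equal priors with conditional likelihoods (0.008, 0.002) -> (0.8, 0.2)."""
    joint = np.log(np.array([[0.5 * 0.008, 0.5 * 0.002]]))
    post = np.exp(joint - np.log(np.exp(joint).sum()))
    np.testing.assert_allclose(post, [[0.8, 0.2]], atol=1e-12)


def test_population_shares_examples():
    P = np.array([[0.2, 0.8], [0.6, 0.4]])
    np.testing.assert_allclose(lr.population_shares(P), [0.4, 0.6], atol=1e-12)
    np.testing.assert_allclose(lr.population_shares(np.full((9, 3), 1 / 3)),
                               [1 / 3] * 3, atol=1e-12)


# ---------------------------------------------------------------------------
# estimation


def independent_mnl_loglik_fit(panel, attrs):
    """Textbook conditional-logit MLE via a plain per-observation loop."""
    idx = [panel.attribute_names.index(a) for a in attrs]

    def nll(beta):
        tot = 0.0
        for c in range(panel.n_respondents):
            for k in range(panel.n_scenarios):
                u = panel.x[c, k][:, idx] @ beta
                u = u - u.max()
                tot -= u[panel.chosen[c, k]] - math.log(np.exp(u).sum())
        return tot

    res = minimize(nll, np.zeros(len(attrs)), method="BFGS")
    return res.x, -res.fun


def test_single_segment_rum_matches_textbook_mnl():
    panel = make_panel(C=40, K=5, I=3, M=2, seed=5)
    spec = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", ("a0", "a1")),))
    result = lr.estimate(panel, spec, n_starts=1)
    beta_ref, ll_ref = independent_mnl_loglik_fit(panel, ("a0", "a1"))
    np.testing.assert_allclose(result.params.beta[0], beta_ref, atol=1e-6)
    assert result.loglik == pytest.approx(ll_ref, abs=1e-6)


def test_single_segment_recovery_simulation_study():
    """S=1 RUM simulation study: the estimate recovers the generating
    coefficients within sampling error (joint Wald test at the 1% level)."""
    attrs = ("grade_steep", "travel_time", "mean_exposure")
    spec = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", attrs),))
    truth = np.array([-1.5, -0.08, -0.06])
    params = lr.ParameterSet(gamma={}, beta=[truth], log_spread=[np.array([])])
    panel = lr.simulate_panel(
        lr.DesignConfig(n_respondents=2000, seed=8),
        lr.TruthConfig(spec=spec, params=params, seed=9))
    res = lr.estimate(panel, spec, n_starts=1)
    assert res.converged and res.inference_ok
    z = (res.params.beta[0] - truth) / res.std_errors
    wald = float(z @ z)
    assert wald < 11.34, z  # chi2(3) 99th percentile
    # MLE dominates the generating parameters on the same data
    assert res.loglik >= lr.unconditional_loglik(panel, spec, params)


def test_estimator_sklearn_surface(small_panel):
    spec = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", ("a0", "a1")),))
    model = lr.LatentClassChoiceModel(spec=spec, n_starts=1)
    assert model.get_params()["n_starts"] == 1
    model.set_params(n_starts=2).set_params(n_starts=1)
    fitted = model.fit(small_panel)
    assert fitted is model
    assert hasattr(model, "loglik_") and model.shares_.sum() == pytest.approx(1.0)
    proba = model.predict_proba(small_panel)
    np.testing.assert_allclose(proba.sum(axis=-1), 1.0, atol=1e-12)
    assert model.score(small_panel) == pytest.approx(model.loglik_ / 3)
    with pytest.raises(ValueError):
        model.set_params(bogus=1)


def test_label_switching_symmetry_and_canonical_order(two_class_panel):
    """Swapping same-rule segments with matching parameter swaps leaves LL
    unchanged; reported order is deterministic (RRM first, share-descending)."""
    panel = two_class_panel
    attrs = ("grade_steep", "travel_time")
    spec = lr.ModelSpec(
        segments=(lr.SegmentSpec("RRM", attrs), lr.SegmentSpec("RRM", attrs)),
        membership_covariates=("intercept",))
    b1, b2 = np.array([-2.0, -0.2]), np.array([-0.5, -0.05])
    params = lr.ParameterSet(gamma={1: np.array([0.4])}, beta=[b1, b2],
                             log_spread=[np.array([])] * 2)
    swapped = lr.ParameterSet(gamma={1: np.array([-0.4])}, beta=[b2, b1],
                              log_spread=[np.array([])] * 2)
    LL = lr.unconditional_loglik(panel, spec, params)
    LLs = lr.unconditional_loglik(panel, spec, swapped)
    assert LL == pytest.approx(LLs, rel=1e-12)

    res = lr.estimate(panel, spec, n_starts=2, seed=0)
    assert [s.rule for s in res.spec.segments] == ["RRM", "RRM"]
    assert res.shares[0] >= res.shares[1]  # canonical: descending share in rule
    assert res.spec.base_segment == 0


def test_posteriors_and_shares_are_simplexes(two_class_panel, two_class_truth):
    res = lr.estimate(two_class_panel, two_class_truth.spec, n_starts=2, seed=5)
    np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-9)
    assert res.shares.sum() == pytest.approx(1.0, abs=1e-9)
    post = lr.posterior_segments(res, two_class_panel)
    np.testing.assert_allclose(post, res.posteriors, atol=1e-9)
    assert res.fit.loglik == res.loglik


def test_extra_zero_segment_never_decreases_loglik():
    panel = make_panel(C=30, K=5, I=3, M=2, seed=12)
    one = lr.ModelSpec(segments=(lr.SegmentSpec("RUM", ("a0", "a1")),))
    two = lr.ModelSpec(
        segments=(lr.SegmentSpec("RUM", ("a0", "a1")),) * 2,
        membership_covariates=("intercept",))
    r1 = lr.estimate(panel, one, n_starts=1)
    r2 = lr.estimate(panel, two, n_starts=2, seed=1)
    assert r2.loglik >= r1.loglik - 1e-4  # nesting, up to optimizer tolerance
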