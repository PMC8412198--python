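"""GP marginal likelihood, posterior prediction, fitting and grammar search."""

import numpy as np
import pytest

from patcomm.gp import (
    JITTER,
    GPModel,
    GPResults,
    GrammarResults,
    ObservedPattern,
    component_probability,
    fit_grammar,
    fit_hyperparams,
    log_marginal_likelihood,
    posterior_predict,
)
from patcomm.kernels import KernelSpec, enumerate_grammar, evaluate_kernel


def _dense_mvn_logpdf(y, A):
    """Explicit inversion/determinant multivariate-normal oracle."""
    n = y.size
    sign, logdet = np.linalg.slogdet(A)
    assert sign > 0
    return -0.5 * y @ np.linalg.inv(A) @ y - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)


def _noisy_cov(spec, x):
    K = evaluate_kernel(spec, x, x)
    s2 = spec.params.get("noise_var", 0.0)
    jitter = JITTER * max(np.mean(np.diag(K)) + s2, 1e-12)
    return K + (s2 + jitter) * np.eye(len(x))


def test_lml_single_point_unit_variance():
    spec = KernelSpec("LIN", {"theta1": 0.0, "noise_var": 1.0})
    data = ObservedPattern([0.0], [0.0])
    assert log_marginal_likelihood(data, spec) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-5)


def test_lml_two_points_identity_covariance():
    spec = KernelSpec("LIN", {"theta1": 0.0, "noise_var": 1.0})
    data = ObservedPattern([0.0, 1e-9], [0.0, 0.0])
    assert log_marginal_likelihood(data, spec) == pytest.approx(-np.log(2 * np.pi), abs=1e-5)


@pytest.mark.parametrize("seed", range(5))
def test_lml_matches_dense_mvn_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 15))
    x = np.sort(rng.uniform(0, 1, n))
    y = rng.normal(size=n)
    spec = KernelSpec(("SUM", "RBF", "LIN"),
                      {"theta1": 0.3, "theta2": 1.2, "theta3": 0.4, "noise_var": 0.1})
    expected = _dense_mvn_logpdf(y, _noisy_cov(spec, x))
    assert log_marginal_likelihood(ObservedPattern(x, y), spec) == pytest.approx(expected, abs=1e-8)


def test_posterior_far_from_data_recovers_prior(rbf_spec):
    data = ObservedPattern([0.0, 0.01, 0.02], [1.0, 1.1, 0.9])
    spec = KernelSpec("RBF", {"theta2": 1.0, "theta3": 0.005, "noise_var": 0.01})
    pred = posterior_predict(data, spec, [0.9])
    assert pred.mean[0] == pytest.approx(0.0, abs=1e-6)
    assert pred.variance[0] == pytest.approx(1.0, rel=1e-4)  # k(x*, x*) = theta2^2


def test_posterior_noiseless_interpolation(rbf_spec):
    x = np.array([0.1, 0.5, 0.9])
    y = np.array([0.3, -0.2, 1.0])
    spec = KernelSpec("RBF", {"theta2": 1.0, "theta3": 0.3, "noise_var": 0.0})
    pred = posterior_predict(ObservedPattern(x, y), spec, x)
    np.testing.assert_allclose(pred.mean, y, atol=1e-4)
    np.testing.assert_allclose(pred.variance, 0.0, atol=1e-4)


@pytest.mark.parametrize("seed", range(5))
def test_posterior_matches_block_conditioning_oracle(seed):
    rng = np.random.default_rng(seed)
    x = np.sort(rng.uniform(0, 1, 3))
    y = rng.normal(size=3)
    xs = rng.uniform(0, 1, 4)
    spec = KernelSpec("RBF", {"theta2": 1.1, "theta3": 0.25, "noise_var": 0.05})
    pred = posterior_predict(ObservedPattern(x, y), spec, xs)
    A = _noisy_cov(spec, x)
    Ks = evaluate_kernel(spec, x, xs)
    Kss = evaluate_kernel(spec, xs, xs)
    Ainv = np.linalg.inv(A)
    np.testing.assert_allclose(pred.mean, Ks.T @ Ainv @ y, atol=1e-8)
    np.testing.assert_allclose(pred.variance, np.diag(Kss - Ks.T @ Ainv @ Ks), atol=1e-8)


def test_predictive_variance_nonnegative(rng, grid100):
    data = ObservedPattern.standardized(grid100, rng.normal(size=100))
    for expr in [("SUM", "LIN", "PER"), ("PRODUCT", "RBF", "PER"), ("SPECTRAL", 3)]:
        pred = posterior_predict(data, KernelSpec(expr), rng.uniform(0, 1, 1000))
        assert np.all(pred.variance >= 0)


# -- fitting ------------------------------------------------------------------


def test_fit_improves_over_mismatched_parameters(grid100):
    rng = np.random.default_rng(3)
    y = 2.0 * (grid100 - 0.5) + rng.normal(0, 0.05, 100)
    data = ObservedPattern.standardized(grid100, y)
    fit = fit_hyperparams(data, "LIN", n_restarts=3, seed=0)
    bad = KernelSpec("LIN", {"theta1": 10.0, "noise_var": 0.1})
    assert fit.log_ml > log_marginal_likelihood(data, bad)


def test_fit_reproducible_given_seed(sine_pattern):
    a = fit_hyperparams(sine_pattern, "PER", n_restarts=2, seed=42)
    b = fit_hyperparams(sine_pattern, "PER", n_restarts=2, seed=42)
    assert a.log_ml == b.log_ml
    assert a.optimized_params == b.optimized_params


def test_period_recovery_across_seeds(grid100):
    """Fitted periodic kernel recovers a 0.2 period within 10% in >= 80% of runs."""
    hits = 0
    n_runs = 10
    for s in range(n_runs):
        rng = np.random.default_rng(s)
        y = np.sin(2 * np.pi * grid100 / 0.2) + rng.normal(0, 0.05, 100)
        fit = fit_hyperparams(ObservedPattern.standardized(grid100, y), "PER",
                              n_restarts=5, seed=s)
        hits += abs(fit.spec.params["theta5"] - 0.2) / 0.2 < 0.1
    assert hits >= 0.8 * n_runs


def test_grammar_search_finds_linear_structure(grid100):
    hits = 0
    for s in range(5):
        rng = np.random.default_rng(100 + s)
        y = 1.5 * grid100 + rng.normal(0, 0.05, 100)
        gf = fit_grammar(ObservedPattern.standardized(grid100, y), n_restarts=2, seed=s)
        hits += "LIN" in [l for l in _leaves(gf.best_fit.spec.expr)]
    assert hits >= 4


def _leaves(expr):
    from patcomm.kernels import leaves
    return leaves(expr)


def test_grammar_search_constant_pattern_completes(grid100):
    data = ObservedPattern(grid100, np.zeros(100))
    gf = fit_grammar(data, n_restarts=1, seed=0)
    assert len(gf.fits) == 17
    assert all(isinstance(f, GPResults) for f in gf.fits)
    assert gf.best_fit.log_ml == max(f.log_ml for f in gf.fits)


def test_compositional_beats_spectral_on_compositional_data(grid100):
    """Directional model recovery: the grammar's best fit should outscore the
    spectral mixture on data actually drawn from a composition."""
    from patcomm.patterns import sample_pattern

    wins, n_runs = 0, 8
    for s in range(n_runs):
        spec = KernelSpec(("SUM", "LIN", "PER"),
                          {"theta1": 0.5, "theta4": 1.0, "theta5": 0.25, "theta6": 1.0})
        pat = sample_pattern(spec, seed=50 + s)
        rng = np.random.default_rng(s)
        y = pat.y + rng.normal(0, 0.1, 100)
        gf = fit_grammar(ObservedPattern.standardized(grid100, y), n_restarts=2,
                         seed=s, include_spectral=True)
        wins += gf.best_fit.log_ml > gf.spectral_fit.log_ml
    assert wins >= 0.7 * n_runs


# -- component probabilities ---------------------------------------------------


def _synthetic_grammar_results(structures, log_ml):
    data = ObservedPattern([0.0, 1.0], [0.0, 0.0])
    fits = [GPResults(KernelSpec(s), log_ml, True, 1, data) for s in structures]
    best = int(np.argmax([f.log_ml for f in fits]))
    return GrammarResults(fits=fits, best=best)


def test_component_probability_equal_loglik():
    gf = _synthetic_grammar_results(enumerate_grammar(), -5.0)
    for comp in ("LIN", "RBF", "PER"):
        assert component_probability(gf, comp) == pytest.approx(13 / 17)


def test_component_probability_singletons_only():
    gf = _synthetic_grammar_results(["LIN", "RBF", "PER"], -2.0)
    for comp in ("LIN", "RBF", "PER"):
        assert component_probability(gf, comp) == pytest.approx(1 / 3)


def test_component_scores_need_not_sum_to_one():
    gf = _synthetic_grammar_results(enumerate_grammar(), -5.0)
    total = sum(component_probability(gf, c) for c in ("LIN", "RBF", "PER"))
    assert total == pytest.approx(39 / 17)
    assert total != pytest.approx(1.0)


def test_component_probability_softmax_mode():
    gf = _synthetic_grammar_results(enumerate_grammar(), -5.0)
    for comp in ("LIN", "RBF", "PER"):
        assert component_probability(gf, comp, mode="softmax") == pytest.approx(13 / 17)


def test_component_probability_mixed_sign_warns():
    gf = _synthetic_grammar_results(["LIN", "RBF", "PER"], -2.0)
    gf.fits[0].log_ml = 3.0
    with pytest.warns(RuntimeWarning, match="mixed-sign"):
        component_probability(gf, "LIN")
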