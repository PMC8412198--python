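"""Base kernels, composition operators, spectral mixture, grammar."""

import itertools

import numpy as np
import pytest

from patcomm import kernels as kern
from patcomm.kernels import (
    ConfigError,
    HyperParams,
    InvalidParameterError,
    KernelSpec,
    KernelSpecError,
    canonicalize,
    components,
    enumerate_grammar,
    evaluate_kernel,
    evaluate_spectral,
    leaves,
)


def test_linear_kernel_matches_closed_form():
    spec = KernelSpec("LIN", {"theta1": 0.0})
    K = evaluate_kernel(spec, [1.0, 2.0], [1.0, 2.0])
    np.testing.assert_allclose(K, [[1.0, 2.0], [2.0, 4.0]])


def test_rbf_diagonal_equals_squared_amplitude():
    spec = KernelSpec("RBF", {"theta2": 1.7, "theta3": 0.3})
    x = np.linspace(0, 1, 9)
    K = evaluate_kernel(spec, x, x)
    np.testing.assert_allclose(np.diag(K), np.full(9, 1.7**2))


def test_periodic_kernel_at_full_period_lag():
    t4, t5 = 1.3, 0.25
    spec = KernelSpec("PER", {"theta4": t4, "theta5": t5, "theta6": 0.8})
    K = evaluate_kernel(spec, [0.0], [t5])
    np.testing.assert_allclose(K, [[t4**2]], atol=1e-14)


def test_spectral_at_zero_lag_sums_weights():
    spec = KernelSpec(("SPECTRAL", 2),
                      {"w1": 0.7, "w2": 1.4, "mu1": 2.0, "mu2": 5.0, "v1": 1.0, "v2": 2.0})
    K = evaluate_spectral(spec, [0.3], [0.3])
    np.testing.assert_allclose(K, [[0.7 + 1.4]])


def test_spectral_zero_weights_gives_zero_matrix():
    spec = KernelSpec(("SPECTRAL", 2),
                      {"w1": 0.0, "w2": 0.0, "mu1": 2.0, "mu2": 5.0, "v1": 1.0, "v2": 2.0})
    K = evaluate_spectral(spec, np.linspace(0, 1, 5), np.linspace(0, 1, 5))
    np.testing.assert_allclose(K, 0.0)


def test_spectral_matches_brute_force_closed_form():
    """Direct evaluation of the Gaussian spectral-density mixture at 10 lags."""
    params = {"w1": 0.5, "w2": 1.2, "w3": 0.3,
              "mu1": 1.5, "mu2": 4.0, "mu3": 9.0,
              "v1": 0.4, "v2": 2.0, "v3": 0.05}
    spec = KernelSpec(("SPECTRAL", 3), params)
    taus = np.linspace(-1, 1, 10)
    K = evaluate_spectral(spec, taus, [0.0])
    expected = np.zeros(10)
    for q in (1, 2, 3):
        w, mu, v = params[f"w{q}"], params[f"mu{q}"], params[f"v{q}"]
        expected += w * np.exp(-2 * np.pi**2 * taus**2 * v) * np.cos(2 * np.pi * taus * mu)
    np.testing.assert_allclose(K[:, 0], expected, atol=1e-12)


def test_spectral_low_frequency_limit_is_rbf_shaped():
    """With mu -> 0 a single-component term reduces to w exp(-2 pi^2 tau^2 v)."""
    spec = KernelSpec(("SPECTRAL", 2),
                      {"w1": 1.0, "w2": 0.0, "mu1": 1e-9, "mu2": 1.0, "v1": 1.0, "v2": 1.0})
    taus = np.linspace(0, 0.5, 10)
    K = evaluate_spectral(spec, taus, [0.0])[:, 0]
    np.testing.assert_allclose(K, np.exp(-2 * np.pi**2 * taus**2), atol=1e-8)


# -- composition --------------------------------------------------------------


@pytest.mark.parametrize("op,combine", [("SUM", np.add), ("PRODUCT", np.multiply)])
@pytest.mark.parametrize("pair", list(itertools.combinations(kern.BASE_KERNELS, 2)))
def test_sum_product_closure(op, combine, pair, rng):
    params = {"theta1": rng.uniform(0, 1),
              "theta2": rng.uniform(0.1, 2), "theta3": rng.uniform(0.1, 2),
              "theta4": rng.uniform(0.1, 2), "theta5": rng.uniform(0.1, 1),
              "theta6": rng.uniform(0.1, 2)}
    x = rng.uniform(0, 1, 12)
    Ka = evaluate_kernel(KernelSpec(pair[0], params), x, x)
    Kb = evaluate_kernel(KernelSpec(pair[1], params), x, x)
    K = evaluate_kernel(KernelSpec((op, *pair), params), x, x)
    np.testing.assert_allclose(K, combine(Ka, Kb), atol=1e-12)


@pytest.mark.parametrize("expr", enumerate_grammar() + [("SPECTRAL", 3)])
def test_covariance_symmetric_and_psd(expr, grid100):
    K = evaluate_kernel(KernelSpec(expr), grid100, grid100)
    np.testing.assert_allclose(K, K.T, atol=1e-12)
    assert np.linalg.eigvalsh(K).min() >= -1e-8


# -- grammar enumeration -------------------------------------------------------


def _brute_force_structures():
    """Independent generator: all operator trees over <= 3 distinct leaves,
    deduplicated by a flatten-and-sort normal form."""

    def norm(t):
        if isinstance(t, str):
            return t
        op, kids = t[0], []
        for k in t[1:]:
            nk = norm(k)
            if isinstance(nk, tuple) and nk[0] == op:
                kids.extend(nk[1:])
            else:
                kids.append(nk)
        return (op, *sorted(kids, key=repr))

    bases = list(kern.BASE_KERNELS)
    out = set(bases)
    for a, b in itertools.permutations(bases, 2):
        for op in ("SUM", "PRODUCT"):
            out.add(norm((op, a, b)))
    for a, b, c in itertools.permutations(bases, 3):
        for op1 in ("SUM", "PRODUCT"):
            for op2 in ("SUM", "PRODUCT"):
                out.add(norm((op1, (op2, a, b), c)))  # covers flat triples too
    return out


def test_grammar_has_17_canonical_structures():
    grammar = enumerate_grammar()
    assert len(grammar) == 17
    assert len(set(grammar)) == 17

    def norm_label(t):
        if isinstance(t, str):
            return t
        return (t[0], *sorted((norm_label(c) for c in t[1:]), key=repr))

    assert {norm_label(g) for g in grammar} == _brute_force_structures()


def test_grammar_contains_three_singletons_and_no_repeats():
    grammar = enumerate_grammar()
    singletons = [g for g in grammar if isinstance(g, str)]
    assert sorted(singletons) == sorted(kern.BASE_KERNELS)
    for g in grammar:
        ls = leaves(g)
        assert len(ls) <= 3
        assert len(set(ls)) == len(ls)


def test_grammar_enumeration_is_stable():
    assert enumerate_grammar() == enumerate_grammar()


def test_canonicalize_commutative_and_associative():
    assert canonicalize(("SUM", "PER", "LIN")) == canonicalize(("SUM", "LIN", "PER"))
    assert canonicalize(("SUM", ("SUM", "LIN", "RBF"), "PER")) == canonicalize(
        ("SUM", "LIN", "RBF", "PER")
    )
    assert canonicalize(("PRODUCT", "RBF", ("SUM", "PER", "LIN"))) == canonicalize(
        ("PRODUCT", ("SUM", "LIN", "PER"), "RBF")
    )


def test_component_membership_counts():
    grammar = enumerate_grammar()
    for comp in kern.BASE_KERNELS:
        assert sum(comp in components(g) for g in grammar) == 13


# -- validation and serialization ---------------------------------------------


def test_invalid_parameters_rejected():
    with pytest.raises(InvalidParameterError):
        HyperParams(theta3=-1.0)
    with pytest.raises(InvalidParameterError):
        KernelSpec("RBF", {"theta2": 1.0, "theta3": 0.0})
    with pytest.raises(InvalidParameterError):
        HyperParams(noise_var=-0.1)


def test_malformed_trees_rejected():
    with pytest.raises(KernelSpecError):
        canonicalize("FOO")
    with pytest.raises(KernelSpecError):
        canonicalize(("SUM", "LIN"))
    with pytest.raises(KernelSpecError):
        KernelSpec(("SUM", "LIN", "LIN"))
    with pytest.raises(ConfigError):
        KernelSpec(("SPECTRAL", 7))
    with pytest.raises(ConfigError):
        KernelSpec(("SPECTRAL", 1))


def test_hyperparams_round_trip():
    hp = HyperParams(theta1=0.3, theta2=1.2, theta5=0.17, noise_var=0.01)
    assert HyperParams.from_dict(hp.to_dict()) == hp


@pytest.mark.parametrize("expr", [("SUM", ("PRODUCT", "LIN", "PER"), "RBF"), ("SPECTRAL", 2)])
def test_kernelspec_json_round_trip(expr):
    spec = KernelSpec(expr)
    again = KernelSpec.from_json(spec.to_json())
    assert again.expr == spec.expr
    assert again.params == spec.params
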