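"""Base kernels, the composition grammar, and the spectral mixture kernel.

The pattern description language is built from three base covariance
functions on a one-dimensional input space:

* ``LIN`` — linear kernel ``k(x, x') = (x - theta1)(x' - theta1)``, encoding
  trends through an offset ``theta1``.
* ``RBF`` — radial basis function kernel
  ``k(x, x') = theta2^2 exp(-(x - x')^2 / (2 theta3^2))``, encoding smooth
  local variation with amplitude ``theta2`` and length-scale ``theta3``.
* ``PER`` — periodic kernel
  ``k(x, x') = theta4^2 exp(-2 sin^2(pi |x - x'| / theta5) / theta6^2)``,
  encoding repetition with period ``theta5``.

Base kernels are combined by elementwise addition (``SUM``) and
multiplication (``PRODUCT``).  A composition may use at most three leaves and
may not repeat a base kernel, which yields exactly 17 distinct structures
under commutativity and associativity of the two operators (see
:func:`enumerate_grammar`).

The noncompositional alternative is a stationary spectral mixture kernel

    k(tau) = sum_q w_q exp(-2 pi^2 tau^2 v_q) cos(2 pi tau mu_q)

whose spectral density is a mixture of Q Gaussians with weights ``w_q``,
centre frequencies ``mu_q`` and bandwidths ``v_q``.

Expressions are plain nested tuples, e.g. ``("SUM", "LIN", "PER")`` or
``("SUM", ("PRODUCT", "LIN", "PER"), "RBF")``; the spectral kernel is the
leaf ``("SPECTRAL", Q)``.  :func:`canonicalize` flattens nested identical
operators and sorts children so structurally equal expressions compare equal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "BASE_KERNELS",
    "OPERATORS",
    "PARAM_RANGES",
    "HyperParams",
    "KernelSpec",
    "InvalidParameterError",
    "KernelSpecError",
    "ConfigError",
    "canonicalize",
    "leaves",
    "components",
    "is_spectral",
    "param_names",
    "param_transforms",
    "evaluate_kernel",
    "evaluate_spectral",
    "enumerate_grammar",
    "structure_label",
]

BASE_KERNELS = ("LIN", "RBF", "PER")
OPERATORS = ("SUM", "PRODUCT")

#: Sampling / initialization ranges for hyperparameters. Positive parameters
#: are drawn log-uniformly from [lo, hi]; the linear offset theta1 uniformly.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "theta1": (0.0, 1.0),       # linear offset, input units
    "theta2": (0.05, 5.0),      # RBF amplitude
    "theta3": (0.05, 5.0),      # RBF length-scale
    "theta4": (0.05, 5.0),      # periodic amplitude
    "theta5": (0.05, 1.0),      # period, input units
    "theta6": (0.05, 5.0),      # periodic roughness length-scale
    "noise_var": (1e-4, 1.0),   # observation noise variance
    "w": (0.05, 5.0),           # spectral mixture weight
    # Spectral priors span the same frequency / length-scale content as the
    # compositional grammar (periods 0.05-1 <-> mu in [1, 20]; envelope
    # correlation lengths ~0.05-3 <-> v in [0.003, 10]), so the two model
    # classes have comparable expressivity by construction.
    "mu": (1.0, 20.0),          # spectral centre frequency, cycles per unit
    "v": (0.003, 10.0),         # spectral bandwidth
}


class InvalidParameterError(ValueError):
    """A kernel hyperparameter violates its positivity constraint."""


class KernelSpecError(ValueError):
    """A kernel expression tree is malformed."""


class ConfigError(ValueError):
    """A configuration value is out of its allowed range."""


# ---------------------------------------------------------------------------
# Hyperparameter containers
# ---------------------------------------------------------------------------


@dataclass
class HyperParams:
    """Hyperparameters of the compositional grammar's base kernels.

    Each base kernel appears at most once in a composition, so a single
    container suffices for any compositional expression.  Scale parameters
    (theta3, theta5, theta6 and the amplitudes) must be strictly positive;
    ``noise_var`` is the observation noise variance and must be nonnegative.
    """

    theta1: float = 0.0
    theta2: float = 1.0
    theta3: float = 1.0
    theta4: float = 1.0
    theta5: float = 0.5
    theta6: float = 1.0
    noise_var: float = 0.01

    def __post_init__(self) -> None:
        for name in ("theta2", "theta3", "theta4", "theta5", "theta6"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.noise_var < 0:
            raise InvalidParameterError(f"noise_var must be >= 0, got {self.noise_var}")

    def to_dict(self) -> dict[str, float]:
        return {
            k: float(getattr(self, k))
            for k in ("theta1", "theta2", "theta3", "theta4", "theta5", "theta6", "noise_var")
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "HyperParams":
        return cls(**{k: float(v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------


def _is_spectral_leaf(expr) -> bool:
    return (
        isinstance(expr, tuple)
        and len(expr) == 2
        and expr[0] == "SPECTRAL"
        and isinstance(expr[1], int)
    )


def _validate_expr(expr) -> None:
    if isinstance(expr, str):
        if expr not in BASE_KERNELS:
            raise KernelSpecError(f"unknown base kernel {expr!r}")
        return
    if _is_spectral_leaf(expr):
        if not (2 <= expr[1] <= 6):
            raise ConfigError(f"spectral Q must be in [2, 6], got {expr[1]}")
        return
    if not (isinstance(expr, tuple) and len(expr) >= 3 and expr[0] in OPERATORS):
        raise KernelSpecError(f"malformed kernel expression: {expr!r}")
    for child in expr[1:]:
        _validate_expr(child)


def _sort_key(expr):
    if isinstance(expr, str):
        return (0, BASE_KERNELS.index(expr), ())
    if _is_spectral_leaf(expr):
        return (1, expr[1], ())
    return (2, OPERATORS.index(expr[0]), tuple(_sort_key(c) for c in expr[1:]))


def canonicalize(expr):
    """Return the canonical form of a kernel expression.

    Nested identical operators are flattened (associativity) and children are
    sorted by a fixed key (commutativity), so two expressions denoting the
    same kernel structure canonicalize to the same tuple.
    """
    _validate_expr(expr)
    if isinstance(expr, str) or _is_spectral_leaf(expr):
        return expr
    op = expr[0]
    children = []
    for child in expr[1:]:
        c = canonicalize(child)
        if isinstance(c, tuple) and len(c) >= 3 and c[0] == op:
            children.extend(c[1:])
        else:
            children.append(c)
    children.sort(key=_sort_key)
    return (op, *children)


def leaves(expr) -> list:
    """Leaf nodes of an expression in canonical traversal order."""
    if isinstance(expr, str) or _is_spectral_leaf(expr):
        return [expr]
    out: list = []
    for child in expr[1:]:
        out.extend(leaves(child))
    return out


def components(expr) -> set[str]:
    """The set of base-kernel names appearing in a compositional expression."""
    return {leaf for leaf in leaves(expr) if isinstance(leaf, str)}


def is_spectral(expr) -> bool:
    return any(_is_spectral_leaf(leaf) for leaf in leaves(expr))


def structure_label(expr) -> str:
    """Human-readable label, e.g. ``(LIN*PER)+RBF``."""
    if isinstance(expr, str):
        return expr
    if _is_spectral_leaf(expr):
        return f"SPECTRAL{expr[1]}"
    sep = "+" if expr[0] == "SUM" else "*"
    return "(" + sep.join(structure_label(c) for c in expr[1:]) + ")"


_LEAF_PARAMS = {
    "LIN": ("theta1",),
    "RBF": ("theta2", "theta3"),
    "PER": ("theta4", "theta5", "theta6"),
}


def param_names(expr, include_noise: bool = True) -> list[str]:
    """Free hyperparameter names of an expression, canonical order.

    Spectral leaves contribute ``w1..wQ, mu1..muQ, v1..vQ``.  The observation
    noise variance is appended last when ``include_noise`` is set.
    """
    names: list[str] = []
    for leaf in leaves(canonicalize(expr)):
        if isinstance(leaf, str):
            names.extend(_LEAF_PARAMS[leaf])
        else:
            q = leaf[1]
            names.extend([f"w{i}" for i in range(1, q + 1)])
            names.extend([f"mu{i}" for i in range(1, q + 1)])
            names.extend([f"v{i}" for i in range(1, q + 1)])
    if include_noise:
        names.append("noise_var")
    return names


def param_transforms(expr, include_noise: bool = True) -> list[str]:
    """Per-parameter transform used for unconstrained optimization.

    ``"log"`` for strictly positive scales, ``"id"`` for the unconstrained
    linear offset theta1.
    """
    return ["id" if n == "theta1" else "log" for n in param_names(expr, include_noise)]


@dataclass
class KernelSpec:
    """A kernel structure together with its hyperparameter values.

    Parameters
    ----------
    expr
        Canonical expression tree (see module docstring).
    params
        Mapping from parameter name to value; must cover exactly the names
        returned by :func:`param_names` for ``expr`` (noise optional).
    """

    expr: tuple | str
    params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.expr = canonicalize(self.expr)
        if not self.is_spectral:
            comp_leaves = [l for l in leaves(self.expr) if isinstance(l, str)]
            if len(comp_leaves) > 3:
                raise KernelSpecError("compositional expressions use at most 3 leaves")
            if len(set(comp_leaves)) != len(comp_leaves):
                raise KernelSpecError("base kernels may not repeat within a composition")
        if not self.params:
            self.params = self._default_params()
        self._check_params()

    def _default_params(self) -> dict[str, float]:
        defaults = HyperParams().to_dict()
        out = {}
        for name in param_names(self.expr):
            if name in defaults:
                out[name] = defaults[name]
            elif name.startswith("w"):
                out[name] = 1.0
            elif name.startswith("mu"):
                out[name] = 2.0
            elif name.startswith("v"):
                out[name] = 1.0
        return out

    def _check_params(self) -> None:
        needed = param_names(self.expr, include_noise=False)
        missing = [n for n in needed if n not in self.params]
        if missing:
            raise KernelSpecError(f"missing parameters: {missing}")
        self.params.setdefault("noise_var", 0.0)
        for name, tr in zip(param_names(self.expr), param_transforms(self.expr)):
            v = self.params[name]
            if not np.isfinite(v):
                raise InvalidParameterError(f"{name} is not finite")
            if tr == "log" and name != "noise_var" and not name.startswith("w") and v <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {v}")
            if (name == "noise_var" or name.startswith("w")) and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    @property
    def is_spectral(self) -> bool:
        return is_spectral(self.expr)

    @property
    def label(self) -> str:
        return structure_label(self.expr)

    # -- JSON round trip ----------------------------------------------------

    @staticmethod
    def _expr_to_json(expr):
        if isinstance(expr, str):
            return expr
        if _is_spectral_leaf(expr):
            return {"SPECTRAL": expr[1]}
        return [expr[0], *[KernelSpec._expr_to_json(c) for c in expr[1:]]]

    @staticmethod
    def _expr_from_json(obj):
        if isinstance(obj, str):
            return obj
        if isinstance(obj, dict):
            return ("SPECTRAL", int(obj["SPECTRAL"]))
        return (obj[0], *[KernelSpec._expr_from_json(c) for c in obj[1:]])

    def to_json(self) -> str:
        return json.dumps(
            {"expr": self._expr_to_json(self.expr), "params": {k: float(v) for k, v in self.params.items()}}
        )

    @classmethod
    def from_json(cls, s: str) -> "KernelSpec":
        obj = json.loads(s)
        return cls(expr=cls._expr_from_json(obj["expr"]), params=obj["params"])


# ---------------------------------------------------------------------------
# Covariance evaluation (values and gradients)
# ---------------------------------------------------------------------------


def _leaf_value_grad(leaf, D, X, Xp, theta, grad: bool):
    """Covariance block and, optionally, gradients w.r.t. unconstrained params.

    Positive parameters are optimized on the log scale, so their gradient
    entries already carry the chain-rule factor (d k / d log theta).
    """
    if leaf == "LIN":
        (t1,) = theta
        a = X - t1
        b = Xp - t1
        K = np.outer(a, b)
        if not grad:
            return K, None
        dK = -(b[None, :] + a[:, None])  # d/d theta1, identity transform
        return K, [dK]
    if leaf == "RBF":
        t2, t3 = theta
        E = np.exp(-(D**2) / (2.0 * t3**2))
        K = t2**2 * E
        if not grad:
            return K, None
        return K, [2.0 * K, K * (D**2) / t3**2]
    if leaf == "PER":
        t4, t5, t6 = theta
        arg = np.pi * np.abs(D) / t5
        s = np.sin(arg)
        K = t4**2 * np.exp(-2.0 * s**2 / t6**2)
        if not grad:
            return K, None
        d_log_t5 = K * (4.0 * s * np.cos(arg) * np.pi * np.abs(D)) / (t5 * t6**2)
        d_log_t6 = K * 4.0 * s**2 / t6**2
        return K, [2.0 * K, d_log_t5, d_log_t6]
    # spectral leaf
    q = leaf[1]
    w = np.asarray(theta[:q])
    mu = np.asarray(theta[q : 2 * q])
    v = np.asarray(theta[2 * q : 3 * q])
    K = np.zeros_like(D)
    dKs = [] if grad else None
    terms = []
    for i in range(q):
        E = np.exp(-2.0 * np.pi**2 * D**2 * v[i])
        C = np.cos(2.0 * np.pi * D * mu[i])
        term = w[i] * E * C
        K += term
        if grad:
            terms.append((E, C, term))
    if not grad:
        return K, None
    for i in range(q):
        dKs.append(terms[i][2])  # d/d log w_i = w_i E C
    for i in range(q):
        E, C, _ = terms[i]
        dKs.append(-w[i] * E * np.sin(2.0 * np.pi * D * mu[i]) * 2.0 * np.pi * D * mu[i])
    for i in range(q):
        E, C, term = terms[i]
        dKs.append(term * (-2.0 * np.pi**2 * D**2 * v[i]))
    return K, dKs


def _eval_expr(expr, X, Xp, theta: np.ndarray, grad: bool):
    """Recursive evaluation returning (K, [dK per unconstrained param])."""
    if isinstance(expr, str) or _is_spectral_leaf(expr):
        if isinstance(expr, str):
            n = len(_LEAF_PARAMS[expr])
        else:
            n = 3 * expr[1]
        D = X[:, None] - Xp[None, :]
        K, dKs = _leaf_value_grad(expr, D, X, Xp, theta[:n], grad)
        return K, dKs, n
    op = expr[0]
    Ks, all_d, used = [], [], 0
    for child in expr[1:]:
        K, dKs, n = _eval_expr(child, X, Xp, theta[used:], grad)
        Ks.append(K)
        all_d.append(dKs)
        used += n
    if op == "SUM":
        K = np.sum(Ks, axis=0)
        if grad:
            dKs = [d for ds in all_d for d in ds]
        else:
            dKs = None
    else:  # PRODUCT
        K = np.prod(Ks, axis=0)
        if grad:
            dKs = []
            for i, ds in enumerate(all_d):
                other = np.ones_like(K)
                for j, Kj in enumerate(Ks):
                    if j != i:
                        other = other * Kj
                dKs.extend([other * d for d in ds])
        else:
            dKs = None
    return K, dKs, used


def _theta_vector(spec: KernelSpec, include_noise: bool = False) -> np.ndarray:
    return np.array([spec.params[n] for n in param_names(spec.expr, include_noise)], float)


def kernel_value(expr, x, x_prime, theta: np.ndarray) -> np.ndarray:
    """Evaluate the covariance matrix for a structure at natural parameters."""
    X = np.asarray(x, float).ravel()
    Xp = np.asarray(x_prime, float).ravel()
    K, _, _ = _eval_expr(canonicalize(expr), X, Xp, np.asarray(theta, float), grad=False)
    return K


def kernel_value_grad(expr, x, x_prime, theta: np.ndarray):
    """Covariance matrix and gradients w.r.t. unconstrained parameters.

    Gradient entries for log-transformed parameters are d K / d log(theta);
    theta1's entry is d K / d theta1.
    """
    X = np.asarray(x, float).ravel()
    Xp = np.asarray(x_prime, float).ravel()
    K, dKs, _ = _eval_expr(canonicalize(expr), X, Xp, np.asarray(theta, float), grad=True)
    return K, dKs


def evaluate_kernel(spec: KernelSpec, x, x_prime) -> np.ndarray:
    """Covariance matrix of a compositional spec on a pair of input grids.

    SUM nodes add child matrices elementwise; PRODUCT nodes multiply them.
    Raises :class:`InvalidParameterError` for non-positive scale parameters
    and :class:`KernelSpecError` for malformed trees.
    """
    if not isinstance(spec, KernelSpec):
        spec = KernelSpec(*spec) if isinstance(spec, tuple) else KernelSpec(spec)
    x = np.asarray(x, float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(np.asarray(x_prime, float)))):
        raise ValueError("inputs must be finite")
    return kernel_value(spec.expr, x, x_prime, _theta_vector(spec))


def evaluate_spectral(spec: KernelSpec, x, x_prime) -> np.ndarray:
    """Covariance matrix of a spectral mixture spec (stationary in x - x')."""
    if not spec.is_spectral:
        raise KernelSpecError("evaluate_spectral requires a spectral spec")
    return evaluate_kernel(spec, x, x_prime)


# ---------------------------------------------------------------------------
# Grammar enumeration
# ---------------------------------------------------------------------------


def enumerate_grammar() -> list[tuple | str]:
    """All distinct compositional structures with <= 3 non-repeating leaves.

    Under commutativity/associativity of SUM and PRODUCT the grammar contains
    3 singletons, 6 pairs and 8 triples (full sum, full product, the three
    ``(a*b)+c`` and the three ``(a+b)*c`` nestings): 17 structures in a fixed
    canonical order.
    """
    structures: list = list(BASE_KERNELS)
    for a, b in combinations(BASE_KERNELS, 2):
        for op in OPERATORS:
            structures.append(canonicalize((op, a, b)))
    a, b, c = BASE_KERNELS
    structures.append(canonicalize(("SUM", a, b, c)))
    structures.append(canonicalize(("PRODUCT", a, b, c)))
    for inner_op, outer_op in (("PRODUCT", "SUM"), ("SUM", "PRODUCT")):
        for pair in combinations(BASE_KERNELS, 2):
            third = next(k for k in BASE_KERNELS if k not in pair)
            structures.append(canonicalize((outer_op, (inner_op, *pair), third)))
    seen, out = set(), []
    for s in structures:
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out
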