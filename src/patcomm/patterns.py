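"""Sampling pattern stimuli from both model classes and matching them.

Compositional stimuli are drawn by first sampling a structure uniformly from
the 17-structure grammar and then drawing a function from the corresponding
zero-mean GP on 100 equidistant inputs in [0, 1].  Noncompositional stimuli
are drawn from spectral mixture kernels with Q uniform on {2..6}.
Hyperparameters are sampled from the same documented log-uniform ranges used
to initialize the optimizer (:data:`patcomm.kernels.PARAM_RANGES`).

A matched stimulus set pairs compositional with noncompositional patterns so
the two classes are balanced on spectral entropy and Haar-wavelet distance,
mirroring how the 40-pattern stimulus set was assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from . import kernels as kern
from .kernels import KernelSpec, enumerate_grammar
from .reconstruction import wavelet_distance

__all__ = [
    "Pattern",
    "MatchedSet",
    "default_grid",
    "sample_pattern",
    "sample_compositional_spec",
    "sample_spectral_spec",
    "spectral_entropy",
    "build_matched_set",
]

N_POINTS = 100


def default_grid(n: int = N_POINTS) -> np.ndarray:
    """The canonical input grid: n equidistant points on [0, 1]."""
    return np.linspace(0.0, 1.0, n)


@dataclass
class Pattern:
    """A function sample presented as a stimulus."""

    pattern_id: str
    x: np.ndarray
    y: np.ndarray
    source_class: str  # "compositional" | "noncompositional"
    generator: KernelSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float).ravel()
        self.y = np.asarray(self.y, float).ravel()
        if not np.all(np.isfinite(self.y)):
            raise ValueError("pattern outputs must be finite")
        if self.source_class not in ("compositional", "noncompositional"):
            raise ValueError(f"unknown source_class {self.source_class!r}")

    @property
    def y_standardized(self) -> np.ndarray:
        sd = self.y.std()
        return (self.y - self.y.mean()) / sd if sd > 0 else self.y - self.y.mean()


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _draw_value(name: str, rng: np.random.Generator) -> float:
    base = name.rstrip("0123456789") if name[0] in "wmv" and name != "noise_var" else name
    lo, hi = kern.PARAM_RANGES[base]
    if name == "theta1":
        return float(rng.uniform(lo, hi))
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_params(expr, rng: np.random.Generator) -> dict[str, float]:
    params = {n: _draw_value(n, rng) for n in kern.param_names(expr, include_noise=False)}
    params["noise_var"] = 0.0
    return params


def sample_compositional_spec(seed=None) -> KernelSpec:
    """Uniform draw over the 17 grammar structures with prior hyperparameters."""
    rng = _rng(seed)
    grammar = enumerate_grammar()
    expr = grammar[int(rng.integers(len(grammar)))]
    return KernelSpec(expr, _draw_params(expr, rng))


def sample_spectral_spec(seed=None) -> KernelSpec:
    """Spectral mixture spec with Q uniform on {2, ..., 6}."""
    rng = _rng(seed)
    q = int(rng.integers(2, 7))
    expr = ("SPECTRAL", q)
    return KernelSpec(expr, _draw_params(expr, rng))


def sample_pattern(
    spec: KernelSpec,
    seed=None,
    n_points: int = N_POINTS,
    pattern_id: str = "p0",
) -> Pattern:
    """One draw from the zero-mean multivariate normal with covariance
    ``evaluate_kernel(spec, x, x)`` on the equidistant grid."""
    rng = _rng(seed)
    x = default_grid(n_points)
    K = kern.evaluate_kernel(spec, x, x)
    K = K + 1e-6 * max(np.mean(np.diag(K)), 1e-12) * np.eye(n_points)
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"covariance factorization failed for {spec.label}: {e}")
    y = L @ rng.standard_normal(n_points)
    source = "noncompositional" if spec.is_spectral else "compositional"
    return Pattern(pattern_id, x, y, source, spec, seed if isinstance(seed, int) else None)


def spectral_entropy(y) -> float:
    """Normalized Shannon entropy of the periodogram, in [0, 1].

    The series is mean-removed, its periodogram (excluding the zero
    frequency) normalized to a probability distribution, and the Shannon
    entropy divided by log of the number of frequency bins.  Near-flat
    spectra (white noise) score close to 1, concentrated spectra
    (sinusoids) close to 0; a constant series scores 0 by convention.
    """
    y = np.asarray(y, float).ravel()
    if y.size < 8:
        raise ValueError(f"series too short for spectral entropy: {y.size} < 8")
    y = y - y.mean()
    if np.allclose(y, 0.0):
        return 0.0
    _, p = periodogram(y, detrend=False)
    p = p[1:]  # drop the (zeroed) mean bin
    if p.size >= 3:
        # light smoothing: raw periodogram ordinates are exponentially
        # distributed, which biases the entropy of flat spectra downward
        p = np.convolve(p, np.ones(3) / 3.0, mode="same")
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


@dataclass
class MatchedSet:
    """Entropy/wavelet-matched compositional and noncompositional stimuli."""

    compositional: list[Pattern]
    noncompositional: list[Pattern]
    match_stats: pd.DataFrame = field(repr=False)

    @property
    def patterns(self) -> list[Pattern]:
        return list(self.compositional) + list(self.noncompositional)


def build_matched_set(
    pool_comp: list[Pattern],
    pool_noncomp: list[Pattern],
    size_per_class: int = 20,
) -> MatchedSet:
    """Greedy cross-class pairing minimizing combined z-scored criteria.

    The pair cost is the z-scored absolute spectral-entropy difference plus
    the z-scored wavelet distance between the standardized series; pairs are
    chosen greedily (global minimum among unused patterns) until
    ``size_per_class`` pairs are selected.  Deterministic for fixed pools.
    """
    if len(pool_comp) < size_per_class or len(pool_noncomp) < size_per_class:
        raise ValueError(
            f"pools must contain at least {size_per_class} patterns each "
            f"(got {len(pool_comp)}, {len(pool_noncomp)})"
        )
    ent_c = np.array([spectral_entropy(p.y) for p in pool_comp])
    ent_n = np.array([spectral_entropy(p.y) for p in pool_noncomp])
    d_ent = np.abs(ent_c[:, None] - ent_n[None, :])
    d_wav = np.array(
        [[wavelet_distance(a.y, b.y) for b in pool_noncomp] for a in pool_comp]
    )

    def _z(m):
        sd = m.std()
        return (m - m.mean()) / sd if sd > 0 else np.zeros_like(m)

    cost = _z(d_ent) + _z(d_wav)
    used_c: list[int] = []
    used_n: list[int] = []
    pairs: list[tuple[int, int]] = []
    masked = cost.copy()
    for _ in range(size_per_class):
        i, j = np.unravel_index(np.argmin(masked), masked.shape)
        pairs.append((int(i), int(j)))
        used_c.append(int(i))
        used_n.append(int(j))
        masked[i, :] = np.inf
        masked[:, j] = np.inf
    rows = []
    for i, j in pairs:
        rows.append(
            {
                "comp_id": pool_comp[i].pattern_id,
                "noncomp_id": pool_noncomp[j].pattern_id,
                "entropy_comp": ent_c[i],
                "entropy_noncomp": ent_n[j],
                "entropy_diff": d_ent[i, j],
                "wavelet_distance": d_wav[i, j],
            }
        )
    return MatchedSet(
        compositional=[pool_comp[i] for i in used_c],
        noncompositional=[pool_noncomp[j] for j in used_n],
        match_stats=pd.DataFrame(rows),
    )
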