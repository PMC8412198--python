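# patcomm — compositional pattern description and communication

`patcomm` is a toolkit for studying how structured function patterns are
described, redrawn and rated — the "pattern communication game" from
computational cognitive science — using Gaussian-process (GP) models of
pattern description.

People appear to perceive a time-series-like pattern as a composition of
simpler parts: trends, smooth bumps, oscillations. This package formalizes
that idea as a **compositional kernel grammar**: three base kernels

| name | covariance |
|------|------------|
| linear | k(x, x′) = (x − θ₁)(x′ − θ₁) |
| radial basis (RBF) | k(x, x′) = θ₂² exp(−(x − x′)² / 2θ₃²) |
| periodic | k(x, x′) = θ₄² exp(−2 sin²(π\|x − x′\|/θ₅) / θ₆²) |

combined by addition and multiplication, with at most three non-repeating
components — 17 distinct structures. The noncompositional alternative is a
**spectral mixture kernel** k(τ) = Σ_q w_q exp(−2π²τ²v_q) cos(2πτμ_q),
equally expressive but without explicit structural building blocks.

A structure is scored on a pattern **y** by its log marginal likelihood

    log p(y | X, θ) = −½ yᵀ(K + σ_n²I)⁻¹y − ½ log|K + σ_n²I| − (n/2) log 2π,

maximized over hyperparameters θ by gradient-based optimization with
restarts. Under a uniform prior over structures, the best structure is the
maximum-marginal-likelihood one, and the probability that a component (e.g.
periodicity) is present in a pattern is the likelihood mass of structures
containing it.

Around this core the package provides:

* **Pattern generation** — sampling stimuli from both model classes and
  building class-balanced stimulus sets matched on spectral entropy and
  wavelet distance (`patcomm.patterns`).
* **Reconstruction scoring** — interpolating-spline resampling of dot
  drawings and two dissimilarities: mean absolute error and a Haar-wavelet
  coefficient distance robust to scaling and shifting
  (`patcomm.reconstruction`).
* **Description language metrics** — lexical diversity (type–token ratio),
  differential word lists, component-specific vocabularies and word-set
  presence probabilities (`patcomm.text`).
* **A synthetic communication game** — describers emit component-linked word
  bags, drawers decode them back into kernel structures and redraw patterns
  through a memory-limited GP channel, raters score drawings on a 0–100
  slider (`patcomm.simulate`).
* **Communicability analysis** — hierarchical regressions of reconstruction
  errors and ratings on model log likelihoods, with single-component and
  memorability controls and BIC-approximate Bayes factors
  (`patcomm.analysis`).

## Worked example

Which composition explains a ramp plus an oscillation?

```python
import numpy as np
from patcomm import GrammarSearch, ObservedPattern

x = np.linspace(0, 1, 100)
rng = np.random.default_rng(0)
y = 2.0 * x + np.sin(2 * np.pi * x / 0.25) + rng.normal(0, 0.1, 100)

search = GrammarSearch(ObservedPattern.standardized(x, y), include_spectral=True)
result = search.fit(n_restarts=3, seed=0)
print(result.best_fit.summary())
```

```
GP fit: (PER+(LIN*RBF))
  log marginal likelihood: 55.9723
  converged: True  (restarts: 3)
  hyperparameters:
        theta4 = 9.0336
        theta5 = 0.25099
        theta6 = 15.071
        theta1 = 1.0275
        theta2 = 2.3832
        theta3 = 11.111
     noise_var = 0.012864
```

The search ranks a periodic-plus-trend composition first, recovering the
generating period (θ₅ ≈ 0.251 against a true 0.25); the LIN×RBF factor with
a very long length-scale acts as a smooth trend. `result.summary()` prints
the full 17-structure table together with the spectral-mixture fit and
per-component scores; `result.best_fit.predict(x_star)` gives the posterior
predictive mean and variance.

A full simulated game runs from the command line:

```bash
patcomm simulate-game --seed 3 --out game/        # four dataset files + ground truth
patcomm analyze --table table.csv --outcome wavelet_distance --model both --out report.json
```

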