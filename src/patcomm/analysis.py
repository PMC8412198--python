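"""Statistical linking layer: model likelihoods vs. communicability.

Builds a per-(pattern, drawer) analysis table joining reconstruction
distances, quality ratings and per-pattern model log likelihoods, and fits
hierarchical linear models relating them:

* ``regress_errors`` — outcome (absolute error, wavelet distance or mean
  rating) on standardized model log likelihoods, with a random intercept
  and random slopes per participant group; falls back to a random
  intercept when the random-slope fit is singular.
* ``compare_models`` — approximate Bayes factors from BIC differences,
  ``BF_ab = exp((BIC_b - BIC_a) / 2)``, standing in for full Bayesian
  mixed-model comparison.
* ``control_single_components`` — does a compositional/noncompositional
  flag improve a regression already containing a single component's log
  likelihood?
* ``regress_word_presence`` — links component-specific word usage to the
  model's component probabilities (logistic, random intercept over
  participants).

Mixed models are estimated by maximum likelihood (not REML) so BICs are
comparable across fixed-effect specifications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

from .gp import GPModel, GrammarSearch, ObservedPattern
from .kernels import BASE_KERNELS
from .reconstruction import absolute_error, wavelet_distance
from .simulate import GameDataset

__all__ = [
    "RegressionResult",
    "compute_pattern_fits",
    "build_table",
    "regress_errors",
    "compare_models",
    "control_single_components",
    "regress_word_presence",
]

OUTCOMES = {"absolute_error": "absolute_error", "wavelet_distance": "wavelet_distance",
            "rating": "mean_rating", "mean_rating": "mean_rating"}


@dataclass
class RegressionResult:
    """Fixed effects, uncertainty and fit statistics of one regression."""

    params: pd.Series
    bse: pd.Series
    outcome: str
    predictors: tuple[str, ...]
    grouping: str | None
    loglike: float
    bic: float
    nobs: int
    fallback: bool = False   # random-slope fit was singular; intercept-only used
    flags: list[str] = field(default_factory=list)
    model_result: object = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"Regression: {self.outcome} ~ {' + '.join(self.predictors)}",
            f"  grouping: {self.grouping}   n = {self.nobs}",
            f"  log-likelihood = {self.loglike:.3f}   BIC = {self.bic:.3f}",
        ]
        for name in self.params.index:
            lines.append(f"  {name:>20s}  {self.params[name]:+.4f}  (SE {self.bse[name]:.4f})")
        if self.fallback:
            lines.append("  [random-slope fit singular; random-intercept fallback]")
        for fl in self.flags:
            lines.append(f"  [{fl}]")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------


def compute_pattern_fits(patterns, n_restarts: int = 3, seed: int | None = None) -> pd.DataFrame:
    """Per-pattern log likelihoods: best grammar structure, spectral mixture
    and the three single-component kernels.

    This is the expensive step (a grammar search per pattern); its output
    feeds :func:`build_table` and can be cached.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pat in patterns:
        data = ObservedPattern(pat.x, pat.y_standardized)
        gf = GrammarSearch(data, include_spectral=True).fit(
            n_restarts=n_restarts, seed=int(rng.integers(0, 2**31 - 1))
        )
        row = {
            "pattern_id": pat.pattern_id,
            "loglik_comp": gf.best_fit.log_ml,
            "loglik_spectral": gf.spectral_fit.log_ml,
            "best_structure": gf.best_fit.spec.label,
        }
        for comp in BASE_KERNELS:
            idx = [i for i, f in enumerate(gf.fits) if f.spec.expr == comp][0]
            row[f"loglik_{comp}"] = gf.fits[idx].log_ml
        for comp in BASE_KERNELS:
            row[f"prob_{comp}"] = gf.component_probability(comp, mode="softmax")
        rows.append(row)
    return pd.DataFrame(rows)


def _distances_from_dataset(dataset: GameDataset) -> pd.DataFrame:
    rows = []
    for dr in dataset.drawings:
        pat = dataset.pattern_by_id(dr.pattern_id)
        y = pat.y_standardized
        rows.append(
            {
                "pattern_id": dr.pattern_id,
                "drawer_id": dr.drawer_id,
                "absolute_error": absolute_error(y, dr.resampled),
                "wavelet_distance": wavelet_distance(y, dr.resampled),
            }
        )
    return pd.DataFrame(rows)


def zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def build_table(
    dataset: GameDataset,
    fits: pd.DataFrame,
    distances: pd.DataFrame | None = None,
    memorability: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per (pattern, drawer) pair with distances, ratings, log
    likelihoods and z-scored predictor columns (``z_`` prefix).

    Raises on identifiers present in one input but missing from another.
    """
    if distances is None:
        distances = _distances_from_dataset(dataset)
    table = distances.copy()

    pat_ids = {p.pattern_id for p in dataset.patterns}
    orphans = sorted(set(table["pattern_id"]) - pat_ids)
    if orphans:
        raise ValueError(f"distance rows reference unknown patterns: {orphans}")
    orphans = sorted(set(fits["pattern_id"]) - pat_ids)
    if orphans:
        raise ValueError(f"fit rows reference unknown patterns: {orphans}")
    missing = sorted(set(table["pattern_id"]) - set(fits["pattern_id"]))
    if missing:
        raise ValueError(f"patterns missing model fits: {missing}")

    table = table.merge(fits, on="pattern_id", how="left", validate="many_to_one")
    if len(dataset.ratings):
        mean_rating = (
            dataset.ratings.groupby(["pattern_id", "drawer_id"])["score"]
            .mean()
            .rename("mean_rating")
            .reset_index()
        )
        table = table.merge(mean_rating, on=["pattern_id", "drawer_id"], how="left")
    else:
        table["mean_rating"] = np.nan
    if memorability is not None:
        table = table.merge(
            memorability[["pattern_id", "memorability"]], on="pattern_id",
            how="left", validate="many_to_one",
        )
    src = dataset.ground_truth.get("source_class", {})
    table["is_compositional"] = [
        int(src.get(pid) == "compositional") for pid in table["pattern_id"]
    ]
    table["describer_id"] = [pid.split("_")[0] for pid in table["pattern_id"]]
    for col in table.columns:
        if col.startswith(("loglik_",)) or col == "memorability":
            table[f"z_{col}"] = zscore(table[col].to_numpy())
    return table


# ---------------------------------------------------------------------------
# Mixed-effects regressions
# ---------------------------------------------------------------------------


def _mixedlm_bic(res) -> float:
    k_fe = len(res.fe_params)
    k_re = res.cov_re.shape[0]
    k = k_fe + k_re * (k_re + 1) // 2 + 1  # + residual variance
    return float(-2.0 * res.llf + k * np.log(res.nobs))


def _fit_mixed(formula: str, data: pd.DataFrame, groups: str, re_formula: str | None,
               reml: bool = True):
    """Linear mixed model fit, retrying optimizers until the likelihood is
    finite (degenerate variance estimates give llf = inf).  REML by default
    for coefficient inference; ML refits supply comparable BICs."""
    last = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs"], ["bfgs"], ["powell"], ["cg"]):
            model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
            try:
                res = model.fit(reml=reml, method=method)
            except Exception:
                continue
            last = res
            if np.isfinite(res.llf) and not np.any(np.isnan(res.bse_fe)):
                return res
    if last is None:
        raise np.linalg.LinAlgError("mixed model could not be fitted")
    return last


def regress_errors(
    table: pd.DataFrame,
    outcome: str,
    predictors=("loglik_comp", "loglik_spectral"),
    grouping: str = "drawer_id",
    random_effects: tuple[str, ...] | None = None,
) -> RegressionResult:
    """Hierarchical regression of a communicability outcome on standardized
    model log likelihoods.

    Fits ``outcome ~ z(predictors)`` with a random intercept and random
    slopes for the predictors by ``grouping``; ``random_effects`` overrides
    the random-slope terms.  A singular or non-convergent random-slope fit
    falls back to a random intercept only (flagged).
    """
    outcome_col = OUTCOMES.get(outcome, outcome)
    if outcome_col not in table.columns:
        raise ValueError(f"unknown outcome {outcome!r}")
    predictors = tuple(predictors)
    if table[grouping].nunique() < 2:
        raise ValueError("need at least 2 groups")
    data = table[[outcome_col, grouping]].copy()
    if data[outcome_col].std() == 0:
        raise ValueError(f"outcome {outcome!r} is constant: degenerate fit")
    zcols = []
    for p in predictors:
        col = f"z_{p}"
        data[col] = table[col] if col in table.columns else zscore(table[p].to_numpy())
        zcols.append(col)
    re_terms = tuple(random_effects) if random_effects is not None else predictors
    re_cols = []
    for p in re_terms:
        col = f"z_{p}" if (f"z_{p}" in table.columns or p in predictors) else p
        if col not in data.columns:
            data[col] = table[col] if col in table.columns else table[p]
        re_cols.append(col)
    data = data.dropna(subset=[outcome_col])
    formula = f"{outcome_col} ~ " + " + ".join(zcols) if zcols else f"{outcome_col} ~ 1"
    re_formula = ("~" + " + ".join(re_cols)) if re_cols else None

    res, fallback, flags = None, False, []
    used_re = re_formula
    try:
        res = _fit_mixed(formula, data, grouping, re_formula)
        eigs = np.linalg.eigvalsh(np.atleast_2d(res.cov_re))
        if (
            (not res.converged)
            or not np.isfinite(res.llf)
            or np.any(eigs < -1e-8)
            or np.any(np.isnan(res.bse_fe))
        ):
            raise np.linalg.LinAlgError("singular random-effects fit")
    except Exception:
        res, fallback, used_re = None, True, None
    if res is None:
        res = _fit_mixed(formula, data, grouping, None)
    if not np.isfinite(res.llf):
        # degenerate even with a random intercept: report the fixed-effects
        # OLS fit so downstream BIC comparisons stay finite
        flags.append("mixed model degenerate; OLS fallback")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, data).fit()
        return RegressionResult(
            params=ols.params.rename(lambda s: s.replace("z_", "")),
            bse=ols.bse.rename(lambda s: s.replace("z_", "")),
            outcome=outcome_col,
            predictors=predictors,
            grouping=grouping,
            loglike=float(ols.llf),
            bic=float(ols.bic),
            nobs=int(ols.nobs),
            fallback=True,
            flags=flags,
            model_result=ols,
        )

    # ML refit of the same structure for a BIC comparable across fixed effects
    try:
        res_ml = _fit_mixed(formula, data, grouping, used_re, reml=False)
        if not np.isfinite(res_ml.llf):
            raise np.linalg.LinAlgError
    except Exception:
        res_ml = _fit_mixed(formula, data, grouping, None, reml=False)

    params = res.fe_params.rename(lambda s: s.replace("z_", ""))
    bse = res.bse_fe.rename(lambda s: s.replace("z_", ""))
    return RegressionResult(
        params=params,
        bse=bse,
        outcome=outcome_col,
        predictors=predictors,
        grouping=grouping,
        loglike=float(res_ml.llf),
        bic=_mixedlm_bic(res_ml),
        nobs=int(res.nobs),
        fallback=fallback,
        flags=flags,
        model_result=res,
    )


def compare_models(result_a: RegressionResult, result_b: RegressionResult) -> float:
    """BIC-approximate Bayes factor ``BF_ab = exp((BIC_b - BIC_a)/2)``.

    Values above 1 favor model a.  Both results must model the same outcome
    on the same rows.
    """
    if result_a.outcome != result_b.outcome or result_a.nobs != result_b.nobs:
        raise ValueError("models must share outcome and data rows")
    return float(np.exp((result_b.bic - result_a.bic) / 2.0))


def control_single_components(
    table: pd.DataFrame,
    outcome: str,
    grouping: str = "drawer_id",
) -> dict[str, dict]:
    """Single-component controls for the compositional advantage.

    For each base kernel, fits the outcome on that kernel's log likelihood
    alone (with the compositional flag among the random effects), then adds
    the compositional flag as a fixed effect, and reports the Bayes factor
    favoring the augmented model.
    """
    out: dict[str, dict] = {}
    for comp in BASE_KERNELS:
        pred = f"loglik_{comp}"
        base = regress_errors(
            table, outcome, predictors=(pred,), grouping=grouping,
            random_effects=(pred, "is_compositional"),
        )
        aug = regress_errors(
            table, outcome, predictors=(pred, "is_compositional"),
            grouping=grouping, random_effects=(pred, "is_compositional"),
        )
        if base.fallback != aug.fallback:
            # a BIC comparison is only meaningful across identical
            # random-effects structures; refit both at random intercepts
            base = regress_errors(table, outcome, predictors=(pred,),
                                  grouping=grouping, random_effects=())
            aug = regress_errors(table, outcome,
                                 predictors=(pred, "is_compositional"),
                                 grouping=grouping, random_effects=())
            base.flags.append("matched random-intercept refit for comparison")
            aug.flags.append("matched random-intercept refit for comparison")
        out[comp] = {
            "base": base,
            "with_flag": aug,
            "bf_flag": compare_models(aug, base),
        }
    return out


# ---------------------------------------------------------------------------
# Word presence vs. component probability
# ---------------------------------------------------------------------------


def regress_word_presence(
    descriptions,
    component_probs: pd.DataFrame,
    vocabularies: dict[str, list[str]],
    direction: str = "presence_on_prob",
) -> dict[str, RegressionResult]:
    """Relate composition-specific word usage to component probabilities.

    ``presence_on_prob`` (default): logistic regression of the binary
    presence of a component's words on the model's component probability,
    with a random intercept over describers.  ``prob_on_presence`` reverses
    the roles in a linear mixed model.  Returns one result per component.
    """
    if direction not in ("presence_on_prob", "prob_on_presence"):
        raise ValueError(f"unknown direction {direction!r}")
    for comp, words in vocabularies.items():
        if not words:
            raise ValueError(f"empty vocabulary for component {comp}")
    probs = component_probs.set_index("pattern_id")
    out: dict[str, RegressionResult] = {}
    for comp in BASE_KERNELS:
        rows = []
        for d in descriptions:
            if d.pattern_id not in probs.index:
                raise ValueError(f"description references unfitted pattern {d.pattern_id}")
            rows.append(
                {
                    "describer_id": d.describer_id,
                    "presence": int(bool(set(vocabularies[comp]) & set(d.tokens))),
                    "prob": float(probs.loc[d.pattern_id, f"prob_{comp}"]),
                }
            )
        df = pd.DataFrame(rows)
        df["z_prob"] = zscore(df["prob"].to_numpy())
        if direction == "prob_on_presence":
            res = regress_errors(
                df.assign(outcome=df["prob"]), "outcome", predictors=("presence",),
                grouping="describer_id", random_effects=(),
            )
            out[comp] = res
            continue
        flags: list[str] = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glmm = BinomialBayesMixedGLM.from_formula(
                "presence ~ z_prob", {"a": "0 + C(describer_id)"}, df
            )
            fit = glmm.fit_vb()
        names = list(fit.model.exog_names)
        params = pd.Series(fit.fe_mean, index=names).rename({"z_prob": "prob"})
        bse = pd.Series(fit.fe_sd, index=names).rename({"z_prob": "prob"})
        if np.abs(params["prob"]) > 10:
            flags.append("possible separation; penalized refit")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pen = sm.GLM(
                    df["presence"], sm.add_constant(df[["z_prob"]]),
                    family=sm.families.Binomial(),
                ).fit_regularized(alpha=1.0, L1_wt=0.0)
            params = pd.Series(
                {"Intercept": pen.params["const"], "prob": pen.params["z_prob"]}
            )
            bse = pd.Series({"Intercept": np.nan, "prob": np.nan})
        out[comp] = RegressionResult(
            params=params,
            bse=bse,
            outcome=f"presence[{comp}]",
            predictors=("prob",),
            grouping="describer_id",
            loglike=np.nan,
            bic=np.nan,
            nobs=len(df),
            flags=flags,
            model_result=fit,
        )
    return out
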