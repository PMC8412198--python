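"""Analysis table construction and the mixed-effects linking regressions."""

import numpy as np
import pandas as pd
import pytest

from patcomm.analysis import (
    build_table,
    compare_models,
    compute_pattern_fits,
    control_single_components,
    regress_errors,
    regress_word_presence,
    zscore,
)
from patcomm.simulate import DEFAULT_VOCABULARIES, GameConfig, simulate_game
from patcomm.text import Description


@pytest.fixture(scope="module")
def small_game_with_fits():
    ds = simulate_game(GameConfig(n_describers=2, n_drawers=2, n_raters=2,
                                  pool_oversample=2, seed=21))
    fits = compute_pattern_fits(ds.patterns, n_restarts=1, seed=0)
    return ds, fits


def _planted_table(seed, n=400, n_groups=15, beta=-0.2, null=False):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, n)
    ll_comp = rng.normal(0, 1, n)
    ll_spec = rng.normal(0, 1, n)
    y = 1.0 + rng.normal(0, 0.3, n_groups)[g] + rng.normal(0, 0.3, n)
    if not null:
        y = y + beta * zscore(ll_comp)
    return pd.DataFrame({
        "drawer_id": [f"w{i}" for i in g],
        "wavelet_distance": y,
        "loglik_comp": ll_comp,
        "loglik_spectral": ll_spec,
    })


def test_build_table_joins_and_standardizes(small_game_with_fits):
    ds, fits = small_game_with_fits
    table = build_table(ds, fits)
    n_pairs = len({(d.pattern_id, d.drawer_id) for d in ds.drawings})
    assert len(table) == n_pairs
    assert len(table) <= 2 * 6  # describers x patterns upper bound per drawer count
    for col in ("loglik_comp", "loglik_spectral", "loglik_LIN", "loglik_RBF", "loglik_PER"):
        assert not table[col].isna().any()
        z = table[f"z_{col}"]
        assert z.mean() == pytest.approx(0.0, abs=1e-10)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-10)
    again = build_table(ds, fits)
    pd.testing.assert_frame_equal(table, again)


def test_build_table_reports_orphan_identifiers(small_game_with_fits):
    ds, fits = small_game_with_fits
    bad = fits.copy()
    bad.loc[0, "pattern_id"] = "ghost_p9"
    with pytest.raises(ValueError, match="ghost_p9"):
        build_table(ds, bad)
    with pytest.raises(ValueError, match="missing model fits"):
        build_table(ds, fits.iloc[1:])


def test_regression_recovers_planted_coefficient():
    coefs = [
        regress_errors(_planted_table(s), "wavelet_distance").params["loglik_comp"]
        for s in range(5)
    ]
    assert all(abs(c + 0.2) <= 0.1 for c in coefs)


def test_regression_null_predictor_not_significant():
    """Type-I control: under a planted null the 2-SE interval covers zero at
    roughly its nominal ~95% rate (>= 17/20 rejects a calibrated model with
    probability < 2%)."""
    hits = 0
    for s in range(20):
        r = regress_errors(_planted_table(s, null=True), "wavelet_distance",
                           predictors=("loglik_comp",))
        hits += abs(r.params["loglik_comp"]) < 2 * r.bse["loglik_comp"]
    assert hits >= 17


def test_regression_constant_outcome_rejected():
    tab = _planted_table(0)
    tab["wavelet_distance"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        regress_errors(tab, "wavelet_distance")


def test_regression_requires_multiple_groups():
    tab = _planted_table(0)
    tab["drawer_id"] = "w0"
    with pytest.raises(ValueError, match="groups"):
        regress_errors(tab, "wavelet_distance")


def test_bayes_factor_identity_and_antisymmetry():
    a = regress_errors(_planted_table(1), "wavelet_distance", predictors=("loglik_comp",))
    b = regress_errors(_planted_table(1), "wavelet_distance", predictors=("loglik_spectral",))
    assert compare_models(a, a) == pytest.approx(1.0)
    assert compare_models(a, b) * compare_models(b, a) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compare_models(a, regress_errors(_planted_table(2, n=200), "wavelet_distance"))


def test_model_comparison_favors_true_predictor():
    wins = 0
    for s in range(5):
        tab = _planted_table(s)
        a = regress_errors(tab, "wavelet_distance", predictors=("loglik_comp",))
        b = regress_errors(tab, "wavelet_distance", predictors=("loglik_spectral",))
        wins += compare_models(a, b) > 10
    assert wins >= 4


def _flag_table(seed, n=400, n_groups=15, flag_effect=0.0):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, n_groups, n)
    flag = rng.integers(0, 2, n)
    lls = {c: rng.normal(0, 1, n) for c in ("LIN", "RBF", "PER")}
    y = 1.0 + rng.normal(0, 0.2, n_groups)[g] + 0.1 * zscore(lls["RBF"]) + rng.normal(0, 0.3, n)
    y = y - flag_effect * flag
    df = pd.DataFrame({
        "drawer_id": [f"w{i}" for i in g],
        "wavelet_distance": y,
        "is_compositional": flag,
    })
    for c, v in lls.items():
        df[f"loglik_{c}"] = v
    return df


def test_single_component_controls_detect_planted_flag():
    res = control_single_components(_flag_table(0, flag_effect=0.4), "wavelet_distance")
    assert set(res) == {"LIN", "RBF", "PER"}
    for comp, entry in res.items():
        assert entry["bf_flag"] > 3, comp


def test_single_component_controls_null_flag():
    res = control_single_components(_flag_table(1, flag_effect=0.0), "wavelet_distance")
    for comp, entry in res.items():
        assert entry["bf_flag"] < 3, comp


# -- word presence ------------------------------------------------------------


def _presence_inputs(seed, slope, n_desc=150):
    rng = np.random.default_rng(seed)
    probs = pd.DataFrame({
        "pattern_id": [f"d0_p{i}" for i in range(n_desc)],
        "prob_LIN": rng.uniform(0, 1, n_desc),
        "prob_RBF": rng.uniform(0, 1, n_desc),
        "prob_PER": rng.uniform(0, 1, n_desc),
    })
    descs = []
    for i in range(n_desc):
        words = []
        for comp, vocab in DEFAULT_VOCABULARIES.items():
            p = probs.loc[i, f"prob_{comp}"]
            logit = -1.0 + slope * (p - 0.5) / np.sqrt(1 / 12)
            if rng.random() < 1 / (1 + np.exp(-logit)):
                words.append(vocab[int(rng.integers(len(vocab)))])
        words.append("filler")
        descs.append(Description(f"d{i % 5}", f"d0_p{i}", " ".join(words)))
    return descs, probs


def test_word_presence_recovers_positive_slope():
    hits = 0
    for s in range(5):
        descs, probs = _presence_inputs(s, slope=1.5)
        res = regress_word_presence(descs, probs, DEFAULT_VOCABULARIES)
        hits += all(r.params["prob"] > 0 for r in res.values())
    assert hits >= 4


def test_word_presence_null_slope_covered_by_ci():
    """Under emission independent of component probabilities the 2-SE
    interval covers zero at close to its nominal rate (the bound 18/21
    rejects a calibrated model with probability < 2%)."""
    covered = 0
    total = 0
    for s in range(7):
        descs, probs = _presence_inputs(100 + s, slope=0.0)
        res = regress_word_presence(descs, probs, DEFAULT_VOCABULARIES)
        for r in res.values():
            total += 1
            covered += abs(r.params["prob"]) < 2 * r.bse["prob"]
    assert covered >= 18


def test_word_presence_reverse_direction_runs():
    descs, probs = _presence_inputs(7, slope=1.0)
    res = regress_word_presence(descs, probs, DEFAULT_VOCABULARIES,
                                direction="prob_on_presence")
    for r in res.values():
        assert "presence" in r.params.index


def test_word_presence_empty_vocabulary_rejected():
    descs, probs = _presence_inputs(0, slope=1.0, n_desc=20)
    with pytest.raises(ValueError, match="empty vocabulary"):
        regress_word_presence(descs, probs, {"LIN": [], "RBF": ["a"], "PER": ["b"]})
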