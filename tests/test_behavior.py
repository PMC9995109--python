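"""Discounting model, robust Bayesian t-test, and the mixed GLMs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from itcddm.behavior import (bayesian_ttest, fit_choice_mglm, fit_discounting,
                             fit_rt_mglm, hyperbolic_sv, softmax_ll_probability)
from itcddm.data import make_dataset, standardize_attributes
from itcddm.simulate import d2_template, generate_discounting_dataset


# -- closed forms -----------------------------------------------------------

def test_hyperbolic_identities():
    assert hyperbolic_sv(120.0, 30.0, 0.0) == 120.0
    assert hyperbolic_sv(120.0, 0.0, 0.3) == 120.0
    assert hyperbolic_sv(250.0, 60.0, 0.1) == pytest.approx(250.0 / 7.0)
    with pytest.raises(ValueError):
        hyperbolic_sv(10.0, 5.0, -0.1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0.01, 1.0), st.floats(0.5, 180.0), st.floats(0.5, 180.0))
def test_hyperbolic_monotone_in_delay_and_k(k, d1, d2):
    if d1 * (1 + 1e-9) < d2:
        assert hyperbolic_sv(100.0, d1, k) > hyperbolic_sv(100.0, d2, k)
    assert hyperbolic_sv(100.0, d1, k) < hyperbolic_sv(100.0, d1, k / 2.0)


def test_softmax_identities_and_antisymmetry():
    assert softmax_ll_probability(10.0, 10.0, 1.0) == 0.5
    assert softmax_ll_probability(20.0, 10.0, 1e6) == pytest.approx(1.0)
    assert softmax_ll_probability(20.0, 10.0, 0.1) == pytest.approx(
        1.0 / (1.0 + np.exp(-1.0)))
    p = softmax_ll_probability(17.0, 4.0, 0.2)
    q = softmax_ll_probability(4.0, 17.0, 0.2)
    assert p + q == pytest.approx(1.0, abs=1e-12)
    assert 0.0 < p < 1.0


# -- discounting fit --------------------------------------------------------

def test_discounting_recovery_from_known_generator():
    tpl = d2_template(n_participants=1, trials_per_session=100)
    df = generate_discounting_dataset(tpl, k=0.05, beta_temp=0.5, seed=7)
    fit = fit_discounting(df, seed=3)
    assert fit.k == pytest.approx(0.05, rel=0.2)
    lo, hi = np.quantile(fit.draws_beta, [0.025, 0.975])
    assert lo < 0.5 < hi
    assert not fit.flagged


def test_discounting_flags_degenerate_choices():
    tpl = d2_template(n_participants=1, trials_per_session=10)
    df = generate_discounting_dataset(tpl, k=0.0, beta_temp=0.0, seed=1)
    df["choice"] = 1
    fit = fit_discounting(df, n_iter=1000, burn=500, seed=2)
    assert fit.flagged
    with pytest.raises(ValueError):
        fit_discounting(df.head(3))


# -- Bayesian t-test --------------------------------------------------------

def test_ttest_null_straddles_zero(rng):
    x = rng.normal(0, 1, 40)
    res = bayesian_ttest(x, x.copy(), seed=1)
    assert res["hdi_lo"] <= 0.0 <= res["hdi_hi"]
    assert abs(res["mean"]) < 0.3


def test_ttest_recovers_unit_shift(rng):
    x = rng.normal(0, 1, 50)
    y = x + 1.0 + rng.normal(0, 0.1, 50)
    res = bayesian_ttest(y, x, seed=2)
    assert res["mean"] == pytest.approx(1.0, abs=0.15)
    assert res["excludes_zero"]
    paired = bayesian_ttest(y, x, paired=True, seed=2)
    assert paired["mean"] == pytest.approx(1.0, abs=0.05)
    assert paired["excludes_zero"]


# -- mixed GLMs -------------------------------------------------------------

def _logistic_dataset(rng, n_part=16, n_trials=80, beta=None):
    """Choices from a known hierarchical logistic model on the task design."""
    tpl = d2_template(n_participants=n_part, trials_per_session=n_trials // 2)
    from itcddm.simulate import generate_design
    df = generate_design(tpl, seed=int(rng.integers(1 << 30)))
    md = df["ll_magnitude"] - df["ss_magnitude"]
    dd = df["ll_delay"] - df["ss_delay"]
    md = (md - md.mean()) / md.std(ddof=1)
    dd = (dd - dd.mean()) / dd.std(ddof=1)
    drug = (df["drug"] != 0).astype(float)
    beta = beta or {"intercept": 0.5, "drug": -0.3, "dd": -1.0, "md": 2.0}
    eta = (beta["intercept"] + beta["drug"] * drug + beta["dd"] * dd
           + beta["md"] * md)
    u = rng.normal(0, 0.4, n_part)
    pid_idx = pd.factorize(df["participant_id"])[0]
    eta = eta + u[pid_idx]
    p = 1 / (1 + np.exp(-eta))
    df = df.copy()
    df["choice"] = (rng.random(len(df)) < p).astype(int)
    df["rt"] = rng.uniform(1, 5, len(df))
    return standardize_attributes(make_dataset(df)), beta


def test_choice_mglm_recovers_fixed_effects(rng):
    ds, beta = _logistic_dataset(rng)
    res = fit_choice_mglm(ds, seed=11)
    t = res["table"].set_index("predictor")
    for name, truth in [("Intercept", beta["intercept"]), ("Drug", beta["drug"]),
                        ("Delay_diff", beta["dd"]), ("Magnitude_diff", beta["md"])]:
        assert t.loc[name, "hdi_lo"] - 0.3 <= truth <= t.loc[name, "hdi_hi"] + 0.3
    assert t.loc["Magnitude_diff", "mean"] > 1.0
    assert t.loc["Delay_diff", "mean"] < -0.3


def test_choice_mglm_null_predictor_contains_zero(rng):
    ds, _ = _logistic_dataset(rng)
    # permute choices to break every association
    trials = ds.trials.copy()
    trials["choice"] = rng.permutation(trials["choice"].to_numpy())
    ds2 = standardize_attributes(make_dataset(trials))
    res = fit_choice_mglm(ds2, n_iter=4000, burn=2000, seed=12)
    t = res["table"].set_index("predictor")
    for name in ("Delay_diff", "Magnitude_diff", "Drug"):
        assert t.loc[name, "hdi_lo"] <= 0.0 <= t.loc[name, "hdi_hi"]


def test_rt_mglm_recovers_known_slope(rng):
    ds, _ = _logistic_dataset(rng)
    trials = ds.trials.copy()
    msum = ds.design["magnitude_sum"].to_numpy()
    pid_idx = pd.factorize(trials["participant_id"])[0]
    u = rng.normal(0, 0.2, pid_idx.max() + 1)
    log_rt = 1.2 - 0.25 * msum + u[pid_idx] + rng.normal(0, 0.3, len(trials))
    trials["rt"] = np.exp(log_rt)
    ds2 = standardize_attributes(make_dataset(trials))
    res = fit_rt_mglm(ds2, seed=13)
    t = res["table"].set_index("predictor")
    assert t.loc["Magnitude_sum", "hdi_lo"] <= -0.25 <= t.loc["Magnitude_sum", "hdi_hi"]
    assert t.loc["Magnitude_sum", "mean"] < -0.1
    # predictors with no generated effect stay near zero
    assert t.loc["Drug", "hdi_lo"] <= 0.0 <= t.loc["Drug", "hdi_hi"]


def test_mglm_trial_index_predictors():
    tpl = d2_template(n_participants=6, trials_per_session=20)
    rng = np.random.default_rng(9)
    ds, _ = _logistic_dataset(rng, n_part=6, n_trials=40)
    res = fit_choice_mglm(ds, include_trial_index=True, n_iter=1500, burn=800,
                          seed=3)
    assert "Trial" in res["predictors"]
    assert "Drug x Trial" in res["predictors"]
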