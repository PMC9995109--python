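"""Variant matrix conformance and the trial-level parameter mappings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itcddm.variants import (BIAS_HI, BIAS_LO, CoefficientSet, DesignRow,
                             ParameterError, VARIANTS, bias_regression,
                             drift_discounted_value, drift_linear,
                             drift_time_varying, get_variant, map_trial,
                             sigmoid_link, threshold_and_ndt,
                             trial_params_kernel)
from itcddm.data import ChoiceTrial
from itcddm.wiener import upper_choice_probability

TABLE2 = CoefficientSet(
    drift_magnitude_diff=2.41, drift_drug_magnitude_diff=0.81,
    drift_delay_diff=-1.13, drift_drug_delay_diff=-0.30,
    v_max=0.80, drug_v_max=0.0, bias_intercept=0.57, bias_drug=-0.04,
    bias_delay=-0.02, bias_drug_delay=0.02, threshold_intercept=3.96,
    threshold_drug=0.17, ndt_intercept=1.48, ndt_drug=-0.10)


def _trial(ssm=100, ssd=0, llm=250, lld=60, rt=3.0):
    return ChoiceTrial("p1", "s1", 0.0, ssm, ssd, llm, lld, 1, rt)


# -- variant matrix ---------------------------------------------------------

EXPECTED_SLOTS = {
    # free-coefficient sets per variant (within-subject coding)
    "ddm1": list(range(14)),
    "ddm2": [0, 1, 2, 3, 4, 5, 10, 11, 12, 13],
    "ddm3": [4, 5, 6, 7, 8, 9, 10, 11, 12, 13],
    "ddm4": list(range(14)),
    "ddm5": [4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15],
    "ddm6": [0, 1, 2, 3, 4, 5, 6, 7, 10, 11, 12, 13, 16],
}


@pytest.mark.parametrize("name", sorted(VARIANTS))
def test_variant_free_parameter_sets(name):
    assert VARIANTS[name].active_slots("within_subject") == EXPECTED_SLOTS[name]


def test_between_subject_drops_drug_interaction_slots():
    slots = VARIANTS["ddm1"].active_slots("between_subject")
    assert slots == [0, 2, 4, 6, 8, 10, 12]


# -- drift ------------------------------------------------------------------

def test_drift_linear_examples():
    assert drift_linear(DesignRow(0, 0), CoefficientSet()) == 0.0
    row = DesignRow(magnitude_diff=1.0, delay_diff=0.0)
    assert drift_linear(row, TABLE2) == pytest.approx(2.41)
    row = DesignRow(magnitude_diff=1.0, delay_diff=1.0)
    assert drift_linear(row, TABLE2) == pytest.approx(2.41 - 1.13)


def test_sigmoid_link_identities():
    assert sigmoid_link(0.0, TABLE2, 0.0) == 0.0
    assert sigmoid_link(1e4, TABLE2, 0.0) == pytest.approx(0.80)
    assert sigmoid_link(-1e4, TABLE2, 0.0) == pytest.approx(-0.80)
    assert sigmoid_link(2.41, TABLE2, 0.0) == pytest.approx(
        0.80 * math.tanh(1.205), abs=1e-12)
    with pytest.raises(ParameterError):
        sigmoid_link(1.0, CoefficientSet(v_max=0.0), 0.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.floats(-30, 30), st.floats(-30, 30))
def test_sigmoid_link_odd_bounded_monotone(v1, v2):
    c = CoefficientSet(v_max=0.8)
    y1 = sigmoid_link(v1, c, 0.0)
    assert abs(y1) < 0.8
    assert sigmoid_link(-v1, c, 0.0) == pytest.approx(-y1, abs=1e-12)
    if v1 < v2:
        assert y1 < sigmoid_link(v2, c, 0.0)


def test_drift_discounted_value():
    t = _trial()
    assert drift_discounted_value(t, CoefficientSet(k_disc=0.0), 0.0) == \
        pytest.approx(150.0)  # kd = 0: plain magnitude difference
    assert drift_discounted_value(t, CoefficientSet(k_disc=0.1), 0.0) == \
        pytest.approx(250.0 / 7.0 - 100.0)
    same = _trial(ssm=100, ssd=10, llm=100, lld=10)
    assert drift_discounted_value(same, CoefficientSet(k_disc=0.3), 0.0) == 0.0
    with pytest.raises(ParameterError):
        drift_discounted_value(t, CoefficientSet(k_disc=-0.05), 0.0)


def test_ddm5_drift_decreases_with_discount_weight():
    t = _trial(ssm=100, ssd=0, llm=250, lld=60)
    vals = [drift_discounted_value(t, CoefficientSet(k_disc=k), 0.0)
            for k in np.linspace(0.0, 0.5, 11)]
    assert all(b <= a for a, b in zip(vals, vals[1:]))


def test_drift_time_varying_branches():
    c = CoefficientSet(drift_magnitude_diff=2.0, drift_delay_diff=-1.0)
    row = DesignRow(magnitude_diff=1.0, delay_diff=1.0)
    # synchronous onsets: plain sum at every RT
    assert drift_time_varying(row, c, 0.0, rt=3.0, tau=1.0) == pytest.approx(1.0)
    # decision ends before the late attribute comes online: early term alone
    c2 = CoefficientSet(drift_magnitude_diff=2.0, drift_delay_diff=-1.0, tau_diff=0.5)
    assert drift_time_varying(row, c2, 0.0, rt=1.3, tau=1.0) == pytest.approx(-1.0)
    # duration-weighted average: (0.5*(-1) + 0.5*(2-1)) / 1.0 = 0
    assert drift_time_varying(row, c2, 0.0, rt=2.0, tau=1.0) == pytest.approx(0.0)
    # magnitude-first variant (tau_diff < 0)
    c3 = CoefficientSet(drift_magnitude_diff=2.0, drift_delay_diff=-1.0, tau_diff=-0.5)
    assert drift_time_varying(row, c3, 0.0, rt=1.3, tau=1.0) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        drift_time_varying(row, c2, 0.0, rt=0.9, tau=1.0)


# -- bias / threshold / ndt -------------------------------------------------

def test_bias_regression_examples():
    v1 = get_variant("ddm1")
    assert bias_regression(DesignRow(0, 0), TABLE2, 0.0, v1) == pytest.approx(0.57)
    assert bias_regression(DesignRow(0, 0), TABLE2, 1.0, v1) == pytest.approx(0.53)
    assert bias_regression(DesignRow(0, 1.0), TABLE2, 0.0, v1) == pytest.approx(0.55)
    assert bias_regression(DesignRow(0, 5.0), TABLE2, 0.0, get_variant("ddm2")) == 0.5
    # DDM-4 uses the delay sum instead of the difference
    row = DesignRow(0, delay_diff=9.0, delay_sum=1.0)
    assert bias_regression(row, TABLE2, 0.0, get_variant("ddm4")) == pytest.approx(0.55)


def test_threshold_and_ndt_examples():
    a, tau = threshold_and_ndt(TABLE2, 0.0)
    assert (a, tau) == pytest.approx((3.96, 1.48))
    a, tau = threshold_and_ndt(TABLE2, 1.0)
    assert (a, tau) == pytest.approx((3.96 + 0.17, 1.48 - 0.10))


# -- composition ------------------------------------------------------------

def test_map_trial_per_variant():
    row0 = DesignRow(0.0, 0.0)
    # covariate-free trial under DDM-1: v = 0, z = intercept
    p = map_trial(_trial(), row0, TABLE2, get_variant("ddm1"))
    assert p.v == 0.0 and p.z == pytest.approx(0.57)
    # DDM-2: bias always 0.5
    p = map_trial(_trial(), DesignRow(1.0, -2.0), TABLE2, get_variant("ddm2"))
    assert p.z == 0.5
    # DDM-3 with zero v_max terms: drift 0, choice probability equals zeta
    c3 = CoefficientSet(v_max=0.0, bias_intercept=0.6, threshold_intercept=2.0,
                        ndt_intercept=0.3)
    p = map_trial(_trial(), row0, c3, get_variant("ddm3"))
    assert p.v == 0.0
    assert upper_choice_probability(p) == pytest.approx(p.z)


def test_map_trial_rejects_out_of_range_bias():
    c = CoefficientSet(v_max=0.8, bias_intercept=0.99, threshold_intercept=2.0,
                       ndt_intercept=0.3)
    with pytest.raises(ParameterError):
        map_trial(_trial(), DesignRow(0, 0), c, get_variant("ddm1"))
    assert not (BIAS_LO < 0.99 < BIAS_HI)


def test_map_trial_saturates_at_v_max():
    row = DesignRow(magnitude_diff=5.0, delay_diff=0.0)
    p = map_trial(_trial(), row, TABLE2, get_variant("ddm1"))
    assert p.v == pytest.approx(0.80, abs=1e-4)


def test_linear_link_ablation():
    spec = get_variant("ddm1", sigmoid_link=False)
    row = DesignRow(magnitude_diff=1.0, delay_diff=0.0)
    p = map_trial(_trial(), row, TABLE2, spec)
    assert p.v == pytest.approx(2.41)


def test_kernel_agrees_with_reference_mapping(rng):
    """The compiled kernel and the readable composition must agree for every
    variant on random coefficient draws."""
    for name in sorted(VARIANTS):
        spec = get_variant(name)
        for _ in range(25):
            vec = TABLE2.to_vector() + rng.normal(0, 0.05, 17)
            vec[14] = abs(vec[14]) * 0.01  # small non-negative discount weight
            vec[16] = rng.normal(0, 0.2)
            c = CoefficientSet.from_vector(vec)
            drug = float(rng.integers(0, 2))
            row = DesignRow(magnitude_diff=float(rng.normal()),
                            delay_diff=float(rng.normal()),
                            delay_sum=float(rng.normal()), drug_code=drug)
            trial = _trial(rt=float(rng.uniform(2.5, 6.0)))
            v, a, z, tau, ok = trial_params_kernel(
                vec, row.magnitude_diff, row.delay_diff, row.delay_sum, drug,
                trial.ss_magnitude, trial.ss_delay, trial.ll_magnitude,
                trial.ll_delay, trial.rt, spec.code, spec.sigmoid_link)
            try:
                ref = map_trial(trial, row, c, spec)
            except ParameterError:
                assert not ok
                continue
            assert ok
            assert (v, a, z, tau) == pytest.approx(
                (ref.v, ref.a, ref.z, ref.tau), rel=1e-12)
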