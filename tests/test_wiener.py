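"""First-passage density, closed-form choice probability and simulator."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_1samp

from itcddm.wiener import (WienerParams, dataset_loglik, fpt_density,
                           simulate_trials, upper_choice_probability,
                           wiener_pdf)

GRID = [(v, a, z) for v in (-2.0, 0.0, 1.0, 3.0)
        for a in (0.5, 2.0) for z in (0.2, 0.5, 0.8)]


def _mass(params, choice, upper_t=200.0):
    return quad(lambda t: fpt_density(t, choice, params), params.tau,
                params.tau + upper_t, limit=300)[0]


def test_parameter_validation():
    with pytest.raises(ValueError):
        WienerParams(v=0, a=-1, z=0.5)
    with pytest.raises(ValueError):
        WienerParams(v=0, a=1, z=1.2)
    with pytest.raises(ValueError):
        WienerParams(v=0, a=1, z=0.5, tau=-0.1)


def test_density_zero_outside_support():
    p = WienerParams(v=1, a=2, z=0.5, tau=0.5)
    assert fpt_density(0.4, 1, p) == 0.0
    assert fpt_density(0.5, 0, p) == 0.0
    assert fpt_density(0.6, 1, p) > 0.0


@pytest.mark.parametrize("v,a,z", [(0.0, 2.0, 0.5), (1.0, 2.0, 0.5),
                                   (-2.0, 0.5, 0.8), (3.0, 2.0, 0.2)])
def test_mass_conservation_and_absorption_probability(v, a, z):
    p = WienerParams(v=v, a=a, z=z)
    up = _mass(p, 1)
    lo = _mass(p, 0)
    assert abs(up + lo - 1.0) < 1e-6
    assert abs(up - upper_choice_probability(p)) < 1e-6


def test_closed_form_choice_probability_values():
    assert upper_choice_probability(WienerParams(v=0, a=2, z=0.37)) == pytest.approx(0.37)
    p = upper_choice_probability(WienerParams(v=1, a=2, z=0.5))
    expected = (1 - np.exp(-2 * 1 * 2 * 0.5)) / (1 - np.exp(-2 * 1 * 2))
    assert p == pytest.approx(expected, abs=1e-12)
    assert p == pytest.approx(0.8808, abs=1e-4)
    assert upper_choice_probability(WienerParams(v=60, a=2, z=0.5)) == pytest.approx(1.0)
    assert upper_choice_probability(WienerParams(v=-60, a=2, z=0.5)) == pytest.approx(0.0)


def test_reflection_symmetry():
    for v, a, z in GRID:
        for t in (0.2, 0.8, 2.5):
            up = wiener_pdf(t, 1, v, a, z, 0.0)
            mirrored = wiener_pdf(t, 0, -v, a, 1.0 - z, 0.0)
            assert up == pytest.approx(mirrored, abs=1e-10)
    # densities are non-negative everywhere on the grid
    for v, a, z in GRID:
        assert wiener_pdf(0.05, 1, v, a, z, 0.0) >= 0.0


def test_overwhelming_drift_hits_upper_boundary():
    ch, rt = simulate_trials(WienerParams(v=50, a=2, z=0.5), 10_000, seed=1)
    assert ch.mean() >= 0.999
    assert (rt > 0).all()


def test_simulator_matches_closed_form_choice_fraction():
    p = WienerParams(v=1, a=2, z=0.5, tau=0.3)
    n = 50_000
    ch, rt = simulate_trials(p, n, seed=7)
    target = upper_choice_probability(p)
    se = np.sqrt(target * (1 - target) / n)
    assert abs(ch.mean() - target) < 3 * se
    assert rt.min() > p.tau


def test_zero_drift_mean_decision_time():
    # E[T] = a^2 z (1-z) for v = 0
    p = WienerParams(v=0, a=2, z=0.5, tau=0.2)
    ch, rt = simulate_trials(p, 50_000, seed=11)
    dt = rt - p.tau
    se = dt.std(ddof=1) / np.sqrt(dt.size)
    assert abs(dt.mean() - 1.0) < 3 * se


def test_simulated_rt_distribution_matches_density():
    """KS test of simulated upper-boundary RTs against the numerically
    integrated conditional first-passage CDF."""
    p = WienerParams(v=1.0, a=2.0, z=0.5, tau=0.0)
    n = 50_000
    ch, rt = simulate_trials(p, n, seed=13)
    rts = rt[ch == 1]
    p_up = upper_choice_probability(p)
    grid = np.linspace(1e-4, 40, 4000)
    pdf = np.array([wiener_pdf(t, 1, p.v, p.a, p.z, 0.0) for t in grid])
    cdf = np.cumsum(pdf) * (grid[1] - grid[0]) / p_up
    cdf = np.clip(cdf / cdf[-1], 0, 1)

    def cdf_fn(x):
        return np.interp(x, grid, cdf)

    res = ks_1samp(rts, cdf_fn)
    assert res.pvalue > 0.001


def test_dataset_loglik_additivity_and_support(small_pp):
    ds = small_pp
    sub = ds.trials.head(10)
    from itcddm.data import Dataset
    small = Dataset(trials=sub.reset_index(drop=True), study_design=ds.study_design)
    params = [WienerParams(v=0.5, a=3.0, z=0.55, tau=0.5) for _ in range(10)]
    total = dataset_loglik(small, params)
    brute = sum(np.log(fpt_density(r.rt, int(r.choice), params[i]))
                for i, r in enumerate(sub.itertuples()))
    assert total == pytest.approx(brute, rel=1e-12)
    # support violation -> -inf
    bad = [WienerParams(v=0.5, a=3.0, z=0.55, tau=float(sub["rt"].max() + 1))] * 10
    assert dataset_loglik(small, bad) == -np.inf
    with pytest.raises(ValueError):
        dataset_loglik(small, params[:5])


def test_simulation_reproducible_given_seed():
    p = WienerParams(v=0.3, a=3.0, z=0.6, tau=1.0)
    a1 = simulate_trials(p, 500, seed=99)
    a2 = simulate_trials(p, 500, seed=99)
    np.testing.assert_array_equal(a1[0], a2[0])
    np.testing.assert_array_equal(a1[1], a2[1])
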