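"""Posterior predictive checks, parameter recovery, and choice-probability
surfaces.

The posterior predictive check regenerates every trial's (choice, rt) from
the individual-level posterior parameter estimates (posterior means by
default; full-draw mode optional), bins trials into quintiles of the
magnitude and delay differences, and compares observed with
simulation-averaged mean response times per (binning x bin x condition)
cell.  The summary score is the mean over cells of the squared
observed-minus-simulated difference; lower is better.  Simulated trials
inherit each real trial's covariates - only the behavior is regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, make_dataset, standardize_attributes
from .inference import (MCMCSettings, PosteriorSamples, compute_hdi,
                        fit_hierarchical_ddm, _trial_arrays)
from .variants import CoefficientSet, DesignRow, VariantSpec, trial_params_kernel
from .wiener import _upper_prob, simulate_trials_varying


@dataclass
class PPCReport:
    """Observed vs simulated mean RTs per quintile cell, plus the pooled
    squared-difference score."""

    cells: pd.DataFrame
    score: float
    by_participant: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


def _quintile_bins(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Assign near-equal-size rank bins (sizes differ by <= 1); ties broken
    by stable sort on position (trial order)."""
    n = values.shape[0]
    order = np.argsort(values, kind="stable")
    bins = np.empty(n, dtype=np.int64)
    splits = np.array_split(np.arange(n), n_bins)
    for b, chunk in enumerate(splits):
        bins[order[chunk]] = b
    return bins


def _trial_wiener_params(samples: PosteriorSamples, dataset: Dataset,
                         variant: VariantSpec):
    """Trial-level (v, a, z, tau) under each participant's posterior-mean
    coefficients, in the sampler's participant-sorted trial order."""
    arrays, part_start, group_of, groups, participants = _trial_arrays(dataset)
    coeff = samples.individual_means()
    n = arrays["rt"].shape[0]
    v = np.empty(n)
    a = np.empty(n)
    z = np.empty(n)
    tau = np.empty(n)
    for i, pid in enumerate(participants):
        s, e = part_start[i], part_start[i + 1]
        c = np.ascontiguousarray(coeff[i])
        for t in range(s, e):
            vt, at, zt, tt, ok = trial_params_kernel(
                c, arrays["mdiff"][t], arrays["ddiff"][t], arrays["dsum"][t],
                arrays["drugc"][t], arrays["ssm"][t], arrays["ssd"][t],
                arrays["llm"][t], arrays["lld"][t], arrays["rt"][t],
                variant.code, variant.sigmoid_link)
            if not ok:
                raise ValueError(
                    f"posterior-mean parameters inadmissible for trial {t}")
            v[t], a[t], z[t], tau[t] = vt, at, zt, tt
    return arrays, part_start, participants, v, a, z, tau


def posterior_predictive_check(samples: PosteriorSamples, dataset: Dataset,
                               variant: VariantSpec | None = None,
                               n_sims: int = 1000, seed: int = 0,
                               dt: float = 1e-3, n_bins: int = 5,
                               by_participant: bool = False) -> PPCReport:
    """Simulate ``n_sims`` behavioral datasets from the individual posterior
    means and compare quintile-binned mean RTs with the observed data."""
    variant = variant or samples.variant
    arrays, part_start, participants, v, a, z, tau = _trial_wiener_params(
        samples, dataset, variant)
    n = v.shape[0]
    rt_obs = arrays["rt"]
    cond = arrays["drugc"]
    sim_rt = np.empty((n_sims, n))
    for s in range(n_sims):
        _, rts = simulate_trials_varying(v, a, z, tau,
                                         (int(seed) + 7 * s + 1) % (2**31 - 1), dt)
        sim_rt[s] = rts

    cells = []
    conds = np.unique(cond)
    for attr_name, attr in (("magnitude_diff", arrays["mdiff"]),
                            ("delay_diff", arrays["ddiff"])):
        for c in conds:
            mask = cond == c
            bins = _quintile_bins(attr[mask], n_bins)
            idx = np.nonzero(mask)[0]
            for b in range(n_bins):
                sel = idx[bins == b]
                obs = float(rt_obs[sel].mean())
                sim_means = sim_rt[:, sel].mean(axis=1)
                cells.append({
                    "binning": attr_name, "bin": b + 1, "condition": float(c),
                    "n_trials": int(sel.size), "observed_mean_rt": obs,
                    "simulated_mean_rt": float(sim_means.mean()),
                    "env_lo": float(np.quantile(sim_means, 0.025)),
                    "env_hi": float(np.quantile(sim_means, 0.975)),
                })
    cells_df = pd.DataFrame(cells)
    score = float(np.mean(
        (cells_df["observed_mean_rt"] - cells_df["simulated_mean_rt"]) ** 2))

    per_part = None
    if by_participant:
        rows = []
        for i, pid in enumerate(participants):
            s, e = part_start[i], part_start[i + 1]
            for attr_name, attr in (("magnitude_diff", arrays["mdiff"]),
                                    ("delay_diff", arrays["ddiff"])):
                bins = _quintile_bins(attr[s:e], n_bins)
                for b in range(n_bins):
                    sel = np.nonzero(bins == b)[0] + s
                    if sel.size == 0:
                        continue
                    rows.append({
                        "participant_id": pid, "binning": attr_name,
                        "bin": b + 1,
                        "observed_mean_rt": float(rt_obs[sel].mean()),
                        "simulated_mean_rt": float(sim_rt[:, sel].mean()),
                    })
        per_part = pd.DataFrame(rows)
    return PPCReport(cells=cells_df, score=score, by_participant=per_part,
                     meta={"n_sims": n_sims, "variant": variant.variant_id})


def simulate_from_fit(samples: PosteriorSamples, dataset: Dataset,
                      variant: VariantSpec, seed: int,
                      dt: float = 1e-3) -> Dataset:
    """One synthetic dataset from the fitted model's posterior-mean group
    parameters: new individual coefficients ~ N(mu, lambda), new behavior,
    the original trial covariates."""
    arrays, part_start, group_of, groups, participants = _trial_arrays(dataset)
    mu_mean = samples.mu.mean(axis=(0, 1))          # (group, effect)
    lam_mean = samples.lam.mean(axis=(0, 1))        # (effect,)
    rng = np.random.default_rng(int(seed))
    n = arrays["rt"].shape[0]
    v = np.empty(n)
    a = np.empty(n)
    z = np.empty(n)
    tau = np.empty(n)
    for i in range(len(participants)):
        s, e = part_start[i], part_start[i + 1]
        g = group_of[i]
        for _ in range(500):
            c = np.zeros(len(CoefficientSet().to_vector()))
            c[samples.slots] = mu_mean[g] + lam_mean * rng.standard_normal(lam_mean.size)
            ok_all = True
            for t in range(s, e):
                vt, at, zt, tt, ok = trial_params_kernel(
                    c, arrays["mdiff"][t], arrays["ddiff"][t], arrays["dsum"][t],
                    arrays["drugc"][t], arrays["ssm"][t], arrays["ssd"][t],
                    arrays["llm"][t], arrays["lld"][t], 1.0,
                    variant.code, variant.sigmoid_link)
                if not ok:
                    ok_all = False
                    break
                v[t], a[t], z[t], tau[t] = vt, at, zt, tt
            if ok_all:
                break
        if not ok_all:
            raise RuntimeError("could not draw admissible recovery parameters")
    sim_seed = int(rng.integers(0, 2**31 - 1))
    choices, rts = simulate_trials_varying(v, a, z, tau, sim_seed, dt)

    # rebuild a trial table in the sampler's sorted order
    df = dataset.trials.reset_index(drop=True)
    order = df["participant_id"].astype(str).to_numpy()
    idx = np.concatenate([np.nonzero(order == p)[0] for p in participants])
    new_df = df.iloc[idx].reset_index(drop=True).copy()
    new_df["choice"] = choices
    new_df["rt"] = rts
    ds = make_dataset(new_df, study_design=dataset.study_design)
    return standardize_attributes(ds)


def parameter_recovery(fitted: PosteriorSamples, dataset: Dataset,
                       variant: VariantSpec | None = None,
                       n_datasets: int = 10, seed: int = 0,
                       mcmc: MCMCSettings | None = None,
                       dt: float = 1e-3) -> pd.DataFrame:
    """Simulate ``n_datasets`` datasets from the fitted posterior means,
    refit each, and report whether every refit group-level posterior mean
    lies inside the original 95% HDI.  Deterministic given ``seed``."""
    variant = variant or fitted.variant
    rows = []
    for d in range(int(n_datasets)):
        ds_seed = (int(seed) + 7919 * d + 13) % (2**31 - 1)
        sim = simulate_from_fit(fitted, dataset, variant, ds_seed, dt)
        refit = fit_hierarchical_ddm(sim, variant, mcmc=mcmc, seed=ds_seed)
        mu_refit = refit.mu.mean(axis=(0, 1))
        for g, glab in enumerate(fitted.groups):
            for j, eff in enumerate(fitted.effects):
                lo, hi = compute_hdi(fitted.mu[:, :, g, j].reshape(-1), 0.95)
                est = float(mu_refit[g, j])
                rows.append({"dataset": d, "group": glab, "effect": eff,
                             "refit_mean": est, "hdi_lo": lo, "hdi_hi": hi,
                             "recovered": bool(lo <= est <= hi)})
    return pd.DataFrame(rows, columns=["dataset", "group", "effect",
                                       "refit_mean", "hdi_lo", "hdi_hi",
                                       "recovered"])


def choice_probability_surface(coeffs_placebo: CoefficientSet,
                               coeffs_drug: CoefficientSet,
                               variant: VariantSpec,
                               magnitude_grid=None, delay_grid=None,
                               n_sims: int = 0, seed: int = 0,
                               dt: float = 1e-3) -> pd.DataFrame:
    """P(LL choice) over a grid of standardized attribute differences under
    two conditions, and their difference.

    With ``n_sims = 0`` the closed-form absorption probability is used;
    otherwise each cell is estimated from ``n_sims`` simulated trials.  Both
    conditions are evaluated with drug coded 0 (the condition difference is
    carried by the two coefficient sets).
    """
    if magnitude_grid is None:
        magnitude_grid = np.linspace(-2.0, 2.0, 9)
    if delay_grid is None:
        delay_grid = np.linspace(-2.0, 2.0, 9)
    rows = []
    rng = np.random.default_rng(int(seed))
    for md in magnitude_grid:
        for dd in delay_grid:
            probs = {}
            for label, cs in (("placebo", coeffs_placebo), ("drug", coeffs_drug)):
                c = cs.to_vector()
                v, a, z, tau, ok = trial_params_kernel(
                    c, float(md), float(dd), 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                    1.0, variant.code, variant.sigmoid_link)
                if not ok:
                    raise ValueError(
                        f"inadmissible parameters at cell ({md}, {dd})")
                if n_sims > 0:
                    ch, _ = simulate_trials_varying(
                        np.full(n_sims, v), np.full(n_sims, a),
                        np.full(n_sims, z), np.full(n_sims, tau),
                        int(rng.integers(0, 2**31 - 1)), dt)
                    probs[label] = float(ch.mean())
                else:
                    probs[label] = float(_upper_prob(v, a, z))
            rows.append({"magnitude_diff": float(md), "delay_diff": float(dd),
                         "p_ll_placebo": probs["placebo"],
                         "p_ll_drug": probs["drug"],
                         "difference": probs["drug"] - probs["placebo"]})
    return pd.DataFrame(rows)
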