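"""Hierarchical Bayesian estimation of the DDM variant coefficients.

Model
-----
For every free coefficient of the chosen variant, individual-level values are
normally distributed around a group-level mean with a per-effect standard
deviation lambda.  Group-level means carry standard-normal priors; each
lambda carries a Gamma prior (default Gamma(1, 1), weakly informative on the
scale of standardized regressors).  In the between-subject design a separate
group-level mean is estimated for every dose group (lambda is shared across
groups per effect).

Sampling
--------
Adaptive Metropolis-within-Gibbs, compiled with numba: per participant, the
coefficient vector is updated in three blocks (drift, bias,
threshold/non-decision) by random-walk proposals whose scales adapt toward a
~25% acceptance rate during warm-up; group-level means are Gibbs-updated
(normal-normal conjugacy) and lambdas move on the log scale.  Admissibility
constraints (a > 0, 0.02 < zeta < 0.98, tau >= 0, v_max > 0 under the
sigmoidal link, kd >= 0) are enforced by proposal rejection so coefficients
keep the identity scale of the reported tables.

Convergence is summarized by rank-normalized split R-hat (< 1.01 passes) and
effective sample sizes via arviz.  Model comparison uses the deviance
information criterion DIC = D_bar + pD with pD = D_bar - D(theta_bar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from numba import njit

from .data import BETWEEN_SUBJECT, Dataset, WITHIN_SUBJECT
from .variants import (N_SLOTS, SLOT_NAMES, VariantSpec, participant_loglik)

logger = logging.getLogger("itcddm")

#: fixed per-slot reference scales for random-walk proposals
REF_SCALE = np.array([
    0.30, 0.30, 0.30, 0.30,   # drift attribute weights
    0.15, 0.15,               # v_max terms
    0.03, 0.03, 0.010, 0.010,  # bias terms
    0.15, 0.15,               # threshold
    0.05, 0.05,               # non-decision time
    0.02, 0.02,               # discount weight (DDM-5)
    0.05,                     # tau_diff (DDM-6)
])

_BLOCKS = (
    (0, 1, 2, 3, 4, 5, 14, 15),   # drift
    (6, 7, 8, 9),                 # bias
    (10, 11, 12, 13, 16),         # threshold / non-decision
)


@dataclass(frozen=True)
class HierarchicalPrior:
    """Priors: N(group_mean_loc, group_mean_scale) on every group-level
    effect; Gamma(lambda_shape, lambda_rate) on each lambda (SD)."""

    group_mean_loc: float = 0.0
    group_mean_scale: float = 1.0
    lambda_shape: float = 1.0
    lambda_rate: float = 1.0

    def __post_init__(self):
        if self.lambda_shape <= 0 or self.lambda_rate <= 0:
            raise ValueError("gamma hyperparameters must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain/sample settings.  Desk-scale defaults; ``paper_scale`` restores
    the long-run protocol (2 x 500k draws, 450k burn, thin 5 for the
    within-subject study; 2 x 100k, 50k, thin 5 for the between-subject
    study)."""

    n_chains: int = 2
    n_sweeps: int = 20_000
    warmup: int = 10_000
    thin: int = 5

    def __post_init__(self):
        if min(self.n_chains, self.n_sweeps, self.thin) < 1 or self.warmup < 0:
            raise ValueError("mcmc settings must be positive")
        if self.warmup >= self.n_sweeps:
            raise ValueError("warmup must be smaller than n_sweeps")

    @classmethod
    def paper_scale(cls, study_design: str = WITHIN_SUBJECT) -> "MCMCSettings":
        if study_design == WITHIN_SUBJECT:
            return cls(n_chains=2, n_sweeps=500_000, warmup=450_000, thin=5)
        return cls(n_chains=2, n_sweeps=100_000, warmup=50_000, thin=5)


@dataclass
class ConvergenceReport:
    rhat: dict
    ess: dict
    passed: bool

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())


@dataclass
class PosteriorSamples:
    """MCMC draws for one hierarchical DDM fit.

    Group-level draws have shape (chain, draw, group, effect); individual
    draws (chain, draw, participant, effect); lambdas (chain, draw, effect).
    """

    variant: VariantSpec
    study_design: str
    effects: list                     # active slot names
    slots: np.ndarray                 # active slot indices
    groups: list                      # group labels (dose levels or ["all"])
    participants: list
    mu: np.ndarray
    lam: np.ndarray
    ind: np.ndarray
    loglik: np.ndarray                # (chain, draw) total data log-likelihood
    seed: int = 0
    meta: dict = field(default_factory=dict)

    # -- summaries ----------------------------------------------------------
    def group_draws(self, effect: str, group=None) -> np.ndarray:
        j = self.effects.index(effect)
        g = 0 if group is None else self.groups.index(group)
        return self.mu[:, :, g, j].reshape(-1)

    def individual_means(self) -> np.ndarray:
        """Posterior-mean coefficient vector per participant, full 17 slots."""
        out = np.zeros((len(self.participants), N_SLOTS))
        m = self.ind.mean(axis=(0, 1))
        out[:, self.slots] = m
        return out

    def convergence(self) -> ConvergenceReport:
        data = {}
        for j, name in enumerate(self.effects):
            for g, glab in enumerate(self.groups):
                key = name if len(self.groups) == 1 else f"{name}[{glab}]"
                data[key] = self.mu[:, :, g, j]
            data[f"lambda_{name}"] = self.lam[:, :, j]
        idata = az.convert_to_dataset(data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        rhat_d = {k: float(rhat[k].values) for k in data}
        ess_d = {k: float(ess[k].values) for k in data}
        return ConvergenceReport(rhat=rhat_d, ess=ess_d,
                                 passed=max(rhat_d.values()) < 1.01)

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for g, glab in enumerate(self.groups):
            for j, name in enumerate(self.effects):
                draws = self.mu[:, :, g, j].reshape(-1)
                lo, hi = compute_hdi(draws, mass)
                rows.append({"group": glab, "effect": name,
                             "mean": float(draws.mean()),
                             "sd": float(draws.std(ddof=1)),
                             "hdi_lo": lo, "hdi_hi": hi})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "variant": self.variant.variant_id,
            "study_design": self.study_design,
            "groups": list(map(str, self.groups)),
            "summary": self.summary().to_dict(orient="records"),
            "meta": self.meta,
        }


def compute_hdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


def contrast_conditions(samples: PosteriorSamples, effect: str,
                        groups: tuple, mass: float = 0.95) -> dict:
    """Posterior of the difference of one group-level effect between two
    groups (elementwise over draws)."""
    j = samples.effects.index(effect)
    g1 = samples.groups.index(groups[0])
    g2 = samples.groups.index(groups[1])
    diff = (samples.mu[:, :, g1, j] - samples.mu[:, :, g2, j]).reshape(-1)
    lo, hi = compute_hdi(diff, mass)
    return {"effect": effect, "groups": tuple(groups), "draws": diff,
            "mean": float(diff.mean()), "hdi_lo": lo, "hdi_hi": hi}


# ---------------------------------------------------------------------------
# compiled chain runner
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cholesky_lower(a, out):
    """In-place lower Cholesky of ``a`` into ``out``; returns False if the
    matrix is not positive definite."""
    n = a.shape[0]
    for k in range(n):
        for m in range(n):
            out[k, m] = 0.0
    for k in range(n):
        s = a[k, k]
        for m in range(k):
            s -= out[k, m] * out[k, m]
        if s <= 0.0:
            return False
        out[k, k] = np.sqrt(s)
        for r in range(k + 1, n):
            s = a[r, k]
            for m in range(k):
                s -= out[r, m] * out[k, m]
            out[r, k] = s / out[k, k]
    return True


@njit(cache=True)
def _run_chain(mdiff, ddiff, dsum, drugc, ssm, ssd, llm, lld, rt, choice,
               part_start, group_of, n_groups,
               active, block_ptr, block_slots,
               init_ind, init_mu, init_lam, ref_scale,
               mu_loc, mu_scale, lam_shape, lam_rate,
               n_sweeps, warmup, thin, seed, variant, sigmoid):
    np.random.seed(seed)
    n_part = part_start.shape[0] - 1
    n_blocks = block_ptr.shape[0] - 1
    ind = init_ind.copy()
    mu = init_mu.copy()
    lam = init_lam.copy()

    ll = np.empty(n_part)
    for i in range(n_part):
        s, e = part_start[i], part_start[i + 1]
        ll[i] = participant_loglik(ind[i], mdiff[s:e], ddiff[s:e], dsum[s:e],
                                   drugc[s:e], ssm[s:e], ssd[s:e], llm[s:e],
                                   lld[s:e], rt[s:e], choice[s:e],
                                   variant, sigmoid)

    # adaptive proposal state per (participant, block): log step scale plus a
    # running covariance of the block coordinates (Haario-style adaptation,
    # frozen after warm-up so the chain is ergodic on the retained draws)
    log_scale = np.zeros((n_part, n_blocks))
    d_max = 0
    for b in range(n_blocks):
        d_b = block_ptr[b + 1] - block_ptr[b]
        if d_b > d_max:
            d_max = d_b
    ad_mean = np.zeros((n_part, n_blocks, d_max))
    ad_m2 = np.zeros((n_part, n_blocks, d_max, d_max))
    ad_n = np.zeros((n_part, n_blocks))
    chol = np.zeros((n_part, n_blocks, d_max, d_max))
    use_cov = np.zeros((n_part, n_blocks), dtype=np.bool_)
    # group translation move state (shift a group mean and all its members'
    # coefficients together; decouples group-level from individual mixing)
    tr_log_scale = np.full((n_groups, n_blocks), np.log(0.3))
    ll_tmp = np.empty(n_part)
    n_keep = 0
    for sweep in range(warmup, n_sweeps):
        if (sweep - warmup) % thin == 0:
            n_keep += 1
    mu_draws = np.empty((n_keep, n_groups, N_SLOTS))
    lam_draws = np.empty((n_keep, N_SLOTS))
    ind_draws = np.empty((n_keep, n_part, N_SLOTS))
    ll_draws = np.empty(n_keep)
    kept = 0

    prop = np.empty(N_SLOTS)
    for sweep in range(n_sweeps):
        adapt = sweep < warmup
        gamma = 1.0 / (1.0 + 0.05 * sweep) ** 0.6 if adapt else 0.0
        # refresh covariance-informed proposal factors periodically
        if adapt and sweep > 0 and sweep % 50 == 0:
            for i in range(n_part):
                for b in range(n_blocks):
                    bs, be = block_ptr[b], block_ptr[b + 1]
                    d_b = be - bs
                    if d_b == 0 or ad_n[i, b] < 20.0 * d_b:
                        continue
                    cov = np.empty((d_b, d_b))
                    fac = (2.38 * 2.38 / d_b) / (ad_n[i, b] - 1.0)
                    for k in range(d_b):
                        for m in range(d_b):
                            cov[k, m] = ad_m2[i, b, k, m] * fac
                        cov[k, k] += 1e-9 + 1e-6 * cov[k, k]
                    L = np.empty((d_b, d_b))
                    if _cholesky_lower(cov, L):
                        for k in range(d_b):
                            for m in range(d_b):
                                chol[i, b, k, m] = L[k, m]
                        if not use_cov[i, b]:
                            use_cov[i, b] = True
                            log_scale[i, b] = 0.0
        # --- individual-level blocks (two scans per sweep for mixing) ---
        for i in range(n_part):
            s, e = part_start[i], part_start[i + 1]
            g = group_of[i]
            for b in range(2 * n_blocks):
                b = b % n_blocks
                bs, be = block_ptr[b], block_ptr[b + 1]
                d_b = be - bs
                if d_b == 0:
                    continue
                for k in range(N_SLOTS):
                    prop[k] = ind[i, k]
                step = np.exp(log_scale[i, b])
                if use_cov[i, b]:
                    eps = np.empty(d_b)
                    for k in range(d_b):
                        eps[k] = np.random.normal()
                    for k in range(d_b):
                        j = block_slots[bs + k]
                        delta = 0.0
                        for m in range(k + 1):
                            delta += chol[i, b, k, m] * eps[m]
                        prop[j] = ind[i, j] + step * delta
                else:
                    for k in range(bs, be):
                        j = block_slots[k]
                        prop[j] = ind[i, j] + step * ref_scale[j] * np.random.normal()
                llp = participant_loglik(prop, mdiff[s:e], ddiff[s:e], dsum[s:e],
                                         drugc[s:e], ssm[s:e], ssd[s:e],
                                         llm[s:e], lld[s:e], rt[s:e],
                                         choice[s:e], variant, sigmoid)
                accepted = False
                if llp > -np.inf:
                    dprior = 0.0
                    for k in range(bs, be):
                        j = block_slots[k]
                        lj2 = lam[j] * lam[j]
                        dprior += -0.5 * ((prop[j] - mu[g, j]) ** 2
                                          - (ind[i, j] - mu[g, j]) ** 2) / lj2
                    if np.log(np.random.random()) < llp - ll[i] + dprior:
                        for k in range(bs, be):
                            j = block_slots[k]
                            ind[i, j] = prop[j]
                        ll[i] = llp
                        accepted = True
                if adapt:
                    target = 1.0 if accepted else 0.0
                    log_scale[i, b] += gamma * (target - 0.28)
                    if log_scale[i, b] < -8.0:
                        log_scale[i, b] = -8.0
                    elif log_scale[i, b] > 4.0:
                        log_scale[i, b] = 4.0
                    # running covariance of the block coordinates (Welford)
                    ad_n[i, b] += 1.0
                    n_ad = ad_n[i, b]
                    delta_old = np.empty(d_b)
                    for k in range(d_b):
                        j = block_slots[bs + k]
                        delta_old[k] = ind[i, j] - ad_mean[i, b, k]
                        ad_mean[i, b, k] += delta_old[k] / n_ad
                    for k in range(d_b):
                        jk = block_slots[bs + k]
                        dnew_k = ind[i, jk] - ad_mean[i, b, k]
                        for m in range(d_b):
                            ad_m2[i, b, m, k] += delta_old[m] * dnew_k
        # --- group translation moves (mean + members shifted jointly) ---
        for b in range(n_blocks):
            bs, be = block_ptr[b], block_ptr[b + 1]
            d_b = be - bs
            if d_b == 0:
                continue
            for g in range(n_groups):
                step = np.exp(tr_log_scale[g, b])
                delta = np.empty(d_b)
                for k in range(d_b):
                    delta[k] = step * ref_scale[block_slots[bs + k]] * np.random.normal()
                total_cur = 0.0
                total_prop = 0.0
                feasible = True
                for i in range(n_part):
                    if group_of[i] != g:
                        continue
                    total_cur += ll[i]
                    for k in range(N_SLOTS):
                        prop[k] = ind[i, k]
                    for k in range(d_b):
                        prop[block_slots[bs + k]] += delta[k]
                    s, e = part_start[i], part_start[i + 1]
                    llp = participant_loglik(prop, mdiff[s:e], ddiff[s:e],
                                             dsum[s:e], drugc[s:e], ssm[s:e],
                                             ssd[s:e], llm[s:e], lld[s:e],
                                             rt[s:e], choice[s:e],
                                             variant, sigmoid)
                    if llp == -np.inf:
                        feasible = False
                        break
                    ll_tmp[i] = llp
                    total_prop += llp
                accepted = False
                if feasible:
                    dprior = 0.0
                    for k in range(d_b):
                        j = block_slots[bs + k]
                        mu_new = mu[g, j] + delta[k]
                        dprior += -0.5 * (((mu_new - mu_loc) ** 2
                                           - (mu[g, j] - mu_loc) ** 2)
                                          / (mu_scale * mu_scale))
                    if np.log(np.random.random()) < total_prop - total_cur + dprior:
                        accepted = True
                        for k in range(d_b):
                            j = block_slots[bs + k]
                            mu[g, j] += delta[k]
                        for i in range(n_part):
                            if group_of[i] != g:
                                continue
                            for k in range(d_b):
                                j = block_slots[bs + k]
                                ind[i, j] += delta[k]
                            ll[i] = ll_tmp[i]
                if adapt:
                    tr_log_scale[g, b] += gamma * ((1.0 if accepted else 0.0) - 0.25)
                    if tr_log_scale[g, b] < -8.0:
                        tr_log_scale[g, b] = -8.0
                    elif tr_log_scale[g, b] > 3.0:
                        tr_log_scale[g, b] = 3.0
        # --- group-level updates ---
        for jj in range(active.shape[0]):
            j = active[jj]
            lj2 = lam[j] * lam[j]
            for g in range(n_groups):
                sb = 0.0
                ng = 0
                for i in range(n_part):
                    if group_of[i] == g:
                        sb += ind[i, j]
                        ng += 1
                prec = 1.0 / (mu_scale * mu_scale) + ng / lj2
                mean = (mu_loc / (mu_scale * mu_scale) + sb / lj2) / prec
                mu[g, j] = mean + np.random.normal() / np.sqrt(prec)
            # lambda: random walk on log scale, Gamma(shape, rate) prior on lam
            cur = lam[j]
            prop_l = cur * np.exp(0.25 * np.random.normal())
            ss_cur = 0.0
            for i in range(n_part):
                d = ind[i, j] - mu[group_of[i], j]
                ss_cur += d * d
            def_cur = (lam_shape * np.log(cur) - lam_rate * cur
                       - n_part * np.log(cur) - 0.5 * ss_cur / (cur * cur))
            def_prop = (lam_shape * np.log(prop_l) - lam_rate * prop_l
                        - n_part * np.log(prop_l) - 0.5 * ss_cur / (prop_l * prop_l))
            if np.log(np.random.random()) < def_prop - def_cur:
                lam[j] = prop_l
        # --- record ---
        if sweep >= warmup and (sweep - warmup) % thin == 0:
            for g in range(n_groups):
                for k in range(N_SLOTS):
                    mu_draws[kept, g, k] = mu[g, k]
            for k in range(N_SLOTS):
                lam_draws[kept, k] = lam[k]
            for i in range(n_part):
                for k in range(N_SLOTS):
                    ind_draws[kept, i, k] = ind[i, k]
            tot = 0.0
            for i in range(n_part):
                tot += ll[i]
            ll_draws[kept] = tot
            kept += 1
    return mu_draws, lam_draws, ind_draws, ll_draws


# ---------------------------------------------------------------------------
# data preparation and public fitting API
# ---------------------------------------------------------------------------

def _trial_arrays(dataset: Dataset):
    """Concatenated per-trial arrays sorted by participant, plus participant
    offsets and group indices."""
    if dataset.design is None:
        raise ValueError("dataset must be preprocessed (standardize_attributes)")
    df = dataset.trials.reset_index(drop=True)
    des = dataset.design.reset_index(drop=True)
    order = df["participant_id"].astype(str).to_numpy()
    participants = sorted(pd.unique(order))
    idx = np.concatenate([np.nonzero(order == p)[0] for p in participants])
    df = df.iloc[idx].reset_index(drop=True)
    des = des.iloc[idx].reset_index(drop=True)

    counts = [int((order == p).sum()) for p in participants]
    part_start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    if dataset.study_design == BETWEEN_SUBJECT:
        dose_of = df.groupby("participant_id")["drug"].first()
        group_levels = sorted(pd.unique(df["drug"].astype(float)))
        group_of = np.array([group_levels.index(float(dose_of[p]))
                             for p in participants], dtype=np.int64)
        groups = group_levels
        drugc = np.zeros(len(df))  # drug is carried by group membership
    else:
        groups = ["all"]
        group_of = np.zeros(len(participants), dtype=np.int64)
        drugc = des["drug_code"].to_numpy(dtype=float)

    arrays = dict(
        mdiff=des["magnitude_diff"].to_numpy(float),
        ddiff=des["delay_diff"].to_numpy(float),
        dsum=des["delay_sum"].to_numpy(float),
        drugc=drugc,
        ssm=df["ss_magnitude"].to_numpy(float),
        ssd=df["ss_delay"].to_numpy(float),
        llm=df["ll_magnitude"].to_numpy(float),
        lld=df["ll_delay"].to_numpy(float),
        rt=df["rt"].to_numpy(float),
        choice=df["choice"].to_numpy(np.int64),
    )
    return arrays, part_start, group_of, groups, participants


def _blocks_for(active: np.ndarray):
    ptr = [0]
    slots = []
    for block in _BLOCKS:
        slots.extend([j for j in block if j in set(active.tolist())])
        ptr.append(len(slots))
    return (np.asarray(ptr, dtype=np.int64), np.asarray(slots, dtype=np.int64))


def _init_state(arrays, part_start, group_of, n_groups, active, seed):
    """Group means at neutral values (threshold 2, bias 0.5, v_max 1, ndt at
    half the minimum RT), individuals jittered per chain."""
    rng = np.random.default_rng(seed)
    n_part = part_start.shape[0] - 1
    min_rt = float(arrays["rt"].min())
    mu0 = np.zeros(N_SLOTS)
    mu0[4] = 1.0
    mu0[6] = 0.5
    mu0[10] = 2.0
    mu0[12] = 0.5 * min_rt
    init_mu = np.tile(mu0, (n_groups, 1))
    init_lam = np.full(N_SLOTS, 1.0)
    init_ind = np.tile(mu0, (n_part, 1))
    for i in range(n_part):
        s, e = part_start[i], part_start[i + 1]
        # keep tau strictly inside each participant's RT support
        init_ind[i, 12] = min(0.5 * min_rt, 0.45 * float(arrays["rt"][s:e].min()))
        jit = rng.normal(size=active.size) * 0.02 * REF_SCALE[active]
        init_ind[i, active] += jit
        init_ind[i, 12] = abs(init_ind[i, 12])
    return init_ind, init_mu, init_lam


def fit_hierarchical_ddm(dataset: Dataset, variant: VariantSpec,
                         prior: HierarchicalPrior | None = None,
                         mcmc: MCMCSettings | None = None,
                         seed: int = 0) -> PosteriorSamples:
    """Fit one DDM variant hierarchically; deterministic given ``seed``.

    The dataset must be preprocessed (RT-trimmed and standardized).  Returns
    posterior draws for all group-level means, lambdas and individual-level
    coefficients, with total data log-likelihood per retained draw."""
    prior = prior or HierarchicalPrior()
    mcmc = mcmc or MCMCSettings()
    arrays, part_start, group_of, groups, participants = _trial_arrays(dataset)
    n_groups = len(groups)
    active = np.asarray(variant.active_slots(dataset.study_design), dtype=np.int64)
    block_ptr, block_slots = _blocks_for(active)

    mu_chains, lam_chains, ind_chains, ll_chains = [], [], [], []
    for c in range(mcmc.n_chains):
        chain_seed = (int(seed) + 7919 * c + 1) % (2**31 - 1)
        init_ind, init_mu, init_lam = _init_state(
            arrays, part_start, group_of, n_groups, active, chain_seed)
        _check_init(arrays, part_start, init_ind, variant)
        mu_d, lam_d, ind_d, ll_d = _run_chain(
            arrays["mdiff"], arrays["ddiff"], arrays["dsum"], arrays["drugc"],
            arrays["ssm"], arrays["ssd"], arrays["llm"], arrays["lld"],
            arrays["rt"], arrays["choice"],
            part_start, group_of, n_groups,
            active, block_ptr, block_slots,
            init_ind, init_mu, init_lam, REF_SCALE,
            prior.group_mean_loc, prior.group_mean_scale,
            prior.lambda_shape, prior.lambda_rate,
            mcmc.n_sweeps, mcmc.warmup, mcmc.thin, chain_seed,
            variant.code, variant.sigmoid_link)
        mu_chains.append(mu_d[:, :, active])
        lam_chains.append(lam_d[:, active])
        ind_chains.append(ind_d[:, :, active])
        ll_chains.append(ll_d)

    samples = PosteriorSamples(
        variant=variant, study_design=dataset.study_design,
        effects=[SLOT_NAMES[j] for j in active], slots=active,
        groups=groups, participants=participants,
        mu=np.stack(mu_chains), lam=np.stack(lam_chains),
        ind=np.stack(ind_chains), loglik=np.stack(ll_chains), seed=int(seed),
        meta={"mcmc": {"n_chains": mcmc.n_chains, "n_sweeps": mcmc.n_sweeps,
                       "warmup": mcmc.warmup, "thin": mcmc.thin}},
    )
    report = samples.convergence()
    samples.meta["max_rhat"] = report.max_rhat
    samples.meta["converged"] = report.passed
    if not report.passed:
        logger.warning("max R-hat %.4f >= 1.01: treat estimates with care",
                       report.max_rhat)
    return samples


def _check_init(arrays, part_start, init_ind, variant) -> None:
    n_part = part_start.shape[0] - 1
    for i in range(n_part):
        s, e = part_start[i], part_start[i + 1]
        ll = participant_loglik(
            init_ind[i], arrays["mdiff"][s:e], arrays["ddiff"][s:e],
            arrays["dsum"][s:e], arrays["drugc"][s:e], arrays["ssm"][s:e],
            arrays["ssd"][s:e], arrays["llm"][s:e], arrays["lld"][s:e],
            arrays["rt"][s:e], arrays["choice"][s:e],
            variant.code, variant.sigmoid_link)
        if not np.isfinite(ll):
            raise RuntimeError(
                f"initial likelihood undefined for participant index {i}")


def dataset_loglik_at(dataset: Dataset, variant: VariantSpec,
                      coeff_matrix: np.ndarray) -> float:
    """Total log-likelihood with one full coefficient vector per participant
    (rows ordered as in the fit)."""
    arrays, part_start, group_of, groups, participants = _trial_arrays(dataset)
    total = 0.0
    for i in range(len(participants)):
        s, e = part_start[i], part_start[i + 1]
        ll = participant_loglik(
            np.ascontiguousarray(coeff_matrix[i], dtype=float),
            arrays["mdiff"][s:e], arrays["ddiff"][s:e], arrays["dsum"][s:e],
            arrays["drugc"][s:e], arrays["ssm"][s:e], arrays["ssd"][s:e],
            arrays["llm"][s:e], arrays["lld"][s:e], arrays["rt"][s:e],
            arrays["choice"][s:e], variant.code, variant.sigmoid_link)
        total += ll
    return float(total)


def dic_from_deviance(dev_draws, dev_at_mean: float) -> dict:
    """DIC = D_bar + pD with pD = D_bar - D(theta_bar)."""
    dev_draws = np.asarray(dev_draws, dtype=float).ravel()
    d_bar = float(dev_draws.mean())
    pd_eff = d_bar - float(dev_at_mean)
    return {"dic": d_bar + pd_eff, "d_bar": d_bar,
            "d_hat": float(dev_at_mean), "pd": pd_eff}


def compute_dic(samples: PosteriorSamples, dataset: Dataset,
                variant: VariantSpec | None = None) -> dict:
    """Deviance information criterion of a fit; deviance = -2 log L.

    ``theta_bar`` is the posterior mean of the individual-level coefficients
    (the parameters the likelihood depends on)."""
    variant = variant or samples.variant
    ll_at_mean = dataset_loglik_at(dataset, variant, samples.individual_means())
    if not np.isfinite(ll_at_mean):
        raise ValueError("likelihood undefined at the posterior mean")
    return dic_from_deviance(-2.0 * samples.loglik, -2.0 * ll_at_mean)
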