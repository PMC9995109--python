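"""Model-free and value-based behavioral analyses.

* hyperbolic discounting (``SV = magnitude / (1 + k * delay)``) with softmax
  choice, fit per participant and session on a bounded scale
  (k in (0, 1) per day, inverse temperature in (0, 5)), 2 chains x 4000
  Metropolis iterations with 2000 burn-in;
* a robust Bayesian t-test (t likelihood with estimated scale and normality
  parameters) on, e.g., log-k under the two drug conditions, in the
  two-group and paired flavours;
* hierarchical Bayesian mixed GLMs: logistic for LL-vs-SS choice and linear
  for log response time, with participant-level random intercepts and random
  slopes for every predictor.  Fixed effects carry N(0, 5) priors and
  random-effect SDs half-normal(1) priors (package defaults, overridable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ndtr

from .data import Dataset, WITHIN_SUBJECT
from .inference import compute_hdi

# ---------------------------------------------------------------------------
# hyperbolic discounting + softmax
# ---------------------------------------------------------------------------

K_MAX = 1.0
BETA_MAX = 5.0


def hyperbolic_sv(magnitude: float, delay: float, k: float) -> float:
    """Hyperbolically discounted subjective value ``magnitude / (1 + k*delay)``."""
    if k < 0 or delay < 0:
        raise ValueError("k and delay must be non-negative")
    return magnitude / (1.0 + k * delay)


def softmax_ll_probability(sv_ll: float, sv_ss: float, beta_temp: float) -> float:
    """Softmax probability of choosing the larger-later option."""
    if beta_temp < 0:
        raise ValueError("beta_temp must be non-negative")
    x = beta_temp * (sv_ll - sv_ss)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass
class DiscountingFit:
    participant_id: str
    session_id: str
    k: float
    beta_temp: float
    log_k: float
    draws_k: np.ndarray
    draws_beta: np.ndarray
    flagged: bool = False
    meta: dict = field(default_factory=dict)


@njit(cache=True)
def _disc_loglik(raw_k, raw_b, sv_num_ll, sv_den_ll, sv_num_ss, sv_den_ss, choice):
    # bounded transforms: k = K_MAX * Phi(raw_k), beta = BETA_MAX * Phi(raw_b)
    k = 1.0 * 0.5 * (1.0 + math.erf(raw_k / math.sqrt(2.0)))
    b = 5.0 * 0.5 * (1.0 + math.erf(raw_b / math.sqrt(2.0)))
    total = 0.0
    for i in range(choice.shape[0]):
        sv_ll = sv_num_ll[i] / (1.0 + k * sv_den_ll[i])
        sv_ss = sv_num_ss[i] / (1.0 + k * sv_den_ss[i])
        x = b * (sv_ll - sv_ss)
        # log Bernoulli(choice; logistic(x)), stable
        if x >= 0:
            lp1 = -math.log1p(math.exp(-x))
        else:
            lp1 = x - math.log1p(math.exp(x))
        lp0 = lp1 - x
        total += lp1 if choice[i] == 1 else lp0
    # standard-normal priors on the raw parameters
    total += -0.5 * (raw_k * raw_k + raw_b * raw_b)
    return total


@njit(cache=True)
def _disc_chain(llm, lld, ssm, ssd, choice, n_iter, burn, seed):
    np.random.seed(seed)
    raw = np.zeros(2)
    ll = _disc_loglik(raw[0], raw[1], llm, lld, ssm, ssd, choice)
    scale = np.array([0.5, 0.5])
    n_keep = n_iter - burn
    out = np.empty((n_keep, 2))
    kept = 0
    for it in range(n_iter):
        gamma = 1.0 / (1.0 + 0.1 * it) ** 0.6 if it < burn else 0.0
        for j in range(2):
            prop = raw.copy()
            prop[j] += scale[j] * np.random.normal()
            llp = _disc_loglik(prop[0], prop[1], llm, lld, ssm, ssd, choice)
            acc = np.log(np.random.random()) < llp - ll
            if acc:
                raw = prop
                ll = llp
            if gamma > 0.0:
                scale[j] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.35))
                scale[j] = min(max(scale[j], 1e-3), 10.0)
        if it >= burn:
            out[kept, 0] = raw[0]
            out[kept, 1] = raw[1]
            kept += 1
    return out


def fit_discounting(trials: pd.DataFrame, n_iter: int = 4000, burn: int = 2000,
                    n_chains: int = 2, seed: int = 0) -> DiscountingFit:
    """Fit the hyperbolic + softmax model to one participant-session's trials.

    Requires at least 5 trials; all-same choices are fit but flagged (the
    discount rate is then only bounded, not located, by the data)."""
    if len(trials) < 5:
        raise ValueError("need at least 5 trials")
    ch = trials["choice"].to_numpy(np.int64)
    flagged = ch.min() == ch.max()
    llm = trials["ll_magnitude"].to_numpy(float)
    lld = trials["ll_delay"].to_numpy(float)
    ssm = trials["ss_magnitude"].to_numpy(float)
    ssd = trials["ss_delay"].to_numpy(float)
    draws = []
    for c in range(n_chains):
        draws.append(_disc_chain(llm, lld, ssm, ssd, ch, n_iter, burn,
                                 (int(seed) + 4099 * c + 1) % (2**31 - 1)))
    raw = np.concatenate(draws, axis=0)
    k_draws = K_MAX * ndtr(raw[:, 0])
    b_draws = BETA_MAX * ndtr(raw[:, 1])
    k_hat = float(k_draws.mean())
    pid = str(trials["participant_id"].iloc[0]) if "participant_id" in trials else ""
    sid = str(trials["session_id"].iloc[0]) if "session_id" in trials else ""
    return DiscountingFit(
        participant_id=pid, session_id=sid, k=k_hat,
        beta_temp=float(b_draws.mean()), log_k=float(np.log(k_draws).mean()),
        draws_k=k_draws, draws_beta=b_draws, flagged=bool(flagged))


def fit_discounting_by_session(dataset: Dataset, seed: int = 0, **kw) -> pd.DataFrame:
    """Fit the discounting model separately for each participant and session;
    returns one row per fit with k, beta_temp, log_k and the drug condition."""
    rows = []
    for (pid, sid), grp in dataset.trials.groupby(["participant_id", "session_id"]):
        fit = fit_discounting(grp, seed=(int(seed) + abs(hash((pid, sid))) % 10000), **kw)
        rows.append({"participant_id": pid, "session_id": sid,
                     "drug": float(grp["drug"].iloc[0]), "k": fit.k,
                     "beta_temp": fit.beta_temp, "log_k": fit.log_k,
                     "flagged": fit.flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# robust Bayesian t-test (BEST-style)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _t_logpdf(x, mu, sigma, nu):
    z = (x - mu) / sigma
    return (math.lgamma((nu + 1.0) / 2.0) - math.lgamma(nu / 2.0)
            - 0.5 * math.log(nu * math.pi) - math.log(sigma)
            - (nu + 1.0) / 2.0 * math.log(1.0 + z * z / nu))


@njit(cache=True)
def _best_logpost(theta, x, y, pool_mean, pool_sd, paired):
    # theta = (mu1, mu2, log_s1, log_s2, log_numinus1)
    mu1, mu2 = theta[0], theta[1]
    s1 = math.exp(theta[2])
    s2 = math.exp(theta[3])
    nu = 1.0 + math.exp(theta[4])
    lp = 0.0
    for i in range(x.shape[0]):
        lp += _t_logpdf(x[i], mu1, s1, nu)
    if not paired:
        for i in range(y.shape[0]):
            lp += _t_logpdf(y[i], mu2, s2, nu)
    # broad priors on the data scale (BEST-style)
    lp += -0.5 * ((mu1 - pool_mean) / (1000.0 * pool_sd)) ** 2
    lp += -0.5 * ((mu2 - pool_mean) / (1000.0 * pool_sd)) ** 2
    # log-uniform sigma within [pool_sd/1000, pool_sd*1000]
    lo = math.log(pool_sd / 1000.0)
    hi = math.log(pool_sd * 1000.0)
    if theta[2] < lo or theta[2] > hi or theta[3] < lo or theta[3] > hi:
        return -np.inf
    # nu - 1 ~ Exponential(mean 29), with log-scale Jacobian
    lp += -(nu - 1.0) / 29.0 + theta[4]
    return lp


@njit(cache=True)
def _best_chain(x, y, paired, n_iter, burn, seed):
    np.random.seed(seed)
    nx = x.shape[0]
    mx = 0.0
    for i in range(nx):
        mx += x[i]
    mx /= nx
    allv = np.concatenate((x, y))
    pool_mean = np.mean(allv)
    pool_sd = np.std(allv) + 1e-12
    theta = np.array([np.mean(x), np.mean(y),
                      math.log(np.std(x) + 1e-6), math.log(np.std(y) + 1e-6),
                      math.log(29.0)])
    ll = _best_logpost(theta, x, y, pool_mean, pool_sd, paired)
    scale = np.full(5, 0.3)
    n_keep = n_iter - burn
    out = np.empty((n_keep, 5))
    kept = 0
    for it in range(n_iter):
        gamma = 1.0 / (1.0 + 0.1 * it) ** 0.6 if it < burn else 0.0
        for j in range(5):
            prop = theta.copy()
            prop[j] += scale[j] * np.random.normal()
            llp = _best_logpost(prop, x, y, pool_mean, pool_sd, paired)
            acc = llp > -np.inf and np.log(np.random.random()) < llp - ll
            if acc:
                theta = prop
                ll = llp
            if gamma > 0.0:
                scale[j] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.35))
                scale[j] = min(max(scale[j], 1e-4), 10.0)
        if it >= burn:
            for j in range(5):
                out[kept, j] = theta[j]
            kept += 1
    return out


def bayesian_ttest(x, y, paired: bool = False, n_iter: int = 6000,
                   burn: int = 2000, n_chains: int = 2, seed: int = 0,
                   mass: float = 0.95) -> dict:
    """Robust Bayesian estimate of the group (or paired) mean difference.

    Two-group mode models each group with its own t distribution; paired
    mode models the elementwise differences with a single t distribution.
    Returns the posterior of the difference with mean and HDI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        chains = [_best_chain(d, d, True, n_iter, burn,
                              (int(seed) + 733 * c + 1) % (2**31 - 1))
                  for c in range(n_chains)]
        draws = np.concatenate(chains, axis=0)
        diff = draws[:, 0]
    else:
        chains = [_best_chain(x, y, False, n_iter, burn,
                              (int(seed) + 733 * c + 1) % (2**31 - 1))
                  for c in range(n_chains)]
        draws = np.concatenate(chains, axis=0)
        diff = draws[:, 0] - draws[:, 1]
    lo, hi = compute_hdi(diff, mass)
    return {"draws": diff, "mean": float(diff.mean()), "hdi_lo": lo,
            "hdi_hi": hi, "paired": paired,
            "excludes_zero": not (lo <= 0.0 <= hi)}


# ---------------------------------------------------------------------------
# hierarchical mixed GLMs (choice and log-RT)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glm_data_loglik(eta, y, family, sige):
    total = 0.0
    n = y.shape[0]
    if family == 0:  # bernoulli-logit
        for i in range(n):
            x = eta[i]
            if x >= 0:
                lp1 = -math.log1p(math.exp(-x))
            else:
                lp1 = x - math.log1p(math.exp(x))
            total += lp1 if y[i] == 1.0 else lp1 - x
    else:  # gaussian
        c = -0.5 * math.log(2.0 * math.pi) - math.log(sige)
        inv2 = 0.5 / (sige * sige)
        for i in range(n):
            d = y[i] - eta[i]
            total += c - d * d * inv2
    return total


@njit(cache=True)
def _glm_chain(X, y, part_start, family, beta_sd, sigma_scale,
               n_iter, burn, thin, seed):
    np.random.seed(seed)
    n, p = X.shape
    n_part = part_start.shape[0] - 1
    beta = np.zeros(p)
    u = np.zeros((n_part, p))
    sigma = np.full(p, 0.5)
    sige = 1.0

    eta_fix = np.zeros(n)          # X @ beta
    eta_ran = np.zeros(n)          # row-wise X . u[part]
    ll_part = np.empty(n_part)
    for i in range(n_part):
        s, e = part_start[i], part_start[i + 1]
        ll_part[i] = _glm_data_loglik(eta_fix[s:e] + eta_ran[s:e], y[s:e],
                                      family, sige)

    scale_b = np.full(p, 0.2)
    scale_u = np.full(n_part, 0.4)
    scale_s = np.full(p, 0.3)
    n_keep = 0
    for it in range(burn, n_iter):
        if (it - burn) % thin == 0:
            n_keep += 1
    beta_draws = np.empty((n_keep, p))
    sigma_draws = np.empty((n_keep, p))
    sige_draws = np.empty(n_keep)
    kept = 0

    for it in range(n_iter):
        gamma = 1.0 / (1.0 + 0.05 * it) ** 0.6 if it < burn else 0.0
        # fixed effects, coordinate-wise
        for j in range(p):
            step = scale_b[j] * np.random.normal()
            eta_prop = eta_fix + step * X[:, j]
            tot_cur = 0.0
            for i in range(n_part):
                tot_cur += ll_part[i]
            llp = _glm_data_loglik(eta_prop + eta_ran, y, family, sige)
            dprior = -0.5 * (((beta[j] + step) ** 2 - beta[j] ** 2) / (beta_sd * beta_sd))
            acc = np.log(np.random.random()) < llp - tot_cur + dprior
            if acc:
                beta[j] += step
                eta_fix = eta_prop
                for i in range(n_part):
                    s, e = part_start[i], part_start[i + 1]
                    ll_part[i] = _glm_data_loglik(eta_fix[s:e] + eta_ran[s:e],
                                                  y[s:e], family, sige)
            if gamma > 0.0:
                scale_b[j] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.35))
                scale_b[j] = min(max(scale_b[j], 1e-4), 10.0)
        # random-effect vectors per participant
        for i in range(n_part):
            s, e = part_start[i], part_start[i + 1]
            prop = np.empty(p)
            for j in range(p):
                prop[j] = u[i, j] + scale_u[i] * sigma[j] * np.random.normal()
            eta_prop = np.empty(e - s)
            for t in range(s, e):
                acc_eta = eta_fix[t]
                for j in range(p):
                    acc_eta += X[t, j] * prop[j]
                eta_prop[t - s] = acc_eta
            llp = _glm_data_loglik(eta_prop, y[s:e], family, sige)
            dprior = 0.0
            for j in range(p):
                dprior += -0.5 * (prop[j] ** 2 - u[i, j] ** 2) / (sigma[j] * sigma[j])
            acc = np.log(np.random.random()) < llp - ll_part[i] + dprior
            if acc:
                u[i] = prop
                ll_part[i] = llp
                for t in range(s, e):
                    acc_eta = 0.0
                    for j in range(p):
                        acc_eta += X[t, j] * u[i, j]
                    eta_ran[t] = acc_eta
            if gamma > 0.0:
                scale_u[i] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.25))
                scale_u[i] = min(max(scale_u[i], 1e-4), 10.0)
        # random-effect SDs (half-normal prior), log-scale random walk
        for j in range(p):
            cur = sigma[j]
            prop_s = cur * math.exp(scale_s[j] * np.random.normal())
            ss = 0.0
            for i in range(n_part):
                ss += u[i, j] * u[i, j]
            lp_cur = (-n_part * math.log(cur) - 0.5 * ss / (cur * cur)
                      - 0.5 * (cur / sigma_scale) ** 2 + math.log(cur))
            lp_prop = (-n_part * math.log(prop_s) - 0.5 * ss / (prop_s * prop_s)
                       - 0.5 * (prop_s / sigma_scale) ** 2 + math.log(prop_s))
            acc = np.log(np.random.random()) < lp_prop - lp_cur
            if acc:
                sigma[j] = prop_s
            if gamma > 0.0:
                scale_s[j] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.35))
                scale_s[j] = min(max(scale_s[j], 1e-4), 10.0)
        # residual SD for the gaussian family
        if family == 1:
            cur = sige
            prop_s = cur * math.exp(0.1 * np.random.normal())
            ss = 0.0
            for i in range(n):
                d = y[i] - eta_fix[i] - eta_ran[i]
                ss += d * d
            lp_cur = -n * math.log(cur) - 0.5 * ss / (cur * cur) - 0.5 * cur * cur + math.log(cur)
            lp_prop = (-n * math.log(prop_s) - 0.5 * ss / (prop_s * prop_s)
                       - 0.5 * prop_s * prop_s + math.log(prop_s))
            if np.log(np.random.random()) < lp_prop - lp_cur:
                sige = prop_s
                for i in range(n_part):
                    s, e = part_start[i], part_start[i + 1]
                    ll_part[i] = _glm_data_loglik(eta_fix[s:e] + eta_ran[s:e],
                                                  y[s:e], family, sige)
        if it >= burn and (it - burn) % thin == 0:
            for j in range(p):
                beta_draws[kept, j] = beta[j]
                sigma_draws[kept, j] = sigma[j]
            sige_draws[kept] = sige
            kept += 1
    return beta_draws, sigma_draws, sige_draws


def _z(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("constant predictor")
    return (x - np.mean(x)) / sd


def _mglm_design(dataset: Dataset, include_trial_index: bool,
                 rt_model: bool) -> tuple[np.ndarray, list, np.ndarray, np.ndarray]:
    if dataset.design is None:
        raise ValueError("dataset must be standardized first")
    df = dataset.trials.reset_index(drop=True)
    des = dataset.design.reset_index(drop=True)
    drug = des["drug_code"].to_numpy(float)
    if dataset.study_design != WITHIN_SUBJECT:
        drug = _z(df["drug"].to_numpy(float))  # dose as standardized covariate
    md = des["magnitude_diff"].to_numpy(float)
    dd = des["delay_diff"].to_numpy(float)
    cols = [("Intercept", np.ones(len(df))), ("Drug", drug),
            ("Delay_diff", dd), ("Magnitude_diff", md),
            ("Drug x Delay_diff", drug * dd),
            ("Drug x Magnitude_diff", drug * md),
            ("Delay_diff x Magnitude_diff", dd * md),
            ("Drug x Delay_diff x Magnitude_diff", drug * dd * md)]
    if rt_model:
        cols.append(("Choice", df["choice"].to_numpy(float)))
        cols.append(("Magnitude_sum", des["magnitude_sum"].to_numpy(float)))
    if include_trial_index:
        ti = _z(df["trial_index"].to_numpy(float))
        cols.append(("Trial", ti))
        cols.append(("Drug x Trial", drug * ti))
    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])

    order = df["participant_id"].astype(str).to_numpy()
    participants = sorted(pd.unique(order))
    idx = np.concatenate([np.nonzero(order == p)[0] for p in participants])
    counts = [int((order == p).sum()) for p in participants]
    part_start = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return X[idx], names, part_start, idx


def _run_mglm(X, y, part_start, family, n_iter, burn, thin, n_chains, seed):
    chains = []
    for c in range(n_chains):
        b, s, se = _glm_chain(np.ascontiguousarray(X), np.ascontiguousarray(y),
                              part_start, family, 5.0, 1.0, n_iter, burn, thin,
                              (int(seed) + 977 * c + 1) % (2**31 - 1))
        chains.append((b, s, se))
    beta = np.stack([c[0] for c in chains])
    sigma = np.stack([c[1] for c in chains])
    return beta, sigma


def _coef_table(names, beta, mass=0.95) -> pd.DataFrame:
    rows = []
    for j, name in enumerate(names):
        d = beta[:, :, j].reshape(-1)
        lo, hi = compute_hdi(d, mass)
        rows.append({"predictor": name, "mean": float(d.mean()),
                     "sd": float(d.std(ddof=1)), "hdi_lo": lo, "hdi_hi": hi})
    return pd.DataFrame(rows)


def fit_choice_mglm(dataset: Dataset, include_trial_index: bool = False,
                    n_iter: int = 6000, burn: int = 3000, thin: int = 3,
                    n_chains: int = 2, seed: int = 0) -> dict:
    """Hierarchical logistic regression of LL-vs-SS choice on Drug,
    Magnitude_diff, Delay_diff and their interactions, with random intercepts
    and random slopes per participant."""
    X, names, part_start, idx = _mglm_design(dataset, include_trial_index, False)
    y = dataset.trials["choice"].to_numpy(float)[idx]
    beta, sigma = _run_mglm(X, y, part_start, 0, n_iter, burn, thin, n_chains, seed)
    return {"table": _coef_table(names, beta), "predictors": names,
            "beta_draws": beta, "sigma_draws": sigma}


def fit_rt_mglm(dataset: Dataset, include_trial_index: bool = False,
                n_iter: int = 6000, burn: int = 3000, thin: int = 3,
                n_chains: int = 2, seed: int = 0) -> dict:
    """Hierarchical linear regression of log response time with the same
    structure as the choice model plus Choice and Magnitude_sum predictors."""
    X, names, part_start, idx = _mglm_design(dataset, include_trial_index, True)
    rt = dataset.trials["rt"].to_numpy(float)[idx]
    if np.any(rt <= 0):
        raise ValueError("response times must be positive")
    y = np.log(rt)
    beta, sigma = _run_mglm(X, y, part_start, 1, n_iter, burn, thin, n_chains, seed)
    return {"table": _coef_table(names, beta), "predictors": names,
            "beta_draws": beta, "sigma_draws": sigma}
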