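"""Synthetic task designs and behavioral datasets.

Two study templates are emulated:

* ``D2``: within-subject pharmacological crossover; 56 participants x 2
  sessions (placebo / active) x 20 trials; SS magnitude 5-250 francs at
  delay 0-30 days, LL magnitude 15-300 at delay 3-90, sampled uniformly
  within range subject to LL magnitude > SS magnitude and LL delay > SS
  delay (the original adaptive stimulus selection is out of scope; a
  caller-supplied design table can replay real stimuli).
* ``D1``: between-subject dose groups (0/6/15/30 mg), 120 participants,
  54 trials: the full factorial of SS magnitude {0, 2, ..., 16} (delay 0)
  by LL delay level, LL fixed at 16 francs.

Behavioral data are generated from the hierarchical DDM: individual-level
coefficients are drawn around group-level means with per-effect standard
deviation lambda, mapped to trial-level Wiener parameters by the chosen
variant, and (choice, rt) simulated with the diffusion engine.  The default
group-level values reproduce the within-subject study's posterior-mean
estimates (drift weights ~2.4 / -1.1, v_max 0.8, threshold ~4, bias ~0.57,
non-decision time ~1.5 s), which puts response times on the realistic
1-6 s scale so trimming and posterior predictive checks operate as they
would on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BETWEEN_SUBJECT, Dataset, WITHIN_SUBJECT, make_dataset, standardize_attributes
from .variants import CoefficientSet, N_SLOTS, SLOT_NAMES, VariantSpec, get_variant, trial_params_kernel
from .wiener import _simulate_trials_piecewise, simulate_trials_varying

D1_DELAY_LEVELS = (0, 14, 30, 60, 90, 180)


@dataclass(frozen=True)
class TaskTemplate:
    study: str                       # "D2" or "D1"
    n_participants: int
    n_sessions: int
    trials_per_session: int
    study_design: str
    ss_magnitude_range: tuple = (5, 250)
    ss_delay_range: tuple = (0, 30)
    ll_magnitude_range: tuple = (15, 300)
    ll_delay_range: tuple = (3, 90)
    dose_levels: tuple = (0.0, 1.0)  # D2: placebo / active


def d2_template(n_participants: int = 56, trials_per_session: int = 20) -> TaskTemplate:
    return TaskTemplate(study="D2", n_participants=n_participants, n_sessions=2,
                        trials_per_session=trials_per_session,
                        study_design=WITHIN_SUBJECT)


def d1_template(n_participants: int = 120) -> TaskTemplate:
    return TaskTemplate(study="D1", n_participants=n_participants, n_sessions=1,
                        trials_per_session=54, study_design=BETWEEN_SUBJECT,
                        ss_magnitude_range=(0, 16), ss_delay_range=(0, 0),
                        ll_magnitude_range=(16, 16), ll_delay_range=(0, 180),
                        dose_levels=(0.0, 6.0, 15.0, 30.0))


#: group-level posterior-mean coefficients of the within-subject study
#: (used as default ground truth for simulation and recovery)
D2_GROUP_MEANS = CoefficientSet(
    drift_magnitude_diff=2.41, drift_drug_magnitude_diff=0.81,
    drift_delay_diff=-1.13, drift_drug_delay_diff=-0.30,
    v_max=0.80, drug_v_max=0.0,
    bias_intercept=0.57, bias_drug=-0.04,
    bias_delay=-0.02, bias_drug_delay=0.02,
    threshold_intercept=3.96, threshold_drug=0.17,
    ndt_intercept=1.48, ndt_drug=-0.10,
)

#: default individual-level standard deviations (lambda) per effect; chosen
#: once on the scale of each coefficient (see docs/methods.md)
D2_LAMBDA = {
    "drift_magnitude_diff": 0.5, "drift_drug_magnitude_diff": 0.3,
    "drift_delay_diff": 0.5, "drift_drug_delay_diff": 0.3,
    "v_max": 0.2, "drug_v_max": 0.1,
    "bias_intercept": 0.05, "bias_drug": 0.02,
    "bias_delay": 0.01, "bias_drug_delay": 0.01,
    "threshold_intercept": 0.5, "threshold_drug": 0.2,
    "ndt_intercept": 0.2, "ndt_drug": 0.1,
    "k_disc": 0.02, "k_disc_drug": 0.01,
    "tau_diff": 0.05,
}


def lambda_vector(lam: dict | np.ndarray | None) -> np.ndarray:
    if lam is None:
        lam = D2_LAMBDA
    if isinstance(lam, dict):
        return np.array([float(lam.get(n, 0.0)) for n in SLOT_NAMES])
    vec = np.asarray(lam, dtype=float)
    if vec.shape != (N_SLOTS,):
        raise ValueError(f"lambda vector must have length {N_SLOTS}")
    return vec


@dataclass
class SyntheticDataset:
    """Generated trials plus the ground truth that produced them."""

    dataset: Dataset
    group_means: dict                # condition label -> CoefficientSet
    lam: np.ndarray                  # per-slot individual SD
    individual: pd.DataFrame         # one coefficient row per participant
    variant: VariantSpec
    seed: int
    meta: dict = field(default_factory=dict)


def generate_design(template: TaskTemplate, seed: int) -> pd.DataFrame:
    """Task design only (no choices/RTs): one row per planned trial."""
    rng = np.random.default_rng(int(seed))
    rows = []
    for p in range(template.n_participants):
        pid = f"p{p + 1:03d}"
        if template.study_design == WITHIN_SUBJECT:
            order = rng.permutation(len(template.dose_levels))
            session_drug = [template.dose_levels[k] for k in order]
        else:
            dose = template.dose_levels[p % len(template.dose_levels)]
            session_drug = [dose]
        for s_idx in range(template.n_sessions):
            drug = session_drug[s_idx % len(session_drug)]
            sid = f"s{s_idx + 1}"
            if template.study == "D1":
                cells = [(ssm, lld)
                         for ssm in range(template.ss_magnitude_range[0],
                                          template.ss_magnitude_range[1] + 1, 2)
                         for lld in D1_DELAY_LEVELS]
                rng.shuffle(cells)
                for t_idx, (ssm, lld) in enumerate(cells):
                    rows.append((pid, sid, drug, float(ssm), 0.0,
                                 float(template.ll_magnitude_range[1]),
                                 float(lld), t_idx + 1))
            else:
                for t_idx in range(template.trials_per_session):
                    ssm = int(rng.integers(template.ss_magnitude_range[0],
                                           template.ss_magnitude_range[1] + 1))
                    ssd = int(rng.integers(template.ss_delay_range[0],
                                           template.ss_delay_range[1] + 1))
                    llm = int(rng.integers(max(template.ll_magnitude_range[0], ssm + 1),
                                           template.ll_magnitude_range[1] + 1))
                    lld = int(rng.integers(max(template.ll_delay_range[0], ssd + 1),
                                           template.ll_delay_range[1] + 1))
                    rows.append((pid, sid, drug, float(ssm), float(ssd),
                                 float(llm), float(lld), t_idx + 1))
    return pd.DataFrame(rows, columns=[
        "participant_id", "session_id", "drug", "ss_magnitude", "ss_delay",
        "ll_magnitude", "ll_delay", "trial_index"])


def _standardized_columns(design_df: pd.DataFrame) -> dict:
    out = {}
    for name, x in [
        ("magnitude_diff", design_df["ll_magnitude"] - design_df["ss_magnitude"]),
        ("delay_diff", design_df["ll_delay"] - design_df["ss_delay"]),
        ("delay_sum", design_df["ll_delay"] + design_df["ss_delay"]),
    ]:
        x = x.to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        out[name] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    return out


def generate_dataset(template: TaskTemplate,
                     group_means: CoefficientSet | dict | None = None,
                     lam: dict | np.ndarray | None = None,
                     variant: VariantSpec | str = "ddm1",
                     seed: int = 0, dt: float = 1e-3,
                     design_df: pd.DataFrame | None = None) -> SyntheticDataset:
    """Generate a full behavioral dataset from hierarchical DDM ground truth.

    ``group_means`` is a single :class:`CoefficientSet` for the
    within-subject design, or a mapping dose -> CoefficientSet for the
    between-subject design (default: the within-subject study estimates,
    replicated per dose for D1).  ``lam`` maps effect names to individual
    SDs (lambda = 0 collapses the hierarchy).
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    if design_df is None:
        design_df = generate_design(template, seed)
    lam_vec = lambda_vector(lam)
    if group_means is None:
        group_means = D2_GROUP_MEANS
    if isinstance(group_means, CoefficientSet):
        means_by_dose = {d: group_means for d in template.dose_levels}
    else:
        means_by_dose = {float(k): v for k, v in group_means.items()}

    rng = np.random.default_rng(int(seed) + 1)
    std = _standardized_columns(design_df)
    active = np.asarray(variant.active_slots(template.study_design), dtype=np.int64)

    participants = list(dict.fromkeys(design_df["participant_id"]))
    ind_rows = {}
    n_rows = len(design_df)
    v_arr = np.empty(n_rows)
    a_arr = np.empty(n_rows)
    z_arr = np.empty(n_rows)
    tau_arr = np.empty(n_rows)
    time_varying = variant.drift_mode == "time_varying"
    v_early = np.empty(n_rows)
    t_switch = np.zeros(n_rows)

    pos = design_df.reset_index(drop=True)
    for pid in participants:
        mask = (pos["participant_id"] == pid).to_numpy()
        idx = np.nonzero(mask)[0]
        if template.study_design == BETWEEN_SUBJECT:
            dose = float(pos["drug"].iloc[idx[0]])
            mu_vec = means_by_dose[dose].to_vector()
            drugc = np.zeros(idx.size)
        else:
            mu_vec = means_by_dose[template.dose_levels[0]].to_vector()
            drugc = (pos["drug"].iloc[idx].to_numpy(dtype=float) != 0).astype(float)
        ok_all = False
        for _ in range(500):  # redraw until the vector is admissible on every trial
            coeffs = mu_vec.copy()
            coeffs[active] = coeffs[active] + lam_vec[active] * rng.standard_normal(active.size)
            ok_all = True
            for k, i in enumerate(idx):
                v, a, z, tau, ok = trial_params_kernel(
                    coeffs, std["magnitude_diff"][i], std["delay_diff"][i],
                    std["delay_sum"][i], drugc[k],
                    float(pos["ss_magnitude"].iloc[i]), float(pos["ss_delay"].iloc[i]),
                    float(pos["ll_magnitude"].iloc[i]), float(pos["ll_delay"].iloc[i]),
                    1.0, variant.code, variant.sigmoid_link)
                if not ok:
                    ok_all = False
                    break
                v_arr[i], a_arr[i], z_arr[i], tau_arr[i] = v, a, z, tau
                if time_varying:
                    # generative rsDDM: early attribute drives the drift until
                    # the other attribute comes online |tau_diff| later
                    m = (coeffs[0] + coeffs[1] * drugc[k]) * std["magnitude_diff"][i]
                    dd = (coeffs[2] + coeffs[3] * drugc[k]) * std["delay_diff"][i]
                    td = coeffs[16]
                    vmax = coeffs[4] + coeffs[5] * drugc[k]
                    early = dd if td > 0 else (m if td < 0 else m + dd)
                    if variant.sigmoid_link:
                        v_early[i] = vmax * np.tanh(early / 2.0)
                        v_arr[i] = vmax * np.tanh((m + dd) / 2.0)
                    else:
                        v_early[i] = early
                        v_arr[i] = m + dd
                    t_switch[i] = abs(td)
            if ok_all:
                break
        if not ok_all:
            raise RuntimeError(f"could not draw admissible coefficients for {pid}")
        ind_rows[pid] = coeffs

    sim_seed = int(rng.integers(0, 2**31 - 1))
    if time_varying:
        choices, rts = _simulate_trials_piecewise(
            v_early, v_arr, t_switch, a_arr, z_arr, tau_arr, sim_seed, dt)
    else:
        choices, rts = simulate_trials_varying(v_arr, a_arr, z_arr, tau_arr, sim_seed, dt)
    trials = pos.copy()
    trials["choice"] = choices
    trials["rt"] = rts
    dataset = make_dataset(trials, study_design=template.study_design)
    individual = pd.DataFrame.from_dict(ind_rows, orient="index", columns=list(SLOT_NAMES))
    labels = {d: means_by_dose[d] for d in means_by_dose}
    return SyntheticDataset(dataset=dataset, group_means=labels, lam=lam_vec,
                            individual=individual, variant=variant,
                            seed=int(seed),
                            meta={"template": template.study, "dt": dt})


def generate_discounting_dataset(template: TaskTemplate, k: float,
                                 beta_temp: float, seed: int) -> pd.DataFrame:
    """Bernoulli choices from softmax over hyperbolically discounted values;
    no response times (generator for the behavioral model fits)."""
    if k < 0 or beta_temp < 0:
        raise ValueError("k and beta_temp must be non-negative")
    design_df = generate_design(template, seed)
    rng = np.random.default_rng(int(seed) + 1)
    sv_ll = design_df["ll_magnitude"] / (1.0 + k * design_df["ll_delay"])
    sv_ss = design_df["ss_magnitude"] / (1.0 + k * design_df["ss_delay"])
    p_ll = 1.0 / (1.0 + np.exp(-beta_temp * (sv_ll - sv_ss)))
    design_df = design_df.copy()
    design_df["choice"] = (rng.random(len(design_df)) < p_ll).astype(int)
    return design_df
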