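"""Six drift-diffusion model variants for intertemporal choice.

Each variant maps a trial's (standardized) attribute regressors, drug
condition and a coefficient set onto trial-level Wiener parameters:

* drift: either an attribute-difference linear predictor passed through a
  sigmoidal (tanh) link bounded by ±v_max (DDM-1/2/4), a condition-wise
  constant (DDM-3), the difference of hyperbolically discounted subjective
  values (DDM-5), or a time-varying attribute predictor with asynchronous
  attribute onsets (DDM-6, the relative-starting-time DDM);
* starting bias: linear in the drug condition and the delay difference
  (delay sum for DDM-4), or fixed at 0.5 (DDM-2);
* boundary separation and non-decision time: intercept plus drug shift.

Coefficients live in a fixed 17-slot vector so one compiled likelihood kernel
serves every variant; the slot layout is in :data:`SLOT_NAMES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from numba import njit

from .wiener import WienerParams, wiener_logpdf

#: admissible range for the trial-level relative bias during estimation
BIAS_LO, BIAS_HI = 0.02, 0.98

SLOT_NAMES = (
    "drift_magnitude_diff",        # 0  beta1
    "drift_drug_magnitude_diff",   # 1  beta2
    "drift_delay_diff",            # 2  beta3
    "drift_drug_delay_diff",       # 3  beta4
    "v_max",                       # 4  beta5
    "drug_v_max",                  # 5  beta6
    "bias_intercept",              # 6  beta7
    "bias_drug",                   # 7  beta8
    "bias_delay",                  # 8  beta9  (delay_diff; delay_sum in DDM-4)
    "bias_drug_delay",             # 9  beta10
    "threshold_intercept",         # 10 beta11
    "threshold_drug",              # 11 beta12
    "ndt_intercept",               # 12 beta13
    "ndt_drug",                    # 13 beta14
    "k_disc",                      # 14 hyperbolic discount weight (DDM-5)
    "k_disc_drug",                 # 15 its drug shift (DDM-5)
    "tau_diff",                    # 16 attribute-onset asynchrony, s (DDM-6)
)
N_SLOTS = len(SLOT_NAMES)

#: drug-interaction slots (within-subject coding only)
DRUG_SLOTS = (1, 3, 5, 7, 9, 11, 13, 15)


class ParameterError(ValueError):
    """A coefficient draw maps some trial outside the admissible parameter
    region (rejection signal for the sampler)."""


@dataclass(frozen=True)
class DesignRow:
    """Standardized regressors for one trial."""

    magnitude_diff: float
    delay_diff: float
    magnitude_sum: float = 0.0
    delay_sum: float = 0.0
    drug_code: float = 0.0


@dataclass
class CoefficientSet:
    """Named view over the 17-slot coefficient vector (all default 0)."""

    drift_magnitude_diff: float = 0.0
    drift_drug_magnitude_diff: float = 0.0
    drift_delay_diff: float = 0.0
    drift_drug_delay_diff: float = 0.0
    v_max: float = 0.0
    drug_v_max: float = 0.0
    bias_intercept: float = 0.0
    bias_drug: float = 0.0
    bias_delay: float = 0.0
    bias_drug_delay: float = 0.0
    threshold_intercept: float = 0.0
    threshold_drug: float = 0.0
    ndt_intercept: float = 0.0
    ndt_drug: float = 0.0
    k_disc: float = 0.0
    k_disc_drug: float = 0.0
    tau_diff: float = 0.0

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SLOT_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "CoefficientSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_SLOTS,):
            raise ValueError(f"expected a length-{N_SLOTS} vector")
        return cls(**{n: float(vec[i]) for i, n in enumerate(SLOT_NAMES)})


@dataclass(frozen=True)
class VariantSpec:
    """Which regressors enter which diffusion parameter for one variant."""

    variant_id: str
    drift_mode: str                 # attribute_difference | constant | discounted_value | time_varying
    drift_magnitude: bool
    drift_delay: bool
    bias_free: bool                 # False -> z fixed at 0.5 (DDM-2)
    bias_delay_diff: bool
    bias_delay_sum: bool
    ndt_tau_diff: bool
    sigmoid_link: bool = True       # False = linear-link ablation

    @property
    def code(self) -> int:
        return int(self.variant_id[-1])

    def active_slots(self, study_design: str = "within_subject") -> list[int]:
        """Slot indices with free coefficients under this variant.

        In the between-subject design the drug condition is carried by
        separate group-level means, so the drug-interaction slots are not
        free coefficients.
        """
        slots: list[int] = []
        if self.drift_mode == "discounted_value":
            slots += [14, 15]
        elif self.drift_mode in ("attribute_difference", "time_varying"):
            if self.drift_magnitude:
                slots += [0, 1]
            if self.drift_delay:
                slots += [2, 3]
        slots += [4, 5]             # v_max / constant drift, always present
        if self.bias_free:
            slots += [6, 7]
            if self.bias_delay_diff or self.bias_delay_sum:
                slots += [8, 9]
        slots += [10, 11, 12, 13]
        if self.ndt_tau_diff:
            slots += [16]
        if study_design == "between_subject":
            slots = [s for s in slots if s not in DRUG_SLOTS]
        return sorted(slots)


VARIANTS: dict[str, VariantSpec] = {
    "ddm1": VariantSpec("ddm1", "attribute_difference", True, True, True, True, False, False),
    "ddm2": VariantSpec("ddm2", "attribute_difference", True, True, False, False, False, False),
    "ddm3": VariantSpec("ddm3", "constant", False, False, True, True, False, False),
    "ddm4": VariantSpec("ddm4", "attribute_difference", True, True, True, False, True, False),
    "ddm5": VariantSpec("ddm5", "discounted_value", False, True, True, True, False, False),
    "ddm6": VariantSpec("ddm6", "time_varying", True, True, True, False, False, True),
}


def get_variant(name: str, sigmoid_link: bool = True) -> VariantSpec:
    spec = VARIANTS[name.lower()]
    if not sigmoid_link:
        spec = VariantSpec(**{**{f.name: getattr(spec, f.name) for f in fields(spec)},
                              "sigmoid_link": False})
    return spec


# ---------------------------------------------------------------------------
# scalar mapping operations (reference/readable path)
# ---------------------------------------------------------------------------

def drift_linear(row: DesignRow, coeffs: CoefficientSet) -> float:
    """Attribute-difference drift predictor (before the sigmoidal link)."""
    d = row.drug_code
    return (coeffs.drift_magnitude_diff * row.magnitude_diff
            + coeffs.drift_drug_magnitude_diff * d * row.magnitude_diff
            + coeffs.drift_delay_diff * row.delay_diff
            + coeffs.drift_drug_delay_diff * d * row.delay_diff)


def sigmoid_link(v_prime: float, coeffs: CoefficientSet, drug: float) -> float:
    """Bounded drift ``v = V (2 / (1 + exp(-v')) - 1) = V tanh(v'/2)`` with
    condition-wise saturation ``V = v_max + drug_v_max * drug``."""
    vmax = coeffs.v_max + coeffs.drug_v_max * drug
    if vmax <= 0:
        raise ParameterError(f"effective v_max must be > 0, got {vmax}")
    return vmax * math.tanh(v_prime / 2.0)


def bias_regression(row: DesignRow, coeffs: CoefficientSet, drug: float,
                    variant: VariantSpec) -> float:
    """Linear starting-bias predictor on the identity scale; 0.5 fixed when
    the variant has no free bias (DDM-2)."""
    if not variant.bias_free:
        return 0.5
    z = coeffs.bias_intercept + coeffs.bias_drug * drug
    if variant.bias_delay_diff or variant.bias_delay_sum:
        x = row.delay_sum if variant.bias_delay_sum else row.delay_diff
        z += coeffs.bias_delay * x + coeffs.bias_drug_delay * drug * x
    return z


def threshold_and_ndt(coeffs: CoefficientSet, drug: float) -> tuple[float, float]:
    """Boundary separation and non-decision time, intercept + drug shift."""
    a = coeffs.threshold_intercept + coeffs.threshold_drug * drug
    tau = coeffs.ndt_intercept + coeffs.ndt_drug * drug
    return a, tau


def drift_discounted_value(trial, coeffs: CoefficientSet, drug: float) -> float:
    """Hyperbolic-value drift predictor: difference of discounted subjective
    values, ``LL/(1 + kd*LL_delay) - SS/(1 + kd*SS_delay)`` (DDM-5)."""
    kd = coeffs.k_disc + coeffs.k_disc_drug * drug
    if kd < 0:
        raise ParameterError(f"effective discount weight must be >= 0, got {kd}")
    return (trial.ll_magnitude / (1.0 + kd * trial.ll_delay)
            - trial.ss_magnitude / (1.0 + kd * trial.ss_delay))


def drift_time_varying(row: DesignRow, coeffs: CoefficientSet, drug: float,
                       rt: float, tau: float) -> float:
    """Effective (duration-weighted) drift predictor when one attribute's
    accumulation starts ``|tau_diff|`` seconds before the other's (DDM-6).

    Positive ``tau_diff``: delays are processed first.  If the decision ends
    before the late attribute comes online, only the early attribute drives
    the drift; otherwise the early-only drift over the first ``|tau_diff|``
    seconds and the joint drift over the remainder are averaged, weighted by
    duration.
    """
    t = rt - tau
    if t <= 0:
        raise ValueError("rt must exceed the non-decision time")
    d = row.drug_code if drug is None else drug
    m = (coeffs.drift_magnitude_diff + coeffs.drift_drug_magnitude_diff * d) * row.magnitude_diff
    dd = (coeffs.drift_delay_diff + coeffs.drift_drug_delay_diff * d) * row.delay_diff
    td = coeffs.tau_diff
    if td == 0.0:
        return m + dd
    early = dd if td > 0 else m
    lag = abs(td)
    if lag >= t:
        return early
    return (lag * early + (t - lag) * (m + dd)) / t


def map_trial(trial, row: DesignRow, coeffs: CoefficientSet,
              variant: VariantSpec) -> WienerParams:
    """Compose the variant's regressions into trial-level Wiener parameters.

    Raises :class:`ParameterError` when a derived parameter leaves the
    admissible region (the sampler treats this as rejection).
    """
    drug = row.drug_code
    a, tau = threshold_and_ndt(coeffs, drug)
    if a <= 0:
        raise ParameterError(f"boundary separation must be > 0, got {a}")
    if tau < 0:
        raise ParameterError(f"non-decision time must be >= 0, got {tau}")
    z = bias_regression(row, coeffs, drug, variant)
    if variant.bias_free and not (BIAS_LO < z < BIAS_HI):
        raise ParameterError(f"starting bias {z:.3f} outside ({BIAS_LO}, {BIAS_HI})")

    if variant.drift_mode == "constant":
        # DDM-3: the saturation parameter itself is the condition-wise drift
        v = coeffs.v_max + coeffs.drug_v_max * drug
    else:
        if variant.drift_mode == "discounted_value":
            v_prime = drift_discounted_value(trial, coeffs, drug)
        elif variant.drift_mode == "time_varying":
            v_prime = drift_time_varying(row, coeffs, drug, trial.rt, tau)
        else:
            v_prime = drift_linear(row, coeffs)
        v = sigmoid_link(v_prime, coeffs, drug) if variant.sigmoid_link else v_prime
    return WienerParams(v=v, a=a, z=z, tau=tau)


# ---------------------------------------------------------------------------
# compiled kernels (hot path for the sampler and simulators)
# ---------------------------------------------------------------------------

@njit(cache=True)
def trial_params_kernel(c, mdiff, ddiff, dsum, drug, ssm, ssd, llm, lld, rt,
                        variant, sigmoid):
    """Map one trial.  Returns (v, a, z, tau, ok); ok=False signals a
    parameter-region rejection."""
    a = c[10] + c[11] * drug
    tau = c[12] + c[13] * drug
    if a <= 0.0 or tau < 0.0:
        return 0.0, 1.0, 0.5, 0.0, False
    if variant == 2:
        z = 0.5
    else:
        x = dsum if variant == 4 else ddiff
        z = c[6] + c[7] * drug
        if variant != 6:
            z += c[8] * x + c[9] * drug * x
        if z <= BIAS_LO or z >= BIAS_HI:
            return 0.0, 1.0, 0.5, 0.0, False
    if variant == 3:
        v = c[4] + c[5] * drug
        return v, a, z, tau, True
    vmax = c[4] + c[5] * drug
    if sigmoid and vmax <= 0.0:
        return 0.0, 1.0, 0.5, 0.0, False
    if variant == 5:
        kd = c[14] + c[15] * drug
        if kd < 0.0:
            return 0.0, 1.0, 0.5, 0.0, False
        vp = llm / (1.0 + kd * lld) - ssm / (1.0 + kd * ssd)
    elif variant == 6:
        t = rt - tau
        if t <= 0.0:
            # outside the support; density is 0 there regardless of drift
            return 0.0, a, z, tau, True
        m = (c[0] + c[1] * drug) * mdiff
        dd = (c[2] + c[3] * drug) * ddiff
        td = c[16]
        if td == 0.0:
            vp = m + dd
        else:
            early = dd if td > 0.0 else m
            lag = abs(td)
            vp = early if lag >= t else (lag * early + (t - lag) * (m + dd)) / t
    else:
        vp = (c[0] + c[1] * drug) * mdiff + (c[2] + c[3] * drug) * ddiff
    v = vmax * math.tanh(vp / 2.0) if sigmoid else vp
    return v, a, z, tau, True


@njit(cache=True)
def participant_loglik(c, mdiff, ddiff, dsum, drug, ssm, ssd, llm, lld,
                       rt, choice, variant, sigmoid):
    """Summed Wiener log-likelihood of one participant's trials under
    coefficient vector ``c``; -inf on any rejection or support violation."""
    total = 0.0
    for i in range(rt.shape[0]):
        v, a, z, tau, ok = trial_params_kernel(
            c, mdiff[i], ddiff[i], dsum[i], drug[i], ssm[i], ssd[i],
            llm[i], lld[i], rt[i], variant, sigmoid)
        if not ok:
            return -np.inf
        lp = wiener_logpdf(rt[i], choice[i], v, a, z, tau)
        if lp == -np.inf:
            return -np.inf
        total += lp
    return total
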