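"""Trial data model, tabular I/O and preprocessing for intertemporal-choice
response-time datasets.

One row per decision between a smaller-sooner (SS) and a larger-later (LL)
monetary option: participant, session, drug condition, the four option
attributes, the binary choice (1 = LL) and the response time in seconds.

Preprocessing follows the standard pipeline for hierarchical drift-diffusion
analysis of such tasks: pooled trimming of the fastest/slowest response-time
tails, then z-scoring of the attribute difference/sum regressors over all
retained trials of the study so coefficient magnitudes are comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("itcddm")

#: canonical column order for trial tables
TRIAL_COLUMNS = [
    "participant_id", "session_id", "drug", "ss_magnitude", "ss_delay",
    "ll_magnitude", "ll_delay", "choice", "rt", "trial_index",
]

WITHIN_SUBJECT = "within_subject"
BETWEEN_SUBJECT = "between_subject"


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class ValidationError(ValueError):
    """One or more rows violate the trial invariants."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


@dataclass(frozen=True)
class ChoiceTrial:
    """A single intertemporal decision."""

    participant_id: str
    session_id: str
    drug: float            # 0 = placebo, 1 = active (D2) or dose in mg (D1)
    ss_magnitude: float    # currency units
    ss_delay: float        # days
    ll_magnitude: float
    ll_delay: float
    choice: int            # 1 = LL, 0 = SS
    rt: float              # seconds, > 0
    trial_index: int = 1


@dataclass
class Dataset:
    """Trial table plus (optionally) the standardized design matrix.

    ``trials`` holds the raw attributes; ``design`` (after
    :func:`standardize_attributes`) holds z-scored ``magnitude_diff``,
    ``delay_diff``, ``magnitude_sum``, ``delay_sum`` and a numeric
    ``drug_code`` column, one row per trial.
    """

    trials: pd.DataFrame
    study_design: str = WITHIN_SUBJECT
    design: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    def iter_trials(self):
        for row in self.trials.itertuples(index=False):
            yield ChoiceTrial(
                participant_id=str(row.participant_id),
                session_id=str(row.session_id),
                drug=float(row.drug),
                ss_magnitude=float(row.ss_magnitude),
                ss_delay=float(row.ss_delay),
                ll_magnitude=float(row.ll_magnitude),
                ll_delay=float(row.ll_delay),
                choice=int(row.choice),
                rt=float(row.rt),
                trial_index=int(row.trial_index),
            )


def _validate_trials(df: pd.DataFrame) -> list[str]:
    """Row-level invariant checks; returns human-readable diagnostics
    (1-based row numbers in file order)."""
    problems = []
    rt = df["rt"].to_numpy(dtype=float)
    ch = df["choice"].to_numpy()
    for i in np.nonzero(~(rt > 0))[0]:
        problems.append(f"row {i + 1}: non-positive rt {rt[i]!r}")
    for i in np.nonzero(~np.isin(ch, [0, 1]))[0]:
        problems.append(f"row {i + 1}: choice must be 0 or 1, got {ch[i]!r}")
    lld = df["ll_delay"].to_numpy(dtype=float)
    ssd = df["ss_delay"].to_numpy(dtype=float)
    llm = df["ll_magnitude"].to_numpy(dtype=float)
    ssm = df["ss_magnitude"].to_numpy(dtype=float)
    for i in np.nonzero(lld < ssd)[0]:
        problems.append(f"row {i + 1}: ll_delay {lld[i]} < ss_delay {ssd[i]}")
    for i in np.nonzero(llm < ssm)[0]:
        problems.append(f"row {i + 1}: ll_magnitude {llm[i]} < ss_magnitude {ssm[i]}")
    return problems


def _infer_study_design(df: pd.DataFrame) -> str:
    n_conditions = df.groupby("participant_id")["drug"].nunique()
    return WITHIN_SUBJECT if (n_conditions >= 2).all() else BETWEEN_SUBJECT


def make_dataset(df: pd.DataFrame, study_design: str | None = None) -> Dataset:
    """Validate a trial table and wrap it in a :class:`Dataset`."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "trial_index"]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.copy()
    if "trial_index" not in df.columns:
        df["trial_index"] = df.groupby(["participant_id", "session_id"]).cumcount() + 1
    problems = _validate_trials(df)
    if problems:
        raise ValidationError(
            "invalid trials:\n" + "\n".join(problems), rows=problems)
    df = df[TRIAL_COLUMNS].reset_index(drop=True)
    design = study_design or _infer_study_design(df)
    return Dataset(trials=df, study_design=design)


def read_trials(path, schema: dict | None = None,
                study_design: str | None = None) -> Dataset:
    """Read a delimited trial file into a validated :class:`Dataset`.

    Parameters
    ----------
    schema : optional mapping from canonical column names to the names used in
        the file, e.g. ``{"rt": "reaction_time_s"}``.
    """
    df = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    return make_dataset(df, study_design=study_design)


def write_trials(dataset: Dataset, path) -> None:
    """Write the trial table as CSV (canonical columns, header row)."""
    dataset.trials.to_csv(path, index=False)


def trim_rts(dataset: Dataset, lower_frac: float = 0.025,
             upper_frac: float = 0.025, scope: str = "pooled") -> Dataset:
    """Remove response-time outliers: trials strictly below the ``lower_frac``
    quantile or strictly above the ``1 - upper_frac`` quantile of the RT
    distribution.

    ``scope`` is ``"pooled"`` (quantiles over the whole study, the default) or
    ``"participant"`` (within each participant).  Quantiles use the
    linear-interpolation sample definition; ties with the thresholds are
    retained.  Removal counts are logged and stored in ``meta``.
    """
    if not (0 <= lower_frac and 0 <= upper_frac and lower_frac + upper_frac < 1):
        raise ValueError("need 0 <= lower_frac + upper_frac < 1")
    if len(dataset) == 0:
        raise ValueError("cannot trim an empty dataset")
    df = dataset.trials.reset_index(drop=True)

    low_mask = np.zeros(len(df), dtype=bool)
    high_mask = np.zeros(len(df), dtype=bool)
    rt_all = df["rt"].to_numpy(dtype=float)
    if scope == "pooled":
        groups = [np.arange(len(df))]
    elif scope == "participant":
        groups = [idx.to_numpy() for _, idx in
                  df.groupby("participant_id").groups.items()]
    else:
        raise ValueError(f"unknown trimming scope {scope!r}")
    for idx in groups:
        rt = rt_all[idx]
        lo = np.quantile(rt, lower_frac)
        hi = np.quantile(rt, 1.0 - upper_frac)
        low_mask[idx] = rt < lo
        high_mask[idx] = rt > hi
    keep = ~(low_mask | high_mask)
    n_low, n_high = int(low_mask.sum()), int(high_mask.sum())
    trimmed = df[keep].reset_index(drop=True)
    meta = dict(dataset.meta)
    meta["trim"] = {
        "lower_frac": lower_frac, "upper_frac": upper_frac, "scope": scope,
        "n_removed_low": n_low, "n_removed_high": n_high,
        "n_removed": int((~keep).sum()), "n_retained": len(trimmed),
    }
    logger.info("trim_rts: removed %d fast and %d slow of %d trials (scope=%s)",
                n_low, n_high, len(df), scope)
    return Dataset(trials=trimmed, study_design=dataset.study_design, meta=meta)


def _drug_code(trials: pd.DataFrame, study_design: str) -> np.ndarray:
    drug = trials["drug"].to_numpy(dtype=float)
    if study_design == WITHIN_SUBJECT:
        # 0 = placebo, anything else = active
        return (drug != 0).astype(float)
    return drug  # dose in mg; dummies are built at fit time


def standardize_attributes(dataset: Dataset) -> Dataset:
    """Compute attribute difference/sum regressors and z-score them over all
    retained trials of the study (sample SD, ddof=1).

    Raw values stay available in ``design`` under ``raw_*`` names; the inverse
    affine map therefore recovers them exactly.
    """
    df = dataset.trials
    raw = pd.DataFrame({
        "magnitude_diff": df["ll_magnitude"].to_numpy(float) - df["ss_magnitude"].to_numpy(float),
        "delay_diff": df["ll_delay"].to_numpy(float) - df["ss_delay"].to_numpy(float),
        "magnitude_sum": df["ll_magnitude"].to_numpy(float) + df["ss_magnitude"].to_numpy(float),
        "delay_sum": df["ll_delay"].to_numpy(float) + df["ss_delay"].to_numpy(float),
    })
    design = {}
    scaling = {}
    for col in raw.columns:
        x = raw[col].to_numpy(dtype=float)
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"attribute column {col!r} has zero variance")
        design[col] = (x - mu) / sd
        design[f"raw_{col}"] = x
        scaling[col] = {"mean": mu, "sd": sd}
    design["drug_code"] = _drug_code(df, dataset.study_design)
    design_df = pd.DataFrame(design, index=df.index)
    meta = dict(dataset.meta)
    meta["standardization"] = scaling
    return Dataset(trials=df, study_design=dataset.study_design,
                   design=design_df, meta=meta)


def preprocess(dataset: Dataset, lower_frac: float = 0.025,
               upper_frac: float = 0.025, scope: str = "pooled") -> Dataset:
    """Trim RT tails, then standardize the attribute regressors."""
    return standardize_attributes(trim_rts(dataset, lower_frac, upper_frac, scope))


def save_json(obj, path) -> None:
    """Serialize a (possibly numpy-laden) result object as JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
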