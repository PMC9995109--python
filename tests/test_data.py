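"""Trial table I/O, RT trimming and attribute standardization."""

import numpy as np
import pandas as pd
import pytest

from itcddm.data import (SchemaError, ValidationError, make_dataset, read_trials,
                         standardize_attributes, trim_rts, write_trials)


def _table(n=20, rt=None, seed=0):
    rng = np.random.default_rng(seed)
    rt = rt if rt is not None else rng.uniform(1, 5, n)
    return pd.DataFrame({
        "participant_id": ["p1"] * (n // 2) + ["p2"] * (n - n // 2),
        "session_id": ["s1"] * n,
        "drug": [0.0] * n,
        "ss_magnitude": rng.integers(5, 100, n).astype(float),
        "ss_delay": rng.integers(0, 10, n).astype(float),
        "ll_magnitude": rng.integers(150, 300, n).astype(float),
        "ll_delay": rng.integers(20, 90, n).astype(float),
        "choice": rng.integers(0, 2, n),
        "rt": rt,
    })


def test_read_write_round_trip_is_identity(tmp_path):
    df = _table()
    path = tmp_path / "trials.csv"
    df.to_csv(path, index=False)
    ds = read_trials(path)
    assert len(ds) == 20
    out = tmp_path / "copy.csv"
    write_trials(ds, out)
    ds2 = read_trials(out)
    pd.testing.assert_frame_equal(ds.trials, ds2.trials)


def test_schema_mapping_and_missing_column(tmp_path):
    df = _table().rename(columns={"rt": "reaction_time"})
    path = tmp_path / "t.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError):
        read_trials(path)
    ds = read_trials(path, schema={"rt": "reaction_time"})
    assert len(ds) == 20


def test_validation_names_offending_row():
    df = _table()
    df.loc[2, "rt"] = 0.0  # third row
    with pytest.raises(ValidationError, match="row 3"):
        make_dataset(df)


def test_invalid_choice_and_dominance_rejected():
    df = _table()
    df.loc[0, "choice"] = 2
    with pytest.raises(ValidationError, match="choice"):
        make_dataset(df)
    df = _table()
    df.loc[1, "ll_delay"] = df.loc[1, "ss_delay"] - 1
    with pytest.raises(ValidationError, match="ll_delay"):
        make_dataset(df)


def test_trim_removes_expected_counts():
    # 200 distinct RTs: 2.5% quantile thresholds strictly exclude 5 per tail
    rt = np.linspace(0.5, 8.0, 200)
    ds = make_dataset(_table(200, rt=rt))
    trimmed = trim_rts(ds)
    assert len(trimmed) == 190
    assert trimmed.meta["trim"]["n_removed_low"] == 5
    assert trimmed.meta["trim"]["n_removed_high"] == 5


def test_trim_identical_rts_removes_nothing():
    ds = make_dataset(_table(40, rt=np.full(40, 2.0)))
    trimmed = trim_rts(ds)
    assert len(trimmed) == 40
    assert trimmed.meta["trim"]["n_removed"] == 0


def test_trim_small_n_follows_quantile_rule():
    # 20 distinct RTs: thresholds are interpolated between order statistics,
    # so 0 or 1 trials can fall strictly outside per tail
    rt = np.arange(1.0, 21.0)
    ds = make_dataset(_table(20, rt=rt))
    trimmed = trim_rts(ds)
    lo = np.quantile(rt, 0.025)
    hi = np.quantile(rt, 0.975)
    expected = int(((rt >= lo) & (rt <= hi)).sum())
    assert len(trimmed) == expected


def test_trim_rejects_bad_fractions_and_empty():
    ds = make_dataset(_table())
    with pytest.raises(ValueError):
        trim_rts(ds, lower_frac=0.6, upper_frac=0.5)


def test_standardize_mean_zero_sd_one_and_invertible():
    ds = standardize_attributes(make_dataset(_table(100)))
    for col in ("magnitude_diff", "delay_diff", "magnitude_sum", "delay_sum"):
        x = ds.design[col].to_numpy()
        assert abs(x.mean()) < 1e-8
        assert abs(x.std(ddof=1) - 1.0) < 1e-8
        sc = ds.meta["standardization"][col]
        back = x * sc["sd"] + sc["mean"]
        np.testing.assert_allclose(back, ds.design[f"raw_{col}"], atol=1e-10)


def test_standardize_hand_example():
    # raw diffs {1, 2, 3} -> z-scores {-1, 0, 1} with sample SD
    df = _table(3)
    df["ss_magnitude"] = [10.0, 10.0, 10.0]
    df["ll_magnitude"] = [11.0, 12.0, 13.0]
    ds = standardize_attributes(make_dataset(df))
    np.testing.assert_allclose(ds.design["magnitude_diff"], [-1.0, 0.0, 1.0],
                               atol=1e-12)


def test_standardize_constant_column_errors():
    df = _table(10)
    df["ll_delay"] = df["ss_delay"] + 5.0  # constant delay_diff
    with pytest.raises(ValueError, match="zero variance"):
        standardize_attributes(make_dataset(df))
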