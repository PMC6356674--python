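"""Confounder balance, sex effect-modification, and power simulation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitdmr import SimConfig
from vitdmr.diagnostics import (
    BALANCE_THRESHOLD,
    apply_balance_flags,
    confounder_balance,
    power_curve,
    sex_interaction,
)

from conftest import make_participants


def test_balance_threshold_is_bonferroni_over_30_tests():
    assert BALANCE_THRESHOLD == pytest.approx(0.05 / 30)
    flags = apply_balance_flags(np.array([0.001, 0.002, 0.0017, 0.05]))
    assert flags.tolist() == [True, False, False, False]


def test_balance_report_structure(sim_table):
    report = confounder_balance(sim_table, "g1")
    # 3 cohorts x 10 confounders
    assert len(report) == 30
    assert set(report["cohort"]) == {"AGES", "LURIC", "Tromso"}
    tested = report.dropna(subset=["p_value"])
    assert (tested["flagged"] == (tested["p_value"] < BALANCE_THRESHOLD)).all()


def test_balance_skips_constant_confounder():
    df = make_participants(40, seed=1, diabetes=0)
    df["g1"] = df["rs12794714"] + df["rs12785878"]
    report = confounder_balance(df, "g1", confounders=("diabetes", "age"), by_cohort=False)
    row = report.set_index("confounder").loc["diabetes"]
    assert row["note"] == "constant; test skipped"
    assert not row["flagged"]


def test_balance_flag_rate_is_nominal_under_the_null():
    """Score-independent confounders: flag rate ~= the Bonferroni level."""
    rng = np.random.default_rng(99)
    n, m = 400, 2000
    df = pd.DataFrame(rng.normal(size=(n, m)), columns=[f"c{i:04d}" for i in range(m)])
    df["g1"] = rng.binomial(4, 0.4, n).astype(float)
    df["cohort"] = "all"
    report = confounder_balance(df, "g1", confounders=df.columns[:m], by_cohort=False)
    flagged = int(report["flagged"].sum())
    # Binomial(2000, 0.0017): mean 3.4, far tail at 11
    assert flagged <= 11
    # and the p-values are calibrated at a conventional level too
    assert 60 <= int((report["p_value"] < 0.05).sum()) <= 140


def test_sex_interaction_symmetry_gives_zero_estimate():
    df = make_participants(200, seed=6)
    df["g1"] = df["rs12794714"] + df["rs12785878"]
    flipped = df.copy()
    flipped["sex"] = np.where(df["sex"] == "male", "female", "male")
    flipped["id"] = flipped["id"] + "_f"
    doubled = pd.concat([df, flipped], ignore_index=True)
    res = sex_interaction(doubled, "GX", "g1", adjustment=None)
    assert abs(res.estimate) < 1e-8


def test_sex_interaction_requires_both_sexes():
    df = make_participants(30, sex="female")
    df["g1"] = df["rs12794714"] + df["rs12785878"]
    with pytest.raises(ValueError, match="both sexes"):
        sex_interaction(df, "GX", "g1")


def test_sex_interaction_null_pvalues_are_uniform():
    """Equal effects by sex: interaction p-values ~ U(0,1) (KS at alpha=0.01)."""
    rng = np.random.default_rng(1234)
    pvals = []
    for _ in range(150):
        n = 300
        g = rng.binomial(4, 0.4, n)
        male = rng.binomial(1, 0.5, n)
        df = pd.DataFrame({
            "g1": g.astype(float),
            "sex": np.where(male == 1, "male", "female"),
            "x25ohd": 52 - 1.33 * g + rng.normal(0, 18, n),
        })
        pvals.append(sex_interaction(df, "GX", "g1", adjustment=None).p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_sex_interaction_detects_doubled_effect():
    """A 2x stage-1 effect in one sex is detected at n=20,000."""
    rng = np.random.default_rng(7)
    hits = 0
    reps = 15
    for _ in range(reps):
        n = 20_000
        g = rng.binomial(4, 0.4, n)
        male = rng.binomial(1, 0.5, n)
        slope = np.where(male == 1, -2.66, -1.33)
        df = pd.DataFrame({
            "g1": g.astype(float),
            "sex": np.where(male == 1, "male", "female"),
            "x25ohd": 52 + slope * g + rng.normal(0, 18, n),
        })
        hits += sex_interaction(df, "GX", "g1", adjustment=None).p_value < 0.05
    assert hits >= 0.8 * reps


def test_sex_interaction_cox_families_run(sim_table):
    df = sim_table.head(2500)
    for assoc in ("XY", "GY"):
        res = sex_interaction(df, assoc, "g1", adjustment=("age",))
        assert 0.0 <= res.p_value <= 1.0
        assert res.se > 0


def test_power_is_nominal_size_under_null_causal_effect():
    """With zero causal effect the 'power' equals the test size."""
    config = dataclasses.replace(SimConfig(), causal_loghr_per_nmol=0.0)
    curve = power_curve(config, [3000], reps=30, alpha=0.05, seed=11, adjustment=None)
    assert curve.loc[0, "power"] <= 0.2  # Binomial(30, .05) upper envelope
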