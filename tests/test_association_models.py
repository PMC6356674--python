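"""Stage-1 OLS, Cox outcome models, and Poisson rate shapes."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vitdmr.association_models import (
    CollinearDesignError,
    build_design,
    fit_cox,
    fit_rate_shapes,
    fit_stage1,
    mortality_rate,
)

from conftest import make_participants


def _ols_fixture(n=40, seed=2):
    rng = np.random.default_rng(seed)
    df = make_participants(n, seed=seed)
    df["g1"] = rng.binomial(4, 0.4, n)
    df["x25ohd"] = 55 - 1.5 * df["g1"] + 0.2 * df["age"] + rng.normal(0, 10, n)
    return df


def test_stage1_perfect_linear_relation():
    df = make_participants(6)
    df["g1"] = np.arange(6)
    df["x25ohd"] = -1.0 * df["g1"] + 60.0
    est, strength = fit_stage1(df, "g1", adjustment=None)
    assert est.beta == pytest.approx(-1.0, abs=1e-10)
    assert strength.r2 == pytest.approx(1.0, abs=1e-6)


def test_stage1_matches_normal_equations():
    df = _ols_fixture()
    est, _ = fit_stage1(df, "g1", adjustment=("age", "bmi"))
    X = np.column_stack([np.ones(len(df)), df["g1"], df["age"], df["bmi"]])
    y = df["x25ohd"].to_numpy()
    beta_ne = np.linalg.solve(X.T @ X, X.T @ y)
    assert est.beta == pytest.approx(beta_ne[1], abs=1e-10)


def test_stage1_f_equals_statsmodels_f_test():
    """The reported F for the score term matches a formal single-term F test."""
    df = _ols_fixture(n=200, seed=5)
    est, strength = fit_stage1(df, "g1", adjustment=("age", "bmi"))
    X = sm.add_constant(np.column_stack([df["g1"], df["age"], df["bmi"]]))
    fit = sm.OLS(df["x25ohd"].to_numpy(), X).fit()
    f_ref = float(fit.f_test("x1 = 0").fvalue)
    assert strength.f_statistic == pytest.approx(f_ref, rel=1e-8)
    assert strength.f_statistic == pytest.approx((est.beta / est.se) ** 2, rel=1e-8)


def test_collinear_design_names_columns():
    df = _ols_fixture()
    df["g1_copy"] = df["g1"]
    with pytest.raises(CollinearDesignError, match="g1_copy"):
        build_design(df, ["g1", "g1_copy", "age"])


def test_cox_single_event_closed_form():
    """Partial-likelihood solution for a 3-subject risk set: beta = ln(2)/2.

    Events at t=1 (x=0, risk set all) and t=2 (x=1, risk set of two); the
    score equation reduces to exp(2*beta) = 2.
    """
    toy = pd.DataFrame({"x": [0, 1, 0], "followup": [1.0, 2.0, 3.0], "death": [1, 1, 0]})
    est = fit_cox(toy, "x", adjustment=None)
    assert est.beta == pytest.approx(0.5 * math.log(2.0), abs=1e-3)


def test_cox_negated_predictor_negates_beta(sim_table):
    df = sim_table.head(1500).copy()
    est = fit_cox(df, "g1", adjustment=None)
    df["g1_neg"] = -df["g1"]
    est_neg = fit_cox(df, "g1_neg", adjustment=None)
    assert est_neg.beta == pytest.approx(-est.beta, abs=1e-10)


def test_cox_invariant_to_time_rescaling(sim_table):
    df = sim_table.head(1500).copy()
    est = fit_cox(df, "g1", adjustment=("age", "sex"))
    df2 = df.copy()
    df2["followup"] = 2.0 * df2["followup"]
    est2 = fit_cox(df2, "g1", adjustment=("age", "sex"))
    assert est2.beta == pytest.approx(est.beta, abs=1e-8)


def test_cox_per20_decrease_scale(sim_table):
    """The per-20-decrease predictor is -x/20: betas map exactly."""
    df = sim_table.head(2000).copy()
    est20 = fit_cox(df, "x25ohd_per20_decrease", adjustment=None)
    df["xraw"] = df["x25ohd"]
    est_raw = fit_cox(df, "xraw", adjustment=None)
    assert est20.beta == pytest.approx(-20.0 * est_raw.beta, rel=1e-6)


def test_cox_recovers_observational_per20_hazard_ratio():
    """Adjusted per-20-decrease Cox recovers the generating HR of 1.20."""
    from vitdmr import SimConfig, simulate_cohort

    table = simulate_cohort(SimConfig(seed=314).scaled(20_000))
    est = fit_cox(table, "x25ohd_per20_decrease")
    assert est.hr_ci[0] < 1.20 < est.hr_ci[1]
    assert est.hr == pytest.approx(1.20, abs=0.08)


def test_cox_requires_events_and_positive_followup():
    df = make_participants(6, death=0)
    with pytest.raises(ValueError, match="no events"):
        fit_cox(df, "rs12794714", adjustment=None)
    df2 = make_participants(6, death=1)
    df2.loc[0, "followup"] = 0.0
    with pytest.raises(ValueError, match="follow-up"):
        fit_cox(df2, "rs12794714", adjustment=None)


def test_category_cox_returns_non_reference_contrasts(sim_table):
    ests = fit_cox(sim_table.head(3000), "category", adjustment=("age", "sex"))
    labels = [e.term for e in ests]
    assert "75-99.9" not in labels
    assert len(labels) == len(set(labels))
    for e in ests:
        assert e.ci[0] < e.beta < e.ci[1]


@pytest.mark.parametrize(
    "deaths, person_years, expected",
    [(574, 10592, 54.2), (485, 12452, 38.9), (869, 26904, 32.3),
     (1808, 57820, 31.3), (250, 8434, 29.6), (17, 837, 20.3), (0, 100, 0.0)],
)
def test_mortality_rate_per_1000_person_years(deaths, person_years, expected):
    assert round(mortality_rate(deaths, person_years), 1) == expected


def test_mortality_rate_rejects_nonpositive_person_years():
    with pytest.raises(ValueError):
        mortality_rate(10, 0)


def _rate_table(n, seed, slope_log=0.0, base_rate=0.03):
    rng = np.random.default_rng(seed)
    x = rng.uniform(5, 145, n)
    py = rng.uniform(2, 15, n)
    lam = base_rate * np.exp(slope_log * (x - 75))
    deaths = rng.poisson(lam * py)
    return pd.DataFrame({"x25ohd": x, "followup": py, "death": deaths})


def test_rate_shapes_constant_rate_null():
    df = _rate_table(4000, seed=8, slope_log=0.0)
    cmp_ = fit_rate_shapes(df, bootstrap_reps=0)
    lin, log = cmp_.fits["linear"], cmp_.fits["log_linear"]
    assert abs(log.params[1]) < 0.002  # log slope ~ 0
    assert np.allclose(lin.rate, log.rate, rtol=0.15)
    assert (lin.rate > 0).all() and (log.rate > 0).all()


def test_rate_shapes_recover_log_linear_slope():
    df = _rate_table(6000, seed=9, slope_log=-0.02)
    cmp_ = fit_rate_shapes(df, bootstrap_reps=49, seed=1)
    assert cmp_.fits["log_linear"].params[1] == pytest.approx(-0.02, abs=0.004)
    assert cmp_.preferred == "log_linear"
    assert cmp_.aic_difference > 0
    assert cmp_.p_value < 0.05


def test_rate_shapes_prefer_log_linear_across_replicates():
    wins = 0
    for seed in range(10):
        df = _rate_table(3000, seed=100 + seed, slope_log=-0.02)
        cmp_ = fit_rate_shapes(df, bootstrap_reps=0)
        wins += cmp_.aic_difference > 0
    assert wins >= 8  # AIC favors the generating shape in >=90%-ish of reps


def test_rate_curve_table_units():
    df = _rate_table(2000, seed=3)
    cmp_ = fit_rate_shapes(df, bootstrap_reps=0)
    table = cmp_.curve_table()
    assert set(table.columns) == {"x25ohd", "log_linear", "linear", "spline"}
    assert (table["log_linear"] > 0).all()
    # per-1000-person-years scale: constant-rate data generated at 30/1000 py
    assert 15 < table["log_linear"].median() < 60
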