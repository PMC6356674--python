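"""Wald ratio, delta-method SE, midpoint projections, per-allele HRs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitdmr.association_models import StageEstimate
from vitdmr.io_harmonize import DEFAULT_CATEGORIES
from vitdmr.mr_core import (
    delta_se,
    fieller_ci,
    per_allele_hr,
    project_midpoints,
    wald_ratio_hr,
)

# Standard errors back-derived from symmetric 95% CIs as (hi - lo)/3.92.
SE_GY_G1 = (0.0511 + 0.0146) / 3.92
SE_GX_G1 = (1.66 - 1.00) / 3.92
SE_GY_G2 = (0.0291 + 0.0076) / 3.92
SE_GX_G2 = (0.90 - 0.52) / 3.92


@pytest.mark.parametrize(
    "k, beta_gy, beta_gx, expected_2dp",
    [(20.0, 0.0183, -1.33, 1.32), (20.0, 0.01074, -0.71, 1.35), (0.0, 0.0183, -1.33, 1.0)],
)
def test_wald_ratio_worked_examples(k, beta_gy, beta_gx, expected_2dp):
    result = wald_ratio_hr(k, beta_gy, beta_gx)
    assert round(result.hr, 2) == expected_2dp


def test_wald_ratio_sign_convention():
    """Positive per-allele hazard with a lowering allele means harm per decrease."""
    res = wald_ratio_hr(20.0, 0.0183, -1.33)
    assert res.hr > 1.0
    assert res.ratio == pytest.approx(0.0183 / 1.33)


def test_wald_ratio_rejects_null_instrument():
    with pytest.raises(ValueError, match="beta_GX"):
        wald_ratio_hr(20.0, 0.0183, 0.0)


def test_wald_ratio_weak_instrument_flag():
    strong = wald_ratio_hr(20.0, 0.0183, -1.33, f_statistic=52.0)
    weak = wald_ratio_hr(20.0, 0.0183, -1.33, f_statistic=4.0)
    assert not strong.weak_instrument
    assert weak.weak_instrument


def test_wald_ratio_ci_brackets_hr():
    res = wald_ratio_hr(20.0, 0.0183, -1.33, se_gy=SE_GY_G1, se_gx=SE_GX_G1)
    assert res.ci[0] < res.hr < res.ci[1]
    assert res.ci[0] == pytest.approx(0.80, abs=0.005)  # recomputed delta interval


def test_delta_se_degenerate_limit():
    assert delta_se(0.0183, 0.01, 1.33, 0.0) == pytest.approx(0.01 / 1.33)


def test_delta_se_hand_computed_value():
    """Plugging the G1 coefficients and back-derived SEs into the formula."""
    assert delta_se(0.0183, SE_GY_G1, 1.33, SE_GX_G1) == pytest.approx(0.012721, abs=1e-5)


def test_delta_se_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        delta_se(0.1, 0.01, 0.0, 0.01)
    with pytest.raises(ValueError):
        delta_se(0.1, -0.01, 1.0, 0.01)


@pytest.mark.parametrize(
    "beta_gy, se_gy, beta_gx, se_gx",
    [(0.0183, SE_GY_G1, 1.33, SE_GX_G1),
     (0.01074, SE_GY_G2, 0.71, SE_GX_G2),
     (0.05, 0.01, 2.0, 0.1)],
)
def test_delta_se_agrees_with_monte_carlo(beta_gy, se_gy, beta_gx, se_gx):
    """10,000-draw parametric MC SD of the ratio within 5% of the delta SE."""
    rng = np.random.default_rng(0)
    draws = rng.normal(beta_gy, se_gy, 10_000) / rng.normal(beta_gx, se_gx, 10_000)
    mc_sd = draws.std(ddof=1)
    d = delta_se(beta_gy, se_gy, beta_gx, se_gx)
    assert abs(mc_sd / d - 1.0) < 0.05


@settings(deadline=None, derandomize=True)
@given(
    k1=st.floats(-40, 40), k2=st.floats(-40, 40),
    beta_gy=st.floats(-0.1, 0.1), beta_gx=st.floats(0.1, 3.0),
)
def test_wald_ratio_multiplicative_in_k(k1, k2, beta_gy, beta_gx):
    hr = lambda k: wald_ratio_hr(k, beta_gy, -beta_gx).hr
    assert hr(k1 + k2) == pytest.approx(hr(k1) * hr(k2), rel=1e-9)


@settings(deadline=None, derandomize=True)
@given(c=st.floats(0.01, 100).filter(lambda v: v != 0))
def test_delta_se_scale_consistency(c):
    base = delta_se(0.0183, SE_GY_G1, 1.33, SE_GX_G1)
    scaled = delta_se(0.0183, SE_GY_G1, c * 1.33, c * SE_GX_G1)
    assert scaled == pytest.approx(base / abs(c), rel=1e-9)


@pytest.mark.parametrize(
    "beta, se, expected_hr",
    [(0.0183, SE_GY_G1, 1.0184), (0.01074, SE_GY_G2, 1.0108), (0.0, 0.01, 1.0)],
)
def test_per_allele_hr(beta, se, expected_hr):
    # tolerance 1e-4: published HRs were computed from unrounded coefficients
    hr, ci = per_allele_hr(beta, se)
    assert hr == pytest.approx(expected_hr, abs=1e-4)
    assert ci[0] < hr < ci[1]


def test_per_allele_hr_without_se():
    hr, ci = per_allele_hr(0.0183)
    assert ci is None and hr == pytest.approx(math.exp(0.0183))


def test_midpoint_projection_worked_examples():
    """Per-unit G1 ratio projected onto the observed category medians."""
    ratio = 0.0183 / 1.33
    proj = project_midpoints(ratio, DEFAULT_CATEGORIES)
    by_label = dict(zip(proj.labels, proj.hr))
    assert round(by_label["30-39.9"], 2) == 1.87
    assert round(by_label["100-150"], 2) == 0.69
    assert by_label["75-99.9"] == 1.0  # reference projects to exactly 1


def test_midpoint_projection_ci_ordering():
    ratio = 0.0183 / 1.33
    se = delta_se(0.0183, SE_GY_G1, 1.33, SE_GX_G1)
    proj = project_midpoints(ratio, DEFAULT_CATEGORIES, (ratio - 1.96 * se, ratio + 1.96 * se))
    for i, ci in enumerate(proj.ci):
        if i == proj.reference_index:
            assert ci is None
        else:
            assert ci[0] < proj.hr[i] < ci[1]


def test_stage_estimate_inputs_accepted():
    gy = StageEstimate.from_fit("g1", 0.0183, SE_GY_G1, 10501)
    gx = StageEstimate.from_fit("g1", -1.33, SE_GX_G1, 10501)
    res = wald_ratio_hr(20.0, gy, gx, score_used="G1")
    assert round(res.hr, 2) == 1.32
    assert res.se_ratio == pytest.approx(0.012721, abs=1e-5)


def test_fieller_interval_behaviour():
    # strong instrument: bounded interval containing the ratio
    ci = fieller_ci(0.0183, SE_GY_G1, -1.33, SE_GX_G1)
    assert ci is not None
    assert ci[0] < 0.0183 / -1.33 < ci[1]
    # instrument not significantly non-zero: unbounded
    assert fieller_ci(0.0183, SE_GY_G1, -0.1, SE_GX_G1) is None
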