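"""Instrument validity checks, effect-modification tests, and power simulation.

A valid allele-score instrument must be unrelated to measured confounders;
the balance check regresses each of the ten measured confounders on the
score within each cohort (OLS slope t-test for continuous variables,
logistic Wald test for binary ones, an F-test across category dummies for
season) at the Bonferroni level 0.05/(3 cohorts x 10 confounders) = 0.0017.
Sex effect-modification is tested with a sex-by-predictor interaction term
in the relevant stage model. The power simulator reruns the whole
genotype -> exposure -> survival -> Wald-ratio chain at a grid of sample
sizes and reports how often the delta-method CI excludes 1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .allele_scores import G1, ScoreDefinition, add_scores
from .association_models import ADJUSTMENT_SET, StageEstimate, build_design, fit_cox, fit_stage1
from .io_harmonize import CONFOUNDER_SET
from .mr_core import wald_ratio_hr
from .synthetic_cohort import SimConfig, simulate_cohort

#: Bonferroni threshold for the score-confounder balance tests:
#: 0.05 / (3 cohorts x 10 confounders).
BALANCE_THRESHOLD = 0.05 / 30


def apply_balance_flags(p_values: pd.Series | np.ndarray, threshold: float = BALANCE_THRESHOLD) -> np.ndarray:
    """Flag rule of the balance report: flagged iff p < threshold."""
    return np.asarray(p_values) < threshold


def _balance_test(score: np.ndarray, confounder: pd.Series) -> tuple[float, float, str]:
    """Association test of a score with one confounder.

    Returns (statistic, p, family). The score is the predictor: continuous
    confounders use the OLS slope t-test, binary ones a logistic Wald test,
    and multi-level categoricals an OLS F-test of the score on the category
    dummies (a symmetric association screen).
    """
    y = confounder
    if y.dtype == object or isinstance(y.dtype, pd.CategoricalDtype):
        levels = pd.unique(y.astype(str))
        if len(levels) == 2:
            binary = (y.astype(str) == sorted(map(str, levels))[-1]).astype(float).to_numpy()
            return _logistic_wald(score, binary)
        dummies = pd.get_dummies(y.astype(str), drop_first=True, dtype=float).to_numpy()
        model = sm.OLS(score, sm.add_constant(dummies)).fit()
        f = model.fvalue
        return float(f), float(model.f_pvalue), "ols_f"
    vals = y.astype(float).to_numpy()
    if set(np.unique(vals[~np.isnan(vals)])) <= {0.0, 1.0}:
        return _logistic_wald(score, vals)
    model = sm.OLS(vals, sm.add_constant(score)).fit()
    t = model.tvalues[1]
    return float(t), float(model.pvalues[1]), "ols_t"


def _logistic_wald(score: np.ndarray, binary: np.ndarray) -> tuple[float, float, str]:
    model = sm.Logit(binary, sm.add_constant(score)).fit(disp=0, maxiter=100)
    z = model.tvalues[1]
    return float(z), float(model.pvalues[1]), "logit_wald"


def confounder_balance(
    records: pd.DataFrame,
    score: str = "g1",
    confounders: Sequence[str] = CONFOUNDER_SET,
    by_cohort: bool = True,
    threshold: float = BALANCE_THRESHOLD,
) -> pd.DataFrame:
    """Score-confounder balance report.

    One row per (cohort, confounder): test statistic, p-value and a flag at
    the Bonferroni ``threshold``. Constant confounders are skipped with a
    notice in the ``note`` column.
    """
    groups = records.groupby("cohort", sort=True) if by_cohort else [("all", records)]
    rows = []
    for cohort, group in groups:
        data = group.dropna(subset=[score])
        g = data[score].astype(float).to_numpy()
        for confounder in confounders:
            if confounder not in data.columns:
                rows.append(dict(cohort=cohort, score=score, confounder=confounder,
                                 statistic=np.nan, p_value=np.nan, flagged=False,
                                 note="absent"))
                continue
            col = data[confounder].dropna()
            if col.nunique() < 2:
                rows.append(dict(cohort=cohort, score=score, confounder=confounder,
                                 statistic=np.nan, p_value=np.nan, flagged=False,
                                 note="constant; test skipped"))
                continue
            mask = data[confounder].notna()
            stat, p, family = _balance_test(g[mask.to_numpy()], data.loc[mask, confounder])
            rows.append(dict(cohort=cohort, score=score, confounder=confounder,
                             statistic=stat, p_value=p,
                             flagged=bool(p < threshold), note=family))
    return pd.DataFrame(rows)


@dataclasses.dataclass
class InteractionResult:
    """Sex-by-predictor interaction: estimate, SE and Wald p-value."""

    association: str
    estimate: float
    se: float
    p_value: float
    n: int


def sex_interaction(
    records: pd.DataFrame,
    association: str = "GY",
    score: str = "g1",
    adjustment: Sequence[str] | None = ADJUSTMENT_SET,
) -> InteractionResult:
    """Test effect modification by sex for one association.

    ``association`` selects the model: ``"GX"`` (score -> 25(OH)D, OLS),
    ``"XY"`` (25(OH)D -> mortality, Cox on the per-20-decrease scale) or
    ``"GY"`` (score -> mortality, Cox). The model is refitted with a
    sex-by-predictor product term; its Wald p-value is reported.
    """
    if records["sex"].nunique() < 2:
        raise ValueError("both sexes must be present to test sex interaction")
    predictor = {"GX": score, "XY": "x25ohd_per20_decrease", "GY": score}[association]
    adjustment = tuple(a for a in (adjustment or ()) if a not in ("sex", predictor, score))

    data = records.copy()
    if predictor == "x25ohd_per20_decrease":
        data[predictor] = -data["x25ohd"] / 20.0
    data = data.dropna(subset=[predictor, "sex", *(a for a in adjustment if a in data.columns)])
    data["male"] = (data["sex"] == "male").astype(float)
    data["sex_x_predictor"] = data["male"] * data[predictor].astype(float)
    design = build_design(data, [predictor, "male", "sex_x_predictor", *adjustment])

    if association == "GX":
        data = data.dropna(subset=["x25ohd"])
        design = design.loc[data.index]
        X = sm.add_constant(design.to_numpy(float))
        fit = sm.OLS(data["x25ohd"].to_numpy(float), X).fit()
        j = 1 + list(design.columns).index("sex_x_predictor")
        return InteractionResult(association, float(fit.params[j]), float(fit.bse[j]),
                                 float(fit.pvalues[j]), len(data))

    from lifelines import CoxPHFitter

    data = data.dropna(subset=["followup", "death"])
    design = design.loc[data.index]
    fit_df = design.assign(followup=data["followup"].to_numpy(float),
                           death=data["death"].to_numpy(int))
    cph = CoxPHFitter().fit(fit_df, duration_col="followup", event_col="death")
    beta = float(cph.params_["sex_x_predictor"])
    se = float(cph.standard_errors_["sex_x_predictor"])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return InteractionResult(association, beta, se, p, len(data))


def mr_single_replicate(
    config: SimConfig,
    score: ScoreDefinition = G1,
    adjustment: Sequence[str] | None = ADJUSTMENT_SET,
    k: float = 20.0,
) -> tuple[StageEstimate, StageEstimate, "object"]:
    """Simulate one cohort and run the two-stage MR on it.

    Returns (stage-1 estimate, stage-2 per-allele estimate, MrResult per k).
    Used by the power and coverage studies.
    """
    table = add_scores(simulate_cohort(config), (score,))
    stage1, strength = fit_stage1(table, score.column, adjustment)
    stage2 = fit_cox(table, score.column, adjustment)
    mr = wald_ratio_hr(k, stage2, stage1, score_used=score.name,
                       f_statistic=strength.f_statistic)
    return stage1, stage2, mr


def power_curve(
    base_config: SimConfig,
    n_grid: Sequence[int],
    reps: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    score: ScoreDefinition = G1,
    adjustment: Sequence[str] | None = ADJUSTMENT_SET,
    k: float = 20.0,
) -> pd.DataFrame:
    """Empirical power of the MR test (delta CI excluding HR = 1) per sample size.

    For each n the three cohorts are rescaled proportionally, ``reps``
    replicates simulated, and the fraction detected at level ``alpha``
    (two-sided z test on the ratio, i.e. the 1-alpha delta CI excluding 1)
    reported with a binomial standard error.
    """
    z = stats.norm.ppf(1 - alpha / 2)
    root = np.random.SeedSequence(seed)
    rows = []
    for n_total, stream in zip(n_grid, root.spawn(len(n_grid))):
        child_seeds = stream.generate_state(reps)
        hits = 0
        for r in range(reps):
            cfg = base_config.scaled(int(n_total), seed=int(child_seeds[r] % 2**31))
            _, _, mr = mr_single_replicate(cfg, score, adjustment, k)
            if mr.se_ratio and abs(mr.ratio) / mr.se_ratio > z:
                hits += 1
        power = hits / reps
        rows.append(dict(n=int(n_total), reps=reps, alpha=alpha, power=power,
                         se=float(np.sqrt(power * (1 - power) / reps))))
    return pd.DataFrame(rows)
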