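"""Regression machinery: stage-1 exposure models, Cox outcome models, and
Poisson mortality-rate shapes.

Three model families are fitted on the harmonized participant table:

* stage 1 — ordinary least squares of 25(OH)D on a genetic score (plus the
  adjustment set), yielding the per-allele exposure effect beta_GX with its
  F-statistic and partial R-squared (instrument strength);
* stage 2 / observational — Cox proportional hazards (Efron tie handling) of
  all-cause mortality on the score (beta_GY), on 25(OH)D scaled so the hazard
  ratio reads "per 20 nmol/L decrease", or on exposure categories;
* rate shapes — Poisson regression of deaths with log person-years offset,
  with linear (identity-link), log-linear (log-link) and natural-cubic-spline
  mean functions, compared by AIC and a parametric-bootstrap p-value (the two
  single-slope shapes are non-nested).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special
from lifelines import CoxPHFitter

from .io_harmonize import ADJUSTMENT_SET, CategoryScheme, DEFAULT_CATEGORIES, assign_categories

Z95 = 1.96  # normal quantile used for all symmetric 95% intervals


@dataclasses.dataclass
class StageEstimate:
    """A fitted coefficient with its uncertainty.

    ``beta`` is in nmol/L per allele for stage 1, log-hazard per allele for
    the genetic Cox model, and log-hazard per unit predictor otherwise.
    """

    term: str
    beta: float
    se: float
    ci: tuple[float, float]
    n: int

    @classmethod
    def from_fit(cls, term: str, beta: float, se: float, n: int) -> "StageEstimate":
        return cls(term, float(beta), float(se), (float(beta - Z95 * se), float(beta + Z95 * se)), int(n))

    @property
    def hr(self) -> float:
        """exp(beta); meaningful for log-hazard coefficients."""
        return float(np.exp(self.beta))

    @property
    def hr_ci(self) -> tuple[float, float]:
        return (float(np.exp(self.ci[0])), float(np.exp(self.ci[1])))


@dataclasses.dataclass
class InstrumentStrength:
    """First-stage strength: F-statistic and partial variance explained."""

    f_statistic: float
    r2: float


class CollinearDesignError(ValueError):
    """Raised when the adjustment design matrix is rank-deficient."""


_CATEGORICAL = {"cohort", "sex", "season"}


def build_design(
    df: pd.DataFrame, terms: Sequence[str], drop_first: bool = True
) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) for the given terms.

    Categorical terms are dummy-coded against their first level. Raises
    :class:`CollinearDesignError` naming offending columns when the design
    (with intercept) is rank-deficient.
    """
    blocks: list[pd.DataFrame] = []
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"model term {term!r} not in table")
        col = df[term]
        if term in _CATEGORICAL or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=term, drop_first=drop_first, dtype=float)
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(term))
    design = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
    with_const = np.column_stack([np.ones(len(design)), design.to_numpy(float)]) if len(design.columns) else np.ones((len(df), 1))
    rank = np.linalg.matrix_rank(with_const)
    if rank < with_const.shape[1]:
        _, r = np.linalg.qr(with_const)
        diag = np.abs(np.diag(r))
        bad_idx = [i - 1 for i in np.flatnonzero(diag < 1e-8 * diag.max()) if i > 0]
        bad = [design.columns[i] for i in bad_idx] or list(design.columns)
        raise CollinearDesignError(f"collinear design columns: {bad}")
    return design


def _complete_cases(df: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    return df.dropna(subset=[c for c in columns if c in df.columns])


def fit_stage1(
    records: pd.DataFrame,
    score: str = "g1",
    adjustment: Sequence[str] | None = ADJUSTMENT_SET,
    exposure: str = "x25ohd",
) -> tuple[StageEstimate, InstrumentStrength]:
    """OLS of 25(OH)D on a genetic score: the per-allele exposure effect.

    Returns the score coefficient (beta_GX) and instrument strength. The
    F-statistic is the squared t of the score term; partial R-squared is the
    share of residual exposure variance explained by the score after the
    adjustment covariates (t^2 / (t^2 + df_resid)).

    Use ``adjustment=("cohort",)`` for score/SNP associations adjusted only
    for study.
    """
    adjustment = tuple(adjustment or ())
    data = _complete_cases(records, [score, exposure, *adjustment])
    design = build_design(data, [score, *adjustment])
    X = sm.add_constant(design.to_numpy(float), has_constant="add")
    model = sm.OLS(data[exposure].to_numpy(float), X).fit()
    j = 1 + list(design.columns).index(score)
    beta, se = model.params[j], model.bse[j]
    df_resid = model.df_resid
    if se == 0:  # exact fit: the score explains the residual variance fully
        strength = InstrumentStrength(f_statistic=float("inf"), r2=1.0)
    else:
        t = beta / se
        strength = InstrumentStrength(
            f_statistic=float(t**2), r2=float(t**2 / (t**2 + df_resid))
        )
    return StageEstimate.from_fit(score, beta, se, len(data)), strength


def fit_cox(
    records: pd.DataFrame,
    predictor: str = "g1",
    adjustment: Sequence[str] | None = ADJUSTMENT_SET,
    scheme: CategoryScheme = DEFAULT_CATEGORIES,
    duration: str = "followup",
    event: str = "death",
) -> StageEstimate | list[StageEstimate]:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``predictor`` is a column name (e.g. a score for the per-allele
    log-hazard beta_GY), or one of the special forms:

    * ``"x25ohd_per20_decrease"`` — the predictor is -x25ohd/20, so
      exp(beta) is the hazard ratio per 20 nmol/L *decrease* in 25(OH)D;
    * ``"category"`` — exposure-category factor versus the reference bin;
      returns one estimate per non-reference category.
    """
    adjustment = tuple(a for a in (adjustment or ()) if a != predictor)
    data = records.copy()
    if predictor == "x25ohd_per20_decrease":
        data[predictor] = -data["x25ohd"] / 20.0
        base_cols = [predictor]
    elif predictor == "category":
        cats = assign_categories(data["x25ohd"], scheme)
        dummies = pd.get_dummies(cats, prefix="cat", dtype=float)
        dummies = dummies.drop(columns=f"cat_{scheme.reference_label}", errors="ignore")
        dummies = dummies.loc[:, dummies.sum() > 0]  # drop empty categories
        data = pd.concat([data, dummies], axis=1)
        base_cols = list(dummies.columns)
    else:
        base_cols = [predictor]

    data = _complete_cases(data, [*base_cols, duration, event, *adjustment])
    if (data[duration] <= 0).any():
        raise ValueError("all fitted rows must have follow-up > 0")
    if int(data[event].sum()) == 0:
        raise ValueError("no events in the data; Cox model is undefined")

    design = build_design(data, [*base_cols, *adjustment])
    fit_df = design.assign(
        **{duration: data[duration].to_numpy(float), event: data[event].to_numpy(int)}
    )
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col=duration, event_col=event)
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"Cox model did not converge: {exc}") from exc

    n = len(data)
    if predictor == "category":
        out = []
        for label in scheme.labels:
            col = f"cat_{label}"
            if label == scheme.reference_label or col not in base_cols:
                continue
            out.append(
                StageEstimate.from_fit(label, cph.params_[col], cph.standard_errors_[col], n)
            )
        return out
    return StageEstimate.from_fit(
        predictor, cph.params_[base_cols[0]], cph.standard_errors_[base_cols[0]], n
    )


def mortality_rate(deaths: float, person_years: float) -> float:
    """Absolute mortality rate per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if deaths < 0:
        raise ValueError("deaths must be non-negative")
    return 1000.0 * deaths / person_years


# ---------------------------------------------------------------------------
# Mortality-rate shape models (Poisson with person-time offset)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RateShapeFit:
    """One fitted rate shape: coefficients, log-likelihood and a rate curve."""

    shape: str
    params: np.ndarray
    loglik: float
    aic: float
    grid: np.ndarray
    rate: np.ndarray  # events per person-year along `grid`


@dataclasses.dataclass
class RateShapeComparison:
    """Linear vs log-linear vs spline mortality-rate shapes.

    ``p_value`` is a parametric-bootstrap tail probability of the observed
    log-likelihood advantage of the log-linear shape under data simulated
    from the fitted linear shape (the two shapes are non-nested, so no
    standard likelihood-ratio reference distribution applies; this bootstrap
    stands in for an unspecified textbook test and is flagged as such in
    reports).
    """

    fits: dict[str, RateShapeFit]
    preferred: str
    aic_difference: float  # AIC(linear) - AIC(log_linear); > 0 favors log-linear
    p_value: float | None

    def curve_table(self) -> pd.DataFrame:
        """Rate curves (per 1000 person-years) as a long two-column-per-shape table."""
        grid = self.fits["log_linear"].grid
        out = pd.DataFrame({"x25ohd": grid})
        for name, fit in self.fits.items():
            out[name] = 1000.0 * fit.rate
        return out


def _poisson_loglik(deaths: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-300, None)
    return float(np.sum(deaths * np.log(mu) - mu - special.gammaln(deaths + 1)))


def _fit_linear_rate(x: np.ndarray, deaths: np.ndarray, py: np.ndarray) -> tuple[np.ndarray, float]:
    """Identity-link Poisson rate = a + b*x by constrained maximum likelihood.

    Rates are floored at 1e-10 per person-year so the likelihood stays
    defined when the line dips non-positive.
    """

    def nll(theta: np.ndarray) -> float:
        lam = np.maximum(theta[0] + theta[1] * x, 1e-10)
        return -_poisson_loglik(deaths, lam * py)

    rate0 = deaths.sum() / py.sum()
    res = optimize.minimize(nll, x0=np.array([rate0, 0.0]), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    if not res.success:
        raise RuntimeError(f"linear rate fit did not converge: {res.message}")
    return res.x, -res.fun


def _spline_basis(x: np.ndarray, df: int, knots_from: np.ndarray) -> np.ndarray:
    from patsy import dmatrix

    lo, hi = float(knots_from.min()), float(knots_from.max())
    return np.asarray(
        dmatrix(
            "cr(x, df=dfree, lower_bound=lo, upper_bound=hi) - 1",
            {"x": x, "dfree": df, "lo": lo, "hi": hi},
            return_type="matrix",
        )
    )


def fit_rate_shapes(
    records: pd.DataFrame,
    spline_df: int = 4,
    grid: np.ndarray | None = None,
    bootstrap_reps: int = 200,
    seed: int | None = None,
    duration: str = "followup",
    event: str = "death",
) -> RateShapeComparison:
    """Fit the three mortality-rate shapes over 25(OH)D and compare them.

    Deaths are modelled as Poisson counts with person-years of follow-up as
    exposure. The linear shape uses an identity link (constrained so fitted
    rates stay positive), the log-linear shape a log link, and the spline a
    natural cubic basis with ``spline_df`` degrees of freedom on the log
    scale (display only; never used for the MR estimate). Rows with zero
    follow-up are dropped (no person-time contribution).
    """
    data = records.dropna(subset=["x25ohd", duration, event])
    data = data[data[duration] > 0]
    x = data["x25ohd"].to_numpy(float)
    deaths = data[event].to_numpy(float)
    py = data[duration].to_numpy(float)
    if grid is None:
        grid = np.linspace(0.0, 150.0, 151)

    fits: dict[str, RateShapeFit] = {}

    # log-linear: log rate = a + b x
    X_log = sm.add_constant(x)
    glm_log = sm.GLM(deaths, X_log, family=sm.families.Poisson(), exposure=py).fit()
    rate_log = np.exp(glm_log.params[0] + glm_log.params[1] * grid)
    ll_log = _poisson_loglik(deaths, glm_log.mu)
    fits["log_linear"] = RateShapeFit("log_linear", np.asarray(glm_log.params), ll_log,
                                      2 * 2 - 2 * ll_log, grid, rate_log)

    # linear: rate = a + b x, identity link
    theta_lin, ll_lin = _fit_linear_rate(x, deaths, py)
    rate_lin = np.maximum(theta_lin[0] + theta_lin[1] * grid, 1e-10)
    fits["linear"] = RateShapeFit("linear", theta_lin, ll_lin, 2 * 2 - 2 * ll_lin, grid, rate_lin)

    # natural cubic spline on the log scale (display only)
    B = _spline_basis(x, spline_df, knots_from=x)
    X_sp = sm.add_constant(B)
    glm_sp = sm.GLM(deaths, X_sp, family=sm.families.Poisson(), exposure=py).fit()
    grid_sp = np.clip(grid, x.min(), x.max())
    Bg = _spline_basis(grid_sp, spline_df, knots_from=x)
    rate_sp = np.exp(np.asarray(sm.add_constant(Bg)) @ np.asarray(glm_sp.params))
    ll_sp = _poisson_loglik(deaths, glm_sp.mu)
    k_sp = X_sp.shape[1]
    fits["spline"] = RateShapeFit("spline", np.asarray(glm_sp.params), ll_sp,
                                  2 * k_sp - 2 * ll_sp, grid, rate_sp)

    aic_diff = fits["linear"].aic - fits["log_linear"].aic
    stat_obs = ll_log - ll_lin

    p_value: float | None = None
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        lam_hat = np.maximum(theta_lin[0] + theta_lin[1] * x, 1e-10)
        hits = 0
        for _ in range(bootstrap_reps):
            d_star = rng.poisson(lam_hat * py).astype(float)
            try:
                glm_b = sm.GLM(d_star, X_log, family=sm.families.Poisson(), exposure=py).fit()
                ll_log_b = _poisson_loglik(d_star, glm_b.mu)
                _, ll_lin_b = _fit_linear_rate(x, d_star, py)
            except Exception:
                continue
            if ll_log_b - ll_lin_b >= stat_obs:
                hits += 1
        p_value = (hits + 1) / (bootstrap_reps + 1)

    preferred = "log_linear" if aic_diff > 0 else "linear"
    return RateShapeComparison(fits=fits, preferred=preferred,
                               aic_difference=float(aic_diff), p_value=p_value)
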