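"""End-to-end orchestration: data -> harmonization -> scores -> models -> MR -> report.

`run_pipeline` reproduces the full analysis on a simulated or user-supplied
participant table: descriptive summaries per cohort, score/SNP exposure
associations, per-allele and per-20 nmol/L hazard ratios, Wald-ratio MR
estimates with delta-method intervals, a category table (N, deaths,
person-years, death rates and four hazard-ratio rows), mortality-rate shape
fits, and instrument diagnostics. A coefficient-override entry point
(`mr_from_betas`) feeds externally obtained stage coefficients straight into
the causal estimator, for worked examples when raw data are unavailable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import allele_scores, association_models, diagnostics, io_harmonize, mr_core
from .allele_scores import G1, G2, ScoreDefinition
from .association_models import InstrumentStrength, RateShapeComparison, StageEstimate
from .io_harmonize import ADJUSTMENT_SET, CategoryScheme, DEFAULT_CATEGORIES, SNP_IDS
from .mr_core import CategoryProjection, MrResult
from .synthetic_cohort import SimConfig, simulate_cohort


@dataclasses.dataclass
class RunConfig:
    """One analysis run.

    ``mode`` is ``"simulate"`` (generate a synthetic multi-cohort sample from
    ``sim``) or ``"files"`` (read ``participants`` with genotypes inline or
    joined from ``vcf``). ``k`` is the exposure change, in nmol/L decrease,
    at which causal hazard ratios are reported.
    """

    mode: str = "simulate"
    participants: str | Path | None = None
    vcf: str | Path | None = None
    orientation: Mapping[str, str] | None = None
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    scores: tuple[ScoreDefinition, ...] = (G1, G2)
    k: float = 20.0
    scheme: CategoryScheme = DEFAULT_CATEGORIES
    adjustment: tuple[str, ...] = ADJUSTMENT_SET
    seed: int = 0
    rate_bootstrap_reps: int = 100
    run_diagnostics: bool = True

    def validate(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k <= 0:
            raise ValueError("k must be positive (nmol/L decrease)")
        if self.mode == "files" and self.participants is None:
            raise ValueError("files mode requires a participants path")


@dataclasses.dataclass
class PipelineResult:
    """All tables and estimates of one run, plus the structured log."""

    table: pd.DataFrame
    descriptive: pd.DataFrame
    stage1_table: pd.DataFrame
    stage1: dict[str, tuple[StageEstimate, InstrumentStrength]]
    stage2: dict[str, StageEstimate]
    observational_per20: StageEstimate
    mr: dict[str, MrResult]
    category_table: pd.DataFrame
    projections: dict[str, CategoryProjection]
    rate_shapes: RateShapeComparison | None
    balance: pd.DataFrame | None
    interactions: pd.DataFrame | None
    log: list[str]

    def write(self, outdir: str | Path) -> None:
        """Write the report bundle as deterministic delimited text."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.6g")
        self.descriptive.to_csv(out / "table1_descriptive.tsv", **kw)
        self.stage1_table.to_csv(out / "table2_score_exposure.tsv", **kw)
        self._hr_table().to_csv(out / "hazard_ratios.tsv", **kw)
        self.category_table.to_csv(out / "table3_categories.tsv", **kw)
        if self.rate_shapes is not None:
            self.rate_shapes.curve_table().to_csv(out / "rate_shapes.tsv", **kw)
        if self.balance is not None:
            self.balance.to_csv(out / "balance_report.tsv", **kw)
        if self.interactions is not None:
            self.interactions.to_csv(out / "sex_interactions.tsv", **kw)
        (out / "run.log").write_text("\n".join(self.log) + "\n", encoding="utf-8")

    def _hr_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.stage2.items():
            hr, ci = mr_core.per_allele_hr(est)
            rows.append(dict(quantity=f"per-allele HR ({name})", hr=hr,
                             ci_low=ci[0], ci_high=ci[1], n=est.n))
        e = self.observational_per20
        rows.append(dict(quantity="observational HR per 20 nmol/L decrease",
                         hr=e.hr, ci_low=e.hr_ci[0], ci_high=e.hr_ci[1], n=e.n))
        for name, mr in self.mr.items():
            rows.append(dict(quantity=f"MR HR per {mr.k:g} nmol/L decrease ({name})",
                             hr=mr.hr, ci_low=mr.ci[0] if mr.ci else np.nan,
                             ci_high=mr.ci[1] if mr.ci else np.nan, n=self.stage2[name].n))
        return pd.DataFrame(rows)


def _descriptive_table(df: pd.DataFrame) -> pd.DataFrame:
    def summarize(group: pd.DataFrame, label: str) -> dict:
        return dict(
            cohort=label,
            n=len(group),
            females_pct=100.0 * (group["sex"] == "female").mean(),
            age_mean=group["age"].mean(),
            age_sd=group["age"].std(),
            bmi_mean=group["bmi"].mean(),
            x25ohd_mean=group["x25ohd"].mean(),
            x25ohd_sd=group["x25ohd"].std(),
            smoker_pct=100.0 * group["smoker"].mean(),
            diabetes_pct=100.0 * group["diabetes"].mean(),
            hypertension_pct=100.0 * group["hypertension"].mean(),
            cvd_pct=100.0 * group["cvd_history"].mean(),
            cancer_pct=100.0 * group["cancer_history"].mean(),
            deaths=int(group["death"].sum()),
            deaths_pct=100.0 * group["death"].mean(),
            person_years=group["followup"].sum(),
        )

    rows = [summarize(df, "Total")]
    for cohort, group in df.groupby("cohort", sort=True):
        rows.append(summarize(group, str(cohort)))
    return pd.DataFrame(rows)


def _category_table(
    df: pd.DataFrame,
    scheme: CategoryScheme,
    obs_category_fits: list[StageEstimate],
    projections: dict[str, CategoryProjection],
) -> pd.DataFrame:
    cats = io_harmonize.assign_categories(df["x25ohd"], scheme)
    rows = []
    obs_by_label = {e.term: e for e in obs_category_fits}
    for i, label in enumerate(scheme.labels):
        mask = (cats == label).to_numpy()
        sub = df.loc[mask]
        deaths = int(sub["death"].sum())
        py = float(sub["followup"].sum())
        row = dict(
            category=label,
            median_x25ohd=float(sub["x25ohd"].median()) if len(sub) else np.nan,
            n=int(mask.sum()),
            deaths=deaths,
            person_years=py,
            death_rate_per_1000py=association_models.mortality_rate(deaths, py) if py > 0 else np.nan,
        )
        est = obs_by_label.get(label)
        if label == scheme.reference_label:
            row.update(obs_hr=1.0, obs_ci_low=np.nan, obs_ci_high=np.nan)
        elif est is None:  # empty category: no fitted contrast
            row.update(obs_hr=np.nan, obs_ci_low=np.nan, obs_ci_high=np.nan)
        else:
            row.update(obs_hr=est.hr, obs_ci_low=est.hr_ci[0], obs_ci_high=est.hr_ci[1])
        for name, proj in projections.items():
            row[f"{name}_midpoint_hr"] = proj.hr[i]
            ci = proj.ci[i]
            row[f"{name}_midpoint_ci_low"] = np.nan if ci is None else ci[0]
            row[f"{name}_midpoint_ci_high"] = np.nan if ci is None else ci[1]
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis described in the module docstring."""
    config.validate()
    log: list[str] = [
        f"mode={config.mode} seed={config.seed} k={config.k:g} "
        f"scores={'/'.join(s.name for s in config.scores)}"
    ]

    stage = "input"
    try:
        if config.mode == "simulate":
            sim = dataclasses.replace(config.sim, seed=config.seed)
            table = io_harmonize.validate_participants(simulate_cohort(sim))
            log.append(f"simulated {len(table)} participants in {len(sim.cohorts)} cohorts")
        else:
            table = io_harmonize.read_participants(config.participants, genotype_vcf=config.vcf)
            if config.vcf is not None and config.orientation:
                alleles = table.attrs.get("vcf_alleles", {})
                geno = allele_scores.orient_alleles(table[list(alleles)], alleles, config.orientation)
                table[list(alleles)] = geno
            log.append(f"read {len(table)} participants from {config.participants}")

        stage = "harmonize"
        trunc = io_harmonize.truncate_range(table)
        log.append(trunc.summary())
        data = allele_scores.add_scores(trunc.kept, config.scores)
        incomplete = io_harmonize.flag_incomplete(data)
        if incomplete.any():
            log.append(f"{int(incomplete.sum())} rows incomplete on the adjustment set; "
                       "dropped from model fits, retained in descriptive output")
        model_data = data.loc[~incomplete]

        # observed per-bin medians drive the midpoint projections
        cats = io_harmonize.assign_categories(model_data["x25ohd"], config.scheme)
        medians = tuple(
            float(model_data.loc[(cats == lab).to_numpy(), "x25ohd"].median())
            for lab in config.scheme.labels
        )
        scheme = dataclasses.replace(config.scheme, medians=medians)

        stage = "stage1"
        stage1: dict[str, tuple[StageEstimate, InstrumentStrength]] = {}
        s1_rows = []
        for rsid in SNP_IDS:
            if rsid in model_data.columns and model_data[rsid].notna().any():
                est, _ = association_models.fit_stage1(model_data, rsid, ("cohort",))
                s1_rows.append(dict(term=rsid, adjustment="study", beta=est.beta,
                                    se=est.se, ci_low=est.ci[0], ci_high=est.ci[1], n=est.n))
        for score in config.scores:
            est_c, _ = association_models.fit_stage1(model_data, score.column, ("cohort",))
            s1_rows.append(dict(term=score.name, adjustment="study", beta=est_c.beta,
                                se=est_c.se, ci_low=est_c.ci[0], ci_high=est_c.ci[1], n=est_c.n))
            est, strength = association_models.fit_stage1(model_data, score.column, config.adjustment)
            stage1[score.name] = (est, strength)
            s1_rows.append(dict(term=score.name, adjustment="full", beta=est.beta,
                                se=est.se, ci_low=est.ci[0], ci_high=est.ci[1], n=est.n))
            log.append(f"stage 1 {score.name}: beta_GX={est.beta:.4g} nmol/L/allele, "
                       f"F={strength.f_statistic:.1f}, partial R2={100 * strength.r2:.2f}%")

        stage = "cox"
        stage2 = {s.name: association_models.fit_cox(model_data, s.column, config.adjustment)
                  for s in config.scores}
        obs20 = association_models.fit_cox(model_data, "x25ohd_per20_decrease", config.adjustment)
        try:
            obs_cats = association_models.fit_cox(model_data, "category", config.adjustment,
                                                  scheme=scheme)
        except RuntimeError as exc:
            # sparse samples can separate on category dummies; the category
            # HR column is then omitted rather than aborting the run
            obs_cats = []
            log.append(f"warning: category Cox model not fitted ({exc}); "
                       "observed category HRs omitted")

        stage = "mr"
        mr: dict[str, MrResult] = {}
        projections: dict[str, CategoryProjection] = {}
        # obs20.beta is already on the per-20-decrease scale; /20 gives per nmol/L
        projections["obs"] = mr_core.project_midpoints(
            obs20.beta / 20.0, scheme, (obs20.ci[0] / 20.0, obs20.ci[1] / 20.0)
        )
        for score in config.scores:
            est, strength = stage1[score.name]
            result = mr_core.wald_ratio_hr(config.k, stage2[score.name], est,
                                           score_used=score.name,
                                           f_statistic=strength.f_statistic)
            mr[score.name] = result
            if result.weak_instrument:
                log.append(f"warning: weak instrument for {score.name} "
                           f"(first-stage F={strength.f_statistic:.1f} < 10)")
            ci_unit = (result.ratio - 1.96 * result.se_ratio,
                       result.ratio + 1.96 * result.se_ratio)
            projections[f"mr_{score.column}"] = mr_core.project_midpoints(
                result.ratio, scheme, ci_unit)
            log.append(result.summary())

        stage = "rates"
        rate_shapes = association_models.fit_rate_shapes(
            model_data, bootstrap_reps=config.rate_bootstrap_reps, seed=config.seed)
        if rate_shapes.p_value is not None:
            log.append(
                f"rate shape: {rate_shapes.preferred} preferred "
                f"(AIC difference {rate_shapes.aic_difference:.1f}, parametric-bootstrap "
                f"p={rate_shapes.p_value:.4g}; bootstrap comparison stands in for an "
                "unspecified non-nested test)")

        stage = "diagnostics"
        balance = interactions = None
        if config.run_diagnostics:
            balance = pd.concat(
                [diagnostics.confounder_balance(model_data, s.column) for s in config.scores],
                ignore_index=True)
            n_flagged = int(balance["flagged"].sum())
            log.append(f"balance report: {n_flagged} of {len(balance)} score-confounder "
                       f"tests flagged at p<{diagnostics.BALANCE_THRESHOLD:.4f}")
            inter_rows = []
            for assoc in ("GX", "XY", "GY"):
                res = diagnostics.sex_interaction(model_data, assoc,
                                                  config.scores[0].column, config.adjustment)
                inter_rows.append(dataclasses.asdict(res))
            interactions = pd.DataFrame(inter_rows)

        stage = "report"
        category_table = _category_table(data, scheme, obs_cats, projections)
        descriptive = _descriptive_table(data)
        return PipelineResult(
            table=data,
            descriptive=descriptive,
            stage1_table=pd.DataFrame(s1_rows),
            stage1=stage1,
            stage2=stage2,
            observational_per20=obs20,
            mr=mr,
            category_table=category_table,
            projections=projections,
            rate_shapes=rate_shapes,
            balance=balance,
            interactions=interactions,
            log=log,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def mr_from_betas(
    k: float,
    beta_gy: float,
    se_gy: float | None,
    beta_gx: float,
    se_gx: float | None,
    score: str = "G1",
    scheme: CategoryScheme = DEFAULT_CATEGORIES,
) -> dict:
    """Coefficient-override entry point: MR worked example from given betas.

    Feeds externally estimated stage coefficients (e.g. published values)
    directly into the Wald ratio, per-allele HR and category midpoint
    projection, without refitting anything.
    """
    result = mr_core.wald_ratio_hr(k, beta_gy, beta_gx, se_gy=se_gy, se_gx=se_gx,
                                   score_used=score)
    hr_allele, ci_allele = mr_core.per_allele_hr(beta_gy, se_gy)
    ci_unit = None
    if result.se_ratio is not None:
        ci_unit = (result.ratio - 1.96 * result.se_ratio,
                   result.ratio + 1.96 * result.se_ratio)
    projection = mr_core.project_midpoints(result.ratio, scheme, ci_unit)
    return {"mr": result, "per_allele_hr": hr_allele, "per_allele_ci": ci_allele,
            "projection": projection}
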