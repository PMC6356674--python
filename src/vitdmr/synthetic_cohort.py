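"""Multi-cohort survival simulator with a genotype -> 25(OH)D -> mortality chain.

The generator emulates the pooled analysis sample of three elderly European
cohorts (AGES, Iceland; LURIC, Germany; Tromso, Norway; 10,501 participants
combined). Per cohort it draws covariates from the published marginal
summaries, Hardy-Weinberg genotypes for the four synthesis-pathway SNPs,
serum 25(OH)D linear in the counted-allele sum (each counted allele lowers
25(OH)D, default -1.33 nmol/L) plus confounder terms and Gaussian noise, and
event times from a proportional-hazards model whose log-hazard is linear in
the 25(OH)D *deficit* and in the confounders. Covariates are mutually
independent within cohort (their joint correlations are not published); no
linkage disequilibrium, population stratification or gene-environment
interaction is generated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io_harmonize import SNP_IDS, season_from_month

#: Centering constants for covariate effects (pooled-sample means), so that
#: `baseline_hazard` is the event rate of an average participant and cohort
#: exposure means stay at their configured values.
COVARIATE_CENTERS: dict[str, float] = {
    "age": 67.1,
    "bmi": 26.8,
    "sbp": 144.3,
    "sex_male": 0.499,
    "smoker": 0.230,
    "diabetes": 0.141,
    "hypertension": 0.772,
    "cvd_history": 0.229,
    "cancer_history": 0.098,
}

#: 25(OH)D value (nmol/L, pooled mean) at which the baseline hazard applies.
EXPOSURE_REFERENCE = 51.7


@dataclasses.dataclass(frozen=True)
class CohortProfile:
    """Marginal covariate distribution of one cohort."""

    name: str
    n: int
    female_frac: float
    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    sbp_mean: float
    sbp_sd: float
    x25ohd_mean: float
    smoker: float
    diabetes: float
    hypertension: float
    cvd_history: float
    cancer_history: float


#: Published cohort summaries (ages in years, BMI kg/m^2, SBP mmHg, 25(OH)D
#: nmol/L; binary columns are prevalences).
DEFAULT_COHORTS: tuple[CohortProfile, ...] = (
    CohortProfile("AGES", 3172, 0.578, 76.4, 5.5, 27.1, 4.4, 142.5, 20.3, 57.1,
                  0.127, 0.115, 0.807, 0.193, 0.154),
    CohortProfile("LURIC", 2864, 0.302, 62.9, 10.5, 27.4, 4.0, 141.3, 23.6, 42.3,
                  0.189, 0.329, 0.935, 0.471, 0.073),
    CohortProfile("Tromso", 4465, 0.575, 63.2, 7.7, 26.2, 4.2, 147.4, 22.9, 54.0,
                  0.330, 0.040, 0.652, 0.098, 0.075),
)


@dataclasses.dataclass(frozen=True)
class ConfounderEffect:
    """Effect of one covariate on the exposure and on the log-hazard."""

    exposure: float  # nmol/L of 25(OH)D per unit of the covariate
    loghazard: float  # log-hazard per unit of the covariate


#: Default confounding structure: classical mortality risk factors that also
#: depress 25(OH)D (smoking, adiposity, chronic disease). SBP is carried as a
#: pure balance variable.
DEFAULT_CONFOUNDER_EFFECTS: dict[str, ConfounderEffect] = {
    "age": ConfounderEffect(-0.05, 0.085),
    "sex_male": ConfounderEffect(1.0, 0.45),
    "bmi": ConfounderEffect(-0.6, 0.01),
    "sbp": ConfounderEffect(0.0, 0.0),
    "smoker": ConfounderEffect(-4.0, 0.55),
    "diabetes": ConfounderEffect(-2.0, 0.45),
    "hypertension": ConfounderEffect(-1.0, 0.15),
    "cvd_history": ConfounderEffect(-2.0, 0.50),
    "cancer_history": ConfounderEffect(-1.0, 0.40),
}

#: Per-20 nmol/L-decrease hazard ratio of 1.20 expressed per 1 nmol/L.
DEFAULT_CAUSAL_LOGHR = float(np.log(1.20) / 20.0)


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic three-cohort study.

    ``per_allele_effect`` is the change in 25(OH)D (nmol/L) per counted
    allele at every score SNP (negative: counted alleles are
    25(OH)D-lowering). ``causal_loghr_per_nmol`` is the log-hazard increase
    per 1 nmol/L *decrease* in 25(OH)D. ``baseline_hazard`` (events per
    person-year) applies to a participant at the pooled covariate means;
    event times are exponential by default (``weibull_shape=1``) and Weibull
    otherwise. A single root seed drives deterministic per-cohort substreams.
    """

    cohorts: tuple[CohortProfile, ...] = DEFAULT_COHORTS
    snp_freqs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {rsid: 0.4 for rsid in SNP_IDS}
    )
    per_allele_effect: float = -1.33
    exposure_sd: float = 18.0
    exposure_floor: float = 0.5
    causal_loghr_per_nmol: float = DEFAULT_CAUSAL_LOGHR
    baseline_hazard: float = 0.027
    weibull_shape: float = 1.0
    censor_time: float = 15.0
    season_amplitude: float = 0.0  # nmol/L; sinusoidal seasonal 25(OH)D swing
    confounder_effects: Mapping[str, ConfounderEffect] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS)
    )
    seed: int = 0

    def validate(self) -> None:
        for rsid, freq in self.snp_freqs.items():
            if not 0.0 < freq < 1.0:
                raise ValueError(
                    f"counted-allele frequency for {rsid} must be strictly inside (0, 1), got {freq}"
                )
        for cohort in self.cohorts:
            if cohort.n < 1:
                raise ValueError(f"cohort {cohort.name}: n must be positive, got {cohort.n}")
        if self.exposure_sd <= 0:
            raise ValueError("exposure_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.cohorts)

    def scaled(self, n_total: int, seed: int | None = None) -> "SimConfig":
        """Same study, resized: cohort sizes scaled proportionally."""
        factor = n_total / self.n_total
        cohorts = tuple(
            dataclasses.replace(c, n=max(1, round(c.n * factor))) for c in self.cohorts
        )
        return dataclasses.replace(
            self, cohorts=cohorts, seed=self.seed if seed is None else seed
        )

    def with_null_confounding(self) -> "SimConfig":
        """Copy with every covariate -> exposure/hazard coefficient zeroed."""
        effects = {k: ConfounderEffect(0.0, 0.0) for k in self.confounder_effects}
        return dataclasses.replace(self, confounder_effects=effects)

    # -- config-file plumbing -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["cohorts"] = [dataclasses.asdict(c) for c in self.cohorts]
        doc["snp_freqs"] = dict(self.snp_freqs)
        doc["confounder_effects"] = {
            k: [v.exposure, v.loghazard] for k, v in self.confounder_effects.items()
        }
        # keep insertion order: SNP order defines genotype column order
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "cohorts" in doc:
            doc["cohorts"] = tuple(CohortProfile(**c) for c in doc["cohorts"])
        if "confounder_effects" in doc:
            doc["confounder_effects"] = {
                k: ConfounderEffect(*v) for k, v in doc["confounder_effects"].items()
            }
        config = cls(**doc)
        config.validate()
        return config


def simulate_genotypes(
    n: int,
    snp_freqs: Mapping[str, float],
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Hardy-Weinberg genotypes: per SNP, allele count ~ Binomial(2, freq).

    ``snp_freqs`` maps rsid to the counted-allele frequency, which must lie
    strictly inside (0, 1). SNPs are mutually independent (no linkage
    disequilibrium).
    """
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    for rsid, freq in snp_freqs.items():
        if not 0.0 < freq < 1.0:
            raise ValueError(
                f"counted-allele frequency for {rsid} must be strictly inside (0, 1), got {freq}"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = {rsid: rng.binomial(2, freq, size=n) for rsid, freq in snp_freqs.items()}
    return pd.DataFrame(data)


def _simulate_one_cohort(
    cohort: CohortProfile, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = cohort.n
    genotypes = simulate_genotypes(n, config.snp_freqs, rng)
    allele_sum = genotypes.sum(axis=1).to_numpy(float)
    expected_alleles = 2.0 * sum(config.snp_freqs.values())

    age = rng.normal(cohort.age_mean, cohort.age_sd, n)
    male = (rng.random(n) >= cohort.female_frac).astype(int)
    bmi = rng.normal(cohort.bmi_mean, cohort.bmi_sd, n)
    sbp = rng.normal(cohort.sbp_mean, cohort.sbp_sd, n)
    month = rng.integers(1, 13, n)
    covariates = {
        "age": age,
        "sex_male": male.astype(float),
        "bmi": bmi,
        "sbp": sbp,
        "smoker": rng.binomial(1, cohort.smoker, n).astype(float),
        "diabetes": rng.binomial(1, cohort.diabetes, n).astype(float),
        "hypertension": rng.binomial(1, cohort.hypertension, n).astype(float),
        "cvd_history": rng.binomial(1, cohort.cvd_history, n).astype(float),
        "cancer_history": rng.binomial(1, cohort.cancer_history, n).astype(float),
    }

    exposure = np.full(n, cohort.x25ohd_mean)
    exposure += config.per_allele_effect * (allele_sum - expected_alleles)
    log_hazard = np.log(config.baseline_hazard) * np.ones(n)
    for name, effect in config.confounder_effects.items():
        centered = covariates[name] - COVARIATE_CENTERS[name]
        exposure += effect.exposure * centered
        log_hazard += effect.loghazard * centered
    if config.season_amplitude:
        # peak 25(OH)D in late summer (month 8), trough in late winter
        exposure += config.season_amplitude * np.cos(2 * np.pi * (month - 8) / 12.0)
    exposure += rng.normal(0.0, config.exposure_sd, n)
    exposure = np.maximum(exposure, config.exposure_floor)

    log_hazard += config.causal_loghr_per_nmol * (EXPOSURE_REFERENCE - exposure)
    rate = np.exp(log_hazard)
    # survival S(t) = exp(-rate * t^shape): exponential when shape == 1
    event_time = (rng.exponential(1.0, n) / rate) ** (1.0 / config.weibull_shape)
    death = (event_time <= config.censor_time).astype(int)
    followup = np.minimum(event_time, config.censor_time)

    table = pd.DataFrame(
        {
            "id": [f"{cohort.name}_{i:05d}" for i in range(n)],
            "cohort": cohort.name,
            "age": np.round(age, 1),
            "sex": np.where(male == 1, "male", "female"),
            "season": [season_from_month(m) for m in month],
            "bmi": np.round(bmi, 1),
            "sbp": np.round(sbp, 1),
            "smoker": covariates["smoker"].astype(int),
            "diabetes": covariates["diabetes"].astype(int),
            "hypertension": covariates["hypertension"].astype(int),
            "cvd_history": covariates["cvd_history"].astype(int),
            "cancer_history": covariates["cancer_history"].astype(int),
            "x25ohd": np.round(exposure, 2),
            # follow-up recorded at 4 decimals, floored at ~9 hours so that
            # same-day deaths keep a positive duration
            "followup": np.maximum(np.round(followup, 4), 1e-3),
            "death": death,
        }
    )
    return pd.concat([table, genotypes], axis=1)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate the full multi-cohort participant table.

    Deterministic for a fixed root seed: each cohort consumes an independent
    child stream spawned from ``config.seed``, so resizing one cohort leaves
    the others' draws unchanged.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(len(config.cohorts))
    frames = [
        _simulate_one_cohort(cohort, config, np.random.default_rng(stream))
        for cohort, stream in zip(config.cohorts, streams)
    ]
    out = pd.concat(frames, ignore_index=True)
    return out
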