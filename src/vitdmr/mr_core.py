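"""The causal estimator: Wald ratio hazard ratios with delta-method intervals.

With an allele score G as instrument, a first-stage per-allele exposure
effect beta_GX (nmol/L of 25(OH)D per counted allele; negative under the
lowering-allele orientation) and a per-allele log-hazard beta_GY from the
genetic Cox model, the genetically determined hazard ratio of death for a
k nmol/L *decrease* in 25(OH)D is

    HR(k) = exp(k * beta_GY / |beta_GX|).

The standard error of the ratio beta_GY/beta_GX comes from the first-order
delta method,

    SE(ratio) = sqrt( SE(beta_GY)^2 / beta_GX^2
                      + beta_GY^2 * SE(beta_GX)^2 / beta_GX^4 ),

and 95% intervals are symmetric on the log-hazard scale,
exp(k*ratio +/- 1.96*k*SE). A Fieller interval for the ratio is available as
an option (it can be unbounded when the instrument is weak) but the delta
interval is the default. Category "midpoint" projections translate the
per-unit causal log-hazard into a hazard ratio for each 25(OH)D category
versus the reference, evaluated at the observed category medians.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .association_models import StageEstimate, Z95
from .io_harmonize import CategoryScheme, DEFAULT_CATEGORIES

#: Conventional first-stage F threshold below which the instrument is
#: considered weak and the ratio estimate flagged.
WEAK_INSTRUMENT_F = 10.0


@dataclasses.dataclass
class MrResult:
    """Causal hazard ratio for a k nmol/L decrease in 25(OH)D.

    ``ratio`` is the causal log-hazard per 1 nmol/L decrease
    (beta_GY/|beta_GX| under the lowering-allele orientation), ``se_ratio``
    its delta-method standard error (per nmol/L), and ``hr``/``ci`` the
    exponentiated k-unit effect.
    """

    k: float
    ratio: float
    se_ratio: float | None
    hr: float
    ci: tuple[float, float] | None
    score_used: str = ""
    weak_instrument: bool = False

    def summary(self) -> str:
        ci = "" if self.ci is None else f" (95% CI: {self.ci[0]:.2f} to {self.ci[1]:.2f})"
        flag = "  [weak instrument: first-stage F < 10]" if self.weak_instrument else ""
        score = f" [{self.score_used}]" if self.score_used else ""
        return (
            f"Causal HR per {self.k:g} nmol/L decrease in 25(OH)D{score}: "
            f"{self.hr:.2f}{ci}{flag}"
        )


@dataclasses.dataclass
class CategoryProjection:
    """Hazard ratios per 25(OH)D category projected from a per-unit log-HR."""

    labels: tuple[str, ...]
    medians: tuple[float, ...]
    hr: tuple[float, ...]
    ci: tuple[tuple[float, float] | None, ...]
    reference_index: int

    def as_rows(self) -> list[dict]:
        rows = []
        for i, label in enumerate(self.labels):
            rows.append(
                {
                    "category": label,
                    "median": self.medians[i],
                    "hr": self.hr[i],
                    "ci_low": None if self.ci[i] is None else self.ci[i][0],
                    "ci_high": None if self.ci[i] is None else self.ci[i][1],
                    "reference": i == self.reference_index,
                }
            )
        return rows


def delta_se(beta_gy: float, se_gy: float, beta_gx: float, se_gx: float) -> float:
    """Delta-method standard error of the ratio beta_GY/beta_GX.

    First-order Taylor expansion of the ratio in both coefficients; exact in
    the limit se_gx -> 0, where it reduces to se_gy/|beta_gx|.
    """
    if beta_gx == 0:
        raise ValueError("beta_GX = 0: the ratio estimator is undefined")
    if se_gy < 0 or se_gx < 0:
        raise ValueError("standard errors must be non-negative")
    return math.sqrt(se_gy**2 / beta_gx**2 + beta_gy**2 * se_gx**2 / beta_gx**4)


def _as_beta_se(estimate: StageEstimate | float, se: float | None) -> tuple[float, float | None]:
    if isinstance(estimate, StageEstimate):
        return float(estimate.beta), float(estimate.se)
    return float(estimate), (None if se is None else float(se))


def wald_ratio_hr(
    k: float,
    beta_gy: StageEstimate | float,
    beta_gx: StageEstimate | float,
    se_gy: float | None = None,
    se_gx: float | None = None,
    score_used: str = "",
    f_statistic: float | None = None,
    weak_f_floor: float = WEAK_INSTRUMENT_F,
) -> MrResult:
    """Wald-ratio causal HR per k nmol/L decrease in 25(OH)D.

    Accepts :class:`StageEstimate` objects or raw coefficients (with optional
    standard errors). The ratio uses |beta_GX|: counted alleles are oriented
    to lower 25(OH)D, so a positive per-allele log-hazard together with a
    negative per-allele exposure effect yields HR > 1 per decrease. When both
    SEs are available the delta-method interval is attached. A first-stage
    F below ``weak_f_floor`` flags the result as weak-instrument.
    """
    b_gy, s_gy = _as_beta_se(beta_gy, se_gy)
    b_gx, s_gx = _as_beta_se(beta_gx, se_gx)
    if b_gx == 0:
        raise ValueError("beta_GX = 0: the Wald ratio is undefined")
    ratio = b_gy / abs(b_gx)
    hr = math.exp(k * ratio)

    se_ratio: float | None = None
    ci: tuple[float, float] | None = None
    if s_gy is not None and s_gx is not None:
        se_ratio = delta_se(b_gy, s_gy, b_gx, s_gx)
        lo = math.exp(k * ratio - Z95 * abs(k) * se_ratio)
        hi = math.exp(k * ratio + Z95 * abs(k) * se_ratio)
        ci = (min(lo, hi), max(lo, hi))

    weak = f_statistic is not None and f_statistic < weak_f_floor
    return MrResult(k=float(k), ratio=ratio, se_ratio=se_ratio, hr=hr, ci=ci,
                    score_used=score_used, weak_instrument=weak)


def per_allele_hr(
    beta: StageEstimate | float, se: float | None = None
) -> tuple[float, tuple[float, float] | None]:
    """Per-allele hazard ratio exp(beta) with symmetric 95% CI when SE given."""
    b, s = _as_beta_se(beta, se)
    hr = math.exp(b)
    if s is None:
        return hr, None
    return hr, (math.exp(b - Z95 * s), math.exp(b + Z95 * s))


def project_midpoints(
    log_hr_per_unit_decrease: float,
    scheme: CategoryScheme = DEFAULT_CATEGORIES,
    ci_per_unit_decrease: Sequence[float] | None = None,
) -> CategoryProjection:
    """Project a per-nmol/L (decrease) log-HR onto the category medians.

    Assuming linearity on the log-hazard scale, the hazard ratio of category
    c versus the reference is exp((median_ref - median_c) * per-unit log-HR):
    categories below the reference median carry HR > 1 under a harmful
    deficiency effect, categories above it HR < 1. The reference projects to
    exactly 1. Confidence bounds are carried through the same linear map
    (bounds swap when the median lies above the reference).
    """
    if scheme.medians is None:
        raise ValueError("category scheme has no observed medians")
    ref_median = scheme.reference_median
    hrs: list[float] = []
    cis: list[tuple[float, float] | None] = []
    for i, median in enumerate(scheme.medians):
        delta = ref_median - median
        if i == scheme.reference_index:
            hrs.append(1.0)
            cis.append(None)
            continue
        hrs.append(math.exp(delta * log_hr_per_unit_decrease))
        if ci_per_unit_decrease is None:
            cis.append(None)
        else:
            lo, hi = (math.exp(delta * b) for b in ci_per_unit_decrease)
            cis.append((min(lo, hi), max(lo, hi)))
    return CategoryProjection(
        labels=scheme.labels,
        medians=scheme.medians,
        hr=tuple(hrs),
        ci=tuple(cis),
        reference_index=scheme.reference_index,
    )


def fieller_ci(
    beta_gy: float, se_gy: float, beta_gx: float, se_gx: float, z: float = Z95
) -> tuple[float, float] | None:
    """Fieller interval for the ratio beta_GY/beta_GX (optional, not default).

    Solves (beta_GY - rho*beta_GX)^2 = z^2 (se_GY^2 + rho^2 se_GX^2) for rho,
    assuming independent coefficient estimates. Returns ``None`` when the
    interval is unbounded (instrument not significantly non-zero).
    """
    a = beta_gx**2 - z**2 * se_gx**2
    b = -2.0 * beta_gy * beta_gx
    c = beta_gy**2 - z**2 * se_gy**2
    disc = b**2 - 4 * a * c
    if a <= 0 or disc < 0:
        return None
    root = math.sqrt(disc)
    lo, hi = (-b - root) / (2 * a), (-b + root) / (2 * a)
    return (min(lo, hi), max(lo, hi))
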