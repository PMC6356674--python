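"""Reading, validation and harmonization of participant-level cohort data.

The analysis operates on a flat participant table: one row per subject with
cohort label, baseline covariates, VDSP-standardized serum 25-hydroxyvitamin D
(25(OH)D, nmol/L), follow-up time in years, an all-cause death indicator, and
allele counts (0/1/2) for the four vitamin-D synthesis-pathway SNPs. This
module reads and validates such tables (with genotypes either inline or joined
from a minimal VCF), applies the 0-150 nmol/L exposure truncation, assigns the
six standard 25(OH)D categories, and codes season of blood draw from the
calendar month.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# The four instrument SNPs: two in CYP2R1 (25-hydroxylation) and two in
# DHCR7/NADSYN1 (regulation of the vitamin D precursor).
SNP_IDS: tuple[str, ...] = ("rs12794714", "rs10741657", "rs12785878", "rs11234027")
SNP_GENES: dict[str, str] = {
    "rs12794714": "CYP2R1",
    "rs10741657": "CYP2R1",
    "rs12785878": "DHCR7/NADSYN1",
    "rs11234027": "DHCR7/NADSYN1",
}

SEX_LABELS: tuple[str, str] = ("female", "male")
SEASON_LABELS: tuple[str, ...] = ("spring", "summer", "fall", "winter")

BOOL_COLUMNS: tuple[str, ...] = (
    "smoker",
    "diabetes",
    "hypertension",
    "cvd_history",
    "cancer_history",
    "death",
)

#: Covariate adjustment set used by every regression model (cohort enters as
#: the "study" categorical).
ADJUSTMENT_SET: tuple[str, ...] = (
    "cohort",
    "age",
    "sex",
    "season",
    "bmi",
    "smoker",
    "diabetes",
    "hypertension",
    "cvd_history",
    "cancer_history",
)

#: The ten measured potential confounders tested for association with the
#: genetic scores (per cohort): the nine non-study adjustment covariates plus
#: systolic blood pressure.
CONFOUNDER_SET: tuple[str, ...] = (
    "age",
    "sex",
    "season",
    "bmi",
    "sbp",
    "smoker",
    "diabetes",
    "hypertension",
    "cvd_history",
    "cancer_history",
)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "id",
    "cohort",
    "age",
    "sex",
    "season",
    "bmi",
    "smoker",
    "diabetes",
    "hypertension",
    "cvd_history",
    "cancer_history",
    "x25ohd",
    "followup",
    "death",
)

EXPOSURE_MAX = 150.0  # nmol/L; upper truncation bound (closed)


class ParticipantDataError(ValueError):
    """Raised when a participant table fails validation."""


@dataclasses.dataclass(frozen=True)
class CategoryScheme:
    """Ordered 25(OH)D categories covering [0, 150] nmol/L.

    Printed bounds like "30-39.9" are display artifacts of 0.1 nmol/L
    precision; bins are half-open ``[lower, next_lower)`` with the last bin
    closed at 150, so no value in [0, 150] is orphaned.
    """

    edges: tuple[float, ...] = (0.0, 30.0, 40.0, 50.0, 75.0, 100.0, 150.0)
    labels: tuple[str, ...] = (
        "<30",
        "30-39.9",
        "40-49.9",
        "50-74.9",
        "75-99.9",
        "100-150",
    )
    reference_index: int = 4
    medians: tuple[float, ...] = (21.8, 35.7, 45.4, 59.9, 81.3, 108.1)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("labels must have one entry per bin")
        if list(self.edges) != sorted(self.edges) or len(set(self.edges)) != len(self.edges):
            raise ValueError("edges must be strictly increasing")
        if not 0 <= self.reference_index < len(self.labels):
            raise ValueError("reference_index out of range")
        if self.medians is not None and len(self.medians) != len(self.labels):
            raise ValueError("medians must have one entry per bin")

    @property
    def reference_label(self) -> str:
        return self.labels[self.reference_index]

    @property
    def reference_median(self) -> float:
        return self.medians[self.reference_index]


#: Category scheme of the primary analysis, with observed per-bin medians.
DEFAULT_CATEGORIES = CategoryScheme()


def season_from_month(month: int) -> str:
    """Map calendar month (1-12) to meteorological season of blood draw.

    Spring is March-May, summer June-August, fall September-November and
    winter December-February.
    """
    month = int(month)
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if 3 <= month <= 5:
        return "spring"
    if 6 <= month <= 8:
        return "summer"
    if 9 <= month <= 11:
        return "fall"
    return "winter"


def assign_category(x25ohd: float, scheme: CategoryScheme = DEFAULT_CATEGORIES) -> str:
    """Assign a single 25(OH)D value (nmol/L) to its category label.

    The value must already lie in [0, 150]; run :func:`truncate_range` first.
    """
    x = float(x25ohd)
    if not scheme.edges[0] <= x <= scheme.edges[-1]:
        raise ValueError(
            f"25(OH)D value {x} nmol/L outside [{scheme.edges[0]}, {scheme.edges[-1]}]; "
            "apply range truncation before categorization"
        )
    # number of interior edges <= x; x == upper bound falls in the last bin
    idx = int(np.searchsorted(scheme.edges[1:-1], x, side="right"))
    return scheme.labels[idx]


def assign_categories(
    x25ohd: pd.Series | np.ndarray, scheme: CategoryScheme = DEFAULT_CATEGORIES
) -> pd.Series:
    """Vectorized :func:`assign_category`; returns an ordered categorical."""
    x = np.asarray(x25ohd, dtype=float)
    if np.any((x < scheme.edges[0]) | (x > scheme.edges[-1])):
        bad = np.flatnonzero((x < scheme.edges[0]) | (x > scheme.edges[-1]))
        raise ValueError(
            f"{bad.size} 25(OH)D values outside [{scheme.edges[0]}, {scheme.edges[-1]}] "
            f"(first offending positions: {bad[:5].tolist()}); truncate first"
        )
    idx = np.searchsorted(scheme.edges[1:-1], x, side="right")
    labels = pd.Categorical.from_codes(
        idx, categories=list(scheme.labels), ordered=True
    )
    out = pd.Series(labels, name="x25ohd_category")
    if isinstance(x25ohd, pd.Series):
        out.index = x25ohd.index
    return out


@dataclasses.dataclass
class TruncationResult:
    """Outcome of restricting the exposure range to [0, 150] nmol/L."""

    kept: pd.DataFrame
    excluded: pd.DataFrame
    n_excluded: int
    deaths_excluded: int

    def summary(self) -> str:
        return (
            f"Restricted 25(OH)D range to 0-150 nmol/L: omitted "
            f"{self.n_excluded} individuals with {self.deaths_excluded} deaths."
        )


def truncate_range(records: pd.DataFrame) -> TruncationResult:
    """Keep participants with 0 <= 25(OH)D <= 150 nmol/L.

    Values above 150 nmol/L are too sparse to model and are excluded; the
    counts of excluded individuals and excluded deaths are reported.
    Idempotent: truncating a truncated table changes nothing.
    """
    keep = (records["x25ohd"] >= 0.0) & (records["x25ohd"] <= EXPOSURE_MAX)
    kept = records.loc[keep].copy()
    excluded = records.loc[~keep].copy()
    return TruncationResult(
        kept=kept,
        excluded=excluded,
        n_excluded=int((~keep).sum()),
        deaths_excluded=int(excluded["death"].sum()) if len(excluded) else 0,
    )


def _check(condition: pd.Series, message: str, errors: list[str]) -> None:
    if condition.any():
        rows = condition[condition].index.tolist()
        shown = ", ".join(map(str, rows[:10]))
        more = "" if len(rows) <= 10 else f" (+{len(rows) - 10} more)"
        errors.append(f"{message}: rows {shown}{more}")


def validate_participants(df: pd.DataFrame, require_genotypes: bool = False) -> pd.DataFrame:
    """Type and range-check a participant table; returns a typed copy.

    Raises :class:`ParticipantDataError` listing every offending row. Missing
    genotype entries are allowed (scores are simply undefined for those
    participants) unless ``require_genotypes``.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParticipantDataError(f"missing required columns: {missing_cols}")

    out = df.copy()
    errors: list[str] = []

    out["id"] = out["id"].astype(str)
    if out["id"].duplicated().any():
        dup = out.loc[out["id"].duplicated(), "id"].tolist()[:5]
        errors.append(f"duplicate participant ids: {dup}")

    out["sex"] = out["sex"].astype(str).str.lower()
    _check(~out["sex"].isin(SEX_LABELS), f"sex not in {SEX_LABELS}", errors)
    season = out["season"].astype(str).str.lower().replace({"autumn": "fall"})
    out["season"] = season
    _check(~season.isin(SEASON_LABELS), f"unknown season label (expected {SEASON_LABELS})", errors)

    for col in ("age", "bmi", "x25ohd", "followup"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    _check(out["followup"].isna() | (out["followup"] < 0), "negative or missing follow-up", errors)
    _check(out["x25ohd"] < 0, "negative 25(OH)D", errors)

    for col in BOOL_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        _check(~vals.isin([0, 1]), f"{col} must be 0/1", errors)
        out[col] = vals.astype("Int64")

    for rsid in SNP_IDS:
        if rsid in out.columns:
            vals = pd.to_numeric(out[rsid], errors="coerce")
            _check(vals.notna() & ~vals.isin([0, 1, 2]), f"{rsid} allele count not in 0/1/2", errors)
            out[rsid] = vals.astype("Int64")
        elif require_genotypes:
            errors.append(f"genotype column {rsid} absent")

    if errors:
        raise ParticipantDataError("participant table failed validation: " + "; ".join(errors))

    out["death"] = out["death"].astype(int)
    for col in ("smoker", "diabetes", "hypertension", "cvd_history", "cancer_history"):
        out[col] = out[col].astype(int)
    return out


def flag_incomplete(df: pd.DataFrame, variables: Sequence[str] = ADJUSTMENT_SET) -> pd.Series:
    """Flag rows missing any adjustment-set variable (complete-case policy).

    Flagged rows are dropped from model fits but retained in descriptive
    output.
    """
    return df[list(variables)].isna().any(axis=1)


def read_participants(
    path: str | Path | io.TextIOBase,
    genotype_vcf: str | Path | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read and validate a delimited participant table.

    ``sep=None`` sniffs tab vs comma from the header line. When
    ``genotype_vcf`` is given, per-SNP ALT-allele counts are joined on
    participant id (VCF sample names); allele orientation is applied
    downstream by :mod:`vitdmr.allele_scores`.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df = validate_participants(df)
    if genotype_vcf is not None:
        geno, alleles = read_genotypes_vcf(genotype_vcf)
        df = df.merge(geno, left_on="id", right_index=True, how="left")
        df.attrs["vcf_alleles"] = alleles
        df = validate_participants(df)
    return df


def read_genotypes_vcf(path: str | Path) -> tuple[pd.DataFrame, dict[str, tuple[str, str]]]:
    """Read ALT-allele counts for the score SNPs from a minimal VCF.

    Only the GT field is used. Returns ``(counts, alleles)`` where ``counts``
    is indexed by sample id with one column per rsid (ALT-allele dosage,
    missing where any allele is uncalled) and ``alleles`` maps rsid to its
    (REF, ALT) pair for downstream orientation. Multi-allelic records are
    rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    counts: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in SNP_IDS:
            continue
        if len(variant.ALT) != 1:
            raise ParticipantDataError(f"{rsid}: multi-allelic records are not supported")
        dosage = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            a = gt[:-1]  # last entry is the phasing flag
            if any(al < 0 for al in a):
                continue
            dosage[i] = sum(1 for al in a if al > 0)
        counts[rsid] = dosage
        alleles[rsid] = (variant.REF, variant.ALT[0])
    vcf.close()
    if not counts:
        raise ParticipantDataError(f"no score SNPs ({SNP_IDS}) found in {path}")
    geno = pd.DataFrame(counts, index=pd.Index(samples, name="id"))
    return geno, alleles


def write_participants(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a participant table as delimited UTF-8 text (documented header)."""
    df.to_csv(path, sep=sep, index=False)


def write_vcf(
    genotypes: pd.DataFrame,
    path: str | Path,
    alleles: dict[str, tuple[str, str]] | None = None,
) -> None:
    """Write genotypes as a minimal GT-only VCF (one record per SNP).

    ``genotypes`` holds allele counts 0/1/2 (columns = rsids, index = sample
    ids). ``alleles`` optionally gives (REF, ALT) per rsid; by default the
    counted allele is written as ALT, so dosages round-trip unchanged.
    """
    rsids = [c for c in genotypes.columns if c in SNP_IDS]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(map(str, genotypes.index)),
    ]
    for pos, rsid in enumerate(rsids, start=1):
        ref, alt = (alleles or {}).get(rsid, ("A", "G"))
        gts = [
            gt_map[int(v)] if pd.notna(v) else "./."
            for v in genotypes[rsid]
        ]
        chrom = "11"  # all four score SNPs are on chromosome 11
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
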