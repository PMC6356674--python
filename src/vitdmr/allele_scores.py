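"""Unweighted allele-count instruments for 25(OH)D.

Two allelic scores serve as instrumental variables. G1 counts the
25(OH)D-lowering alleles of rs12794714 (CYP2R1) and rs12785878
(DHCR7/NADSYN1), the two variants with the strongest exposure association.
G2 adds rs11234027 (DHCR7/NADSYN1) and rs10741657 (CYP2R1), mirroring the
four-SNP synthesis-pathway score used in the Copenhagen MR study design.
Scores are plain sums of counted alleles; per-SNP weighting is available but
off by default. Which nucleotide is counted is declared in configuration
(oriented so each counted allele lowers 25(OH)D), never inferred from the
sample, keeping the instrument independent of the data.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_harmonize import SNP_GENES, SNP_IDS


@dataclasses.dataclass(frozen=True)
class SnpDefinition:
    """A score SNP: identifier, gene, and the counted (lowering) allele note."""

    rsid: str
    gene: str


@dataclasses.dataclass(frozen=True)
class ScoreDefinition:
    """An unweighted allele-count score over a fixed SNP set."""

    name: str
    snps: tuple[str, ...]
    weights: tuple[float, ...] | None = None  # optional per-SNP weights

    def __post_init__(self) -> None:
        unknown = [s for s in self.snps if s not in SNP_IDS]
        if unknown:
            raise ValueError(f"unknown SNPs in score {self.name}: {unknown}")
        if self.weights is not None and len(self.weights) != len(self.snps):
            raise ValueError("weights must match the SNP list length")

    @property
    def max_score(self) -> int:
        return 2 * len(self.snps)

    @property
    def column(self) -> str:
        return self.name.lower()


#: Two-SNP score: strongest exposure association, available in all cohorts.
G1 = ScoreDefinition("G1", ("rs12794714", "rs12785878"))
#: Four-SNP score over both synthesis-pathway genes.
G2 = ScoreDefinition("G2", ("rs12785878", "rs11234027", "rs12794714", "rs10741657"))

SCORES: dict[str, ScoreDefinition] = {"G1": G1, "G2": G2}


def compute_score(
    genotypes: pd.DataFrame | Mapping[str, float],
    definition: ScoreDefinition,
) -> pd.Series | float:
    """Sum counted-allele counts for one score.

    Participants missing any SNP of the definition get a missing score (never
    silently zero), so they drop out of that score's analyses only.
    """
    if isinstance(genotypes, Mapping) and not isinstance(genotypes, pd.DataFrame):
        vals = [genotypes.get(rsid) for rsid in definition.snps]
        if any(v is None or pd.isna(v) for v in vals):
            return float("nan")
        w = definition.weights or (1.0,) * len(vals)
        total = float(sum(wi * vi for wi, vi in zip(w, vals)))
        return total if definition.weights else float(int(total))

    missing_cols = [s for s in definition.snps if s not in genotypes.columns]
    if missing_cols:
        raise ValueError(f"genotype columns absent for score {definition.name}: {missing_cols}")
    block = genotypes[list(definition.snps)].astype(float)
    w = np.asarray(definition.weights) if definition.weights else np.ones(len(definition.snps))
    score = block.mul(w, axis=1).sum(axis=1, skipna=False)
    score.name = definition.column
    return score


def add_scores(
    df: pd.DataFrame, definitions: Sequence[ScoreDefinition] = (G1, G2)
) -> pd.DataFrame:
    """Append one score column per definition (g1, g2) to the table."""
    out = df.copy()
    for definition in definitions:
        out[definition.column] = compute_score(df, definition)
    return out


def orient_alleles(
    alt_counts: pd.DataFrame,
    vcf_alleles: Mapping[str, tuple[str, str]],
    orientation: Mapping[str, str],
) -> pd.DataFrame:
    """Convert ALT-allele dosages into counted-allele counts.

    ``orientation`` names the counted (25(OH)D-lowering) nucleotide per rsid.
    Counts are flipped (2 - count) where the counted allele is the VCF REF
    allele; heterozygotes are invariant under the flip.
    """
    out = alt_counts.copy()
    for rsid in alt_counts.columns:
        if rsid not in SNP_IDS:
            continue
        if rsid not in orientation:
            raise ValueError(f"no counted-allele orientation declared for {rsid}")
        if rsid not in vcf_alleles:
            raise ValueError(f"no REF/ALT alleles known for {rsid}")
        ref, alt = vcf_alleles[rsid]
        counted = orientation[rsid].upper()
        if counted == alt.upper():
            pass
        elif counted == ref.upper():
            out[rsid] = 2 - out[rsid]
        else:
            raise ValueError(
                f"{rsid}: counted allele {counted!r} is neither REF ({ref}) nor ALT ({alt})"
            )
    return out


def default_snp_definitions() -> list[SnpDefinition]:
    return [SnpDefinition(rsid, SNP_GENES[rsid]) for rsid in SNP_IDS]
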