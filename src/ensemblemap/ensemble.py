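"""Gene-level integration of GWAS and TWAS by Fisher's combined test.

The top fraction (default 10%) of most-associated SNPs from the mixed-model
GWAS are each assigned to their nearest gene; per gene the smallest assigned
SNP p becomes the gene-level GWAS p (genes untouched by a top SNP get p = 1,
mirroring the P = 1 rule for genes absent from TWAS).  Gene-level GWAS and
TWAS p-values are combined with the sumlog statistic
X = -2 (ln p_gwas + ln p_twas), referred to chi-square with 4 degrees of
freedom; for df = 4 the upper tail has the closed form e^(-X/2) (1 + X/2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneModel
from .gwas import SnpAssocRecord
from .twas import TwasRecord

log = logging.getLogger(__name__)

P_FLOOR = 1e-300

__all__ = [
    "GeneGwasRecord",
    "CombinedRecord",
    "assign_snp_to_nearest_gene",
    "select_top_fraction",
    "gene_level_gwas_p",
    "fisher_combine",
    "combine_pipeline",
    "combined_to_frame",
    "manhattan_frame",
]


@dataclass(frozen=True)
class GeneGwasRecord:
    gene_id: str
    best_snp_id: str
    distance: int  # bp, 0 if the SNP lies inside the gene
    p: float

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.gene_id}: p outside (0, 1]")


@dataclass(frozen=True)
class CombinedRecord:
    gene_id: str
    trait: str
    p_gwas: float
    p_twas: float
    statistic: float
    p_combined: float
    method: str  # FisherGWASTWAS | FisherGWASmultiTWAS

    def __post_init__(self) -> None:
        expect = -2.0 * (math.log(self.p_gwas) + math.log(self.p_twas))
        if abs(self.statistic - expect) > 1e-10:
            raise ValueError("fisher statistic inconsistent with input p-values")
        if not (0.0 < self.p_combined <= 1.0):
            raise ValueError("combined p outside (0, 1]")


def assign_snp_to_nearest_gene(
    chromosome: str, position: int, genes: list[GeneModel]
) -> tuple[str | None, int]:
    """Nearest gene on the same chromosome and the bp gap to its interval.

    Ties are broken by smaller start, then lexicographic gene id.  Returns
    (None, -1) when the chromosome has no genes (logged).
    """
    best = None
    for g in genes:
        if g.chromosome != chromosome:
            continue
        d = g.distance_to(position)
        key = (d, g.start, g.id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is None:
        log.warning("assign_snp_to_nearest_gene: no genes on chromosome %s", chromosome)
        return None, -1
    return best[1].id, best[0][0]


def select_top_fraction(
    records: list[SnpAssocRecord], fraction: float = 0.10
) -> list[SnpAssocRecord]:
    """The ceil(fraction * n) records with smallest p (stable on (p, id))."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not records:
        return []
    k = math.ceil(fraction * len(records))
    return sorted(records, key=lambda r: (r.p, r.variant_id))[:k]


def gene_level_gwas_p(
    top_records: list[SnpAssocRecord], genes: list[GeneModel]
) -> list[GeneGwasRecord]:
    """Per gene hit by >= 1 assigned top SNP, the minimum assigned SNP p."""
    best: dict[str, tuple[float, str, int]] = {}
    for r in top_records:
        gid, dist = assign_snp_to_nearest_gene(r.chromosome, r.position, genes)
        if gid is None:
            continue
        cur = best.get(gid)
        if cur is None or r.p < cur[0]:
            best[gid] = (r.p, r.variant_id, dist)
    return [
        GeneGwasRecord(gene_id=g, best_snp_id=s, distance=d, p=p)
        for g, (p, s, d) in sorted(best.items())
    ]


def fisher_combine(p_gwas: float, p_twas: float, trait: str = "",
                   gene_id: str = "", method: str = "FisherGWASTWAS") -> CombinedRecord:
    """Fisher's (sumlog) combination of two p-values against chi-square df 4."""
    for name, p in (("p_gwas", p_gwas), ("p_twas", p_twas)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name} = {p} outside (0, 1]")
    X = -2.0 * (math.log(p_gwas) + math.log(p_twas))
    # upper tail of chi-square with 4 df in closed form
    p_comb = math.exp(-X / 2.0) * (1.0 + X / 2.0)
    p_comb = min(max(p_comb, P_FLOOR), 1.0)
    return CombinedRecord(gene_id, trait, p_gwas, p_twas, X, p_comb, method)


def combine_pipeline(
    gwas_records: list[SnpAssocRecord],
    twas_records: list[TwasRecord],
    genes: list[GeneModel],
    trait: str,
    mode: str = "single",
    top_fraction: float = 0.10,
) -> list[CombinedRecord]:
    """Full gene-level GWAS+TWAS combination for one trait.

    ``mode`` selects which TWAS records feed the combination ("single" for a
    one-tissue scan, "multi" for the multi-tissue ANOVA p-values); the output
    covers the union of genes hit by a top SNP and genes tested in TWAS,
    with p = 1 imputed on the missing side.
    """
    method = "FisherGWASTWAS" if mode == "single" else "FisherGWASmultiTWAS"
    snp_chroms = {r.chromosome for r in gwas_records}
    gene_chroms = {g.chromosome for g in genes}
    if snp_chroms - gene_chroms:
        raise ValueError(
            f"chromosomes {sorted(snp_chroms - gene_chroms)} have SNPs but no annotation"
        )
    top = select_top_fraction(gwas_records, top_fraction)
    gene_gwas = {r.gene_id: r.p for r in gene_level_gwas_p(top, genes)}
    twas_p: dict[str, float] = {}
    for r in twas_records:
        if r.gene_id in twas_p:
            raise ValueError(f"duplicate TWAS record for gene {r.gene_id}")
        twas_p[r.gene_id] = r.p
    out = []
    for gid in sorted(set(gene_gwas) | set(twas_p)):
        pg = max(gene_gwas.get(gid, 1.0), P_FLOOR)
        pt = max(twas_p.get(gid, 1.0), P_FLOOR)
        out.append(fisher_combine(pg, pt, trait=trait, gene_id=gid, method=method))
    return out


def combined_to_frame(records: list[CombinedRecord]) -> pd.DataFrame:
    p = np.array([r.p_combined for r in records], dtype=float)
    return pd.DataFrame({
        "id": [r.gene_id for r in records],
        "chrom": np.nan,
        "pos_or_interval": np.nan,
        "method": [r.method for r in records],
        "trait": [r.trait for r in records],
        "effect": np.nan,
        "r": np.nan,
        "stat": [r.statistic for r in records],
        "p": p,
        "rank": (np.argsort(np.argsort(p)) + 1) if len(records) else [],
        "p_gwas": [r.p_gwas for r in records],
        "p_twas": [r.p_twas for r in records],
    })


def manhattan_frame(
    gwas_records: list[SnpAssocRecord],
    twas_records: list[TwasRecord],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Per-SNP table for "MLM colored by TWAS significance" rendering:
    (chrom, pos, -log10 p_gwas, -log10 p_twas of the nearest gene)."""
    twas_p = {r.gene_id: r.p for r in twas_records}
    rows = []
    for r in gwas_records:
        gid, _ = assign_snp_to_nearest_gene(r.chromosome, r.position, genes)
        pt = twas_p.get(gid, 1.0) if gid else 1.0
        rows.append((r.chromosome, r.position,
                     -math.log10(max(r.p, P_FLOOR)), -math.log10(max(pt, P_FLOOR))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "neglog10_p_gwas",
                                       "neglog10_p_twas_nearest_gene"])
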