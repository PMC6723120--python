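"""Windowed-kinship REML variance partitioning in the validation population.

For each method and trait, the top genes from the discovery population define
SNP windows (gene interval +/- 0.5 Mb); the union of windows yields a single
local kinship matrix whose explained phenotypic variance is estimated by REML
in an independent NAM-like population — pooled across families and within
each family, with the per-family estimates summed ("summed heritability").

The REML solver maximizes the restricted log-likelihood of
y = mu + g + e, g ~ N(0, sk^2 K), over h2 = sk^2 / (sk^2 + se^2) in [0, 1]
through the eigendecomposition of K and a bounded one-dimensional search.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import GeneModel, GenotypePanel, TraitTable
from .covariates import KinshipMatrix, compute_kinship
from .ensemble import assign_snp_to_nearest_gene
from .gwas import SnpAssocRecord

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetSelection",
    "VarianceComponents",
    "select_top_genes_twas",
    "select_top_genes_gwas",
    "window_snp_set",
    "reml_h2",
    "reml_loglik",
    "partition_by_family",
]


@dataclass
class GeneSetSelection:
    method: str
    trait: str
    genes: list[str]
    excluded: list[str]  # GWAS peak-dedup exclusions


@dataclass
class VarianceComponents:
    sigma2_kinship: float
    sigma2_residual: float
    h2: float
    subset: str  # family id or "all"
    n: int
    converged: bool
    identifiability_flag: bool = False  # likelihood flat in h2 (e.g. K = I)

    def __post_init__(self) -> None:
        if self.sigma2_kinship < 0 or self.sigma2_residual < 0:
            raise ValueError("variance components must be >= 0")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 outside [0, 1]")


def select_top_genes_twas(records: pd.DataFrame, n: int = 10,
                          method: str = "twas", trait: str = "") -> GeneSetSelection:
    """First n genes by ascending p (ties by gene id)."""
    from .evaluation import rank_genes

    ranked = rank_genes(records)
    if len(ranked) < n:
        log.warning("select_top_genes: only %d genes available (< %d)", len(ranked), n)
    return GeneSetSelection(method, trait, ranked[:n], [])


def select_top_genes_gwas(
    snp_records: list[SnpAssocRecord],
    genes: list[GeneModel],
    n: int = 10,
    dedup_radius: int = 500_000,
    trait: str = "",
) -> GeneSetSelection:
    """Top unique nearest genes of the most-associated SNPs with peak dedup.

    SNPs are walked in ascending p; a candidate gene is accepted unless it
    was already accepted or lies within ``dedup_radius`` (interval gap, same
    chromosome) of an accepted gene, in which case it is excluded — one gene
    per Manhattan peak.
    """
    by_id = {g.id: g for g in genes}
    accepted: list[str] = []
    excluded: list[str] = []
    for rec in sorted(snp_records, key=lambda r: (r.p, r.variant_id)):
        if len(accepted) >= n:
            break
        gid, _ = assign_snp_to_nearest_gene(rec.chromosome, rec.position, genes)
        if gid is None or gid in accepted or gid in excluded:
            continue
        g = by_id[gid]
        clash = False
        for aid in accepted:
            a = by_id[aid]
            if a.chromosome != g.chromosome:
                continue
            gap = max(a.start - g.end, g.start - a.end, 0)
            if gap <= dedup_radius:
                clash = True
                break
        if clash:
            excluded.append(gid)
        else:
            accepted.append(gid)
    if len(accepted) < n:
        log.warning("select_top_genes_gwas: SNPs exhausted with %d/%d genes", len(accepted), n)
    return GeneSetSelection("gwas", trait, accepted, excluded)


def window_snp_set(gene: GeneModel, panel: GenotypePanel, radius: int = 500_000) -> set[str]:
    """Variant ids within [start - radius, end + radius] on the gene's
    chromosome (clipped at 1; boundaries inclusive)."""
    lo = max(gene.start - radius, 1)
    hi = gene.end + radius
    v = panel.variants
    mask = (v["chrom"] == gene.chromosome) & (v["pos"] >= lo) & (v["pos"] <= hi)
    ids = set(v.loc[mask, "id"])
    if not ids:
        log.warning("window_snp_set: gene %s contributes no SNPs", gene.id)
    return ids


def reml_loglik(y: np.ndarray, K: np.ndarray, h2: float) -> float:
    """Restricted log-likelihood (up to an additive constant) at a given h2.

    Total variance is profiled out; the fixed effect is the intercept.
    Dense formulation usable as an independent check of :func:`reml_h2`.
    """
    n = y.shape[0]
    V = h2 * K + (1.0 - h2) * np.eye(n)
    sign, logdet_V = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    X = np.ones((n, 1))
    XtViX = float((X.T @ Vi @ X).item())
    beta = float((X.T @ Vi @ y).item()) / XtViX
    r = y - beta
    rss = float(r @ Vi @ r)
    df = n - 1
    s2 = rss / df
    return -0.5 * (df * math.log(s2) + logdet_V + math.log(XtViX) + df)


def _neg_ll_rotated(h2: float, S: np.ndarray, ys: np.ndarray, ones_s: np.ndarray) -> float:
    w = 1.0 / (h2 * S + (1.0 - h2))
    xwx = float(np.sum(w * ones_s * ones_s))
    beta = float(np.sum(w * ones_s * ys)) / xwx
    r = ys - beta * ones_s
    rss = float(np.sum(w * r * r))
    n = S.shape[0]
    df = n - 1
    s2 = rss / df
    ll = -0.5 * (df * math.log(s2) + np.sum(np.log(h2 * S + (1.0 - h2))) + math.log(xwx) + df)
    return -ll


def reml_h2(trait: TraitTable, kinship: KinshipMatrix, tol: float = 1e-6) -> VarianceComponents:
    """REML estimate of the variance explained by one kinship matrix."""
    obs = trait.observed()
    ids = [i for i in kinship.individuals if i in obs.index]
    if len(ids) < 30:
        raise ValueError(f"reml_h2: only {len(ids)} individuals (< 30)")
    y = obs.reindex(ids).to_numpy(dtype=float)
    K = kinship.subset(ids).values
    S, U = np.linalg.eigh(K)
    if S[0] < -1e-8:
        raise ValueError(f"kinship not PSD (min eigenvalue {S[0]:.3g})")
    S = np.clip(S, 0.0, None)
    ys = U.T @ y
    ones_s = U.T @ np.ones_like(y)
    eps = 1e-9
    res = optimize.minimize_scalar(
        _neg_ll_rotated, bounds=(eps, 1.0 - eps), method="bounded",
        args=(S, ys, ones_s), options={"xatol": tol * 1e-2},
    )
    cands = [(float(res.x), -_neg_ll_rotated(float(res.x), S, ys, ones_s))]
    for b in (eps, 1.0 - eps):
        cands.append((b, -_neg_ll_rotated(b, S, ys, ones_s)))
    h2, ll = max(cands, key=lambda t: t[1])
    h2 = min(max(h2, 0.0), 1.0)
    if h2 <= 2 * eps:
        h2 = 0.0
    elif h2 >= 1.0 - 2 * eps:
        h2 = 1.0
    # flat-likelihood detection (components not separately identifiable, K ~ I)
    grid = np.linspace(0.05, 0.95, 7)
    lls = np.array([-_neg_ll_rotated(g, S, ys, ones_s) for g in grid])
    flat = bool(lls.max() - lls.min() < 1e-7)
    converged = bool(res.success)
    h2_eval = min(max(h2, eps), 1.0 - eps)
    w = 1.0 / (h2_eval * S + (1.0 - h2_eval))
    xwx = float(np.sum(w * ones_s ** 2))
    beta = float(np.sum(w * ones_s * ys)) / xwx
    r = ys - beta * ones_s
    s2 = float(np.sum(w * r * r)) / (len(y) - 1)
    return VarianceComponents(
        sigma2_kinship=h2 * s2,
        sigma2_residual=(1.0 - h2) * s2,
        h2=float(h2),
        subset="all",
        n=len(y),
        converged=converged,
        identifiability_flag=flat,
    )


def partition_by_family(
    trait: TraitTable,
    panel: GenotypePanel,
    families: pd.Series,
    gene_set: list[GeneModel],
    radius: int = 500_000,
    min_family_n: int = 30,
) -> tuple[list[VarianceComponents], float]:
    """Per-family and pooled windowed-kinship REML, plus summed heritability.

    One kinship per trait is built from the union of the genes' SNP windows;
    within each family the kinship is recomputed from the family subset so
    the centering allele frequencies are family-specific.  Families smaller
    than ``min_family_n`` are skipped with a warning.  Returns the component
    list (one entry per family plus the pooled "all" entry) and the summed
    heritability (sum of per-family h2).
    """
    missing = [i for i in panel.individuals if i not in families.index]
    if missing:
        raise ValueError(f"family label missing for individuals {missing[:5]}")
    snp_ids: set[str] = set()
    for g in gene_set:
        snp_ids |= window_snp_set(g, panel, radius)
    if not snp_ids:
        raise ValueError("gene set contributes no SNPs at this radius")
    results: list[VarianceComponents] = []
    summed = 0.0
    for fam in sorted(families.unique()):
        ids = [i for i in panel.individuals if families[i] == fam]
        if len(ids) < min_family_n:
            log.warning("partition_by_family: family %s has %d individuals (< %d), skipped",
                        fam, len(ids), min_family_n)
            continue
        sub = panel.subset_individuals(ids)
        fam_snps = [s for s in snp_ids if s in set(sub.variants["id"])]
        try:
            k = compute_kinship(sub, variant_subset=fam_snps)
        except ValueError as e:
            log.warning("partition_by_family: family %s skipped (%s)", fam, e)
            continue
        vc = reml_h2(trait, k)
        vc.subset = str(fam)
        results.append(vc)
        summed += vc.h2
    k_all = compute_kinship(panel, variant_subset=sorted(snp_ids))
    vc_all = reml_h2(trait, k_all)
    vc_all.subset = "all"
    results.append(vc_all)
    return results, summed


def genomewide_h2(trait: TraitTable, panel: GenotypePanel) -> VarianceComponents:
    """All-SNP genome-wide heritability of a trait in the panel."""
    return reml_h2(trait, compute_kinship(panel))


def components_to_frame(results: list[VarianceComponents], method: str, trait: str) -> pd.DataFrame:
    return pd.DataFrame({
        "method": method,
        "trait": trait,
        "subset": [r.subset for r in results],
        "n": [r.n for r in results],
        "sigma2_kinship": [r.sigma2_kinship for r in results],
        "sigma2_residual": [r.sigma2_residual for r in results],
        "h2": [r.h2 for r in results],
        "converged": [r.converged for r in results],
    })
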