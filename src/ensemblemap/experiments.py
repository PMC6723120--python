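"""Replicated benchmark experiments over the synthetic generator.

These drivers parameterize the study-condition experiments the package is
validated with: null calibration of all four association tests, the
detection-power ordering of the ensemble versus its component methods, REML
heritability recovery, and the causal-versus-random window discrimination of
the variance-partitioning validator.  They are used by the analysis scripts
and the acceptance machinery alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import KnownGeneList, TraitTable
from .covariates import CovariateSet, compute_kinship, compute_mds_pcs, estimate_hidden_factors
from .ensemble import combine_pipeline, combined_to_frame
from .evaluation import count_detections, rank_genes
from .gwas import genomic_inflation, run_glm_gwas, run_mlm_gwas
from .simulate import (
    SimulationConfig,
    apply_trait_to_panel,
    place_genes,
    simulate_expression,
    simulate_nam_families,
    simulate_panel,
    simulate_trait,
)
from .twas import run_twas_multitissue, run_twas_single, twas_records_to_frame
from .varpart import partition_by_family, reml_h2

__all__ = [
    "null_calibration",
    "power_ordering",
    "reml_recovery",
    "varpart_discrimination",
    "gene_level_tables",
]


def _associate(cfg: SimulationConfig, seed_offset: int):
    """Simulate one panel + expression and prepare covariates/kinship."""
    panel, subpops = simulate_panel(cfg)
    genes = place_genes(cfg)
    tensor, cis, meta = simulate_expression(cfg, panel, genes, subpops)
    K = compute_kinship(panel)
    pcs = compute_mds_pcs(panel, k=5)
    factors = {t: estimate_hidden_factors(tensor.matrix(t), pcs, k=25)
               for t in tensor.tissue_names}
    cov = CovariateSet(panel.individuals, pcs=pcs, factors=factors)
    return panel, subpops, genes, tensor, cis, meta, K, cov


def gene_level_tables(panel, genes, tensor, K, cov, trait,
                      top_snp_fraction: float = 0.10):
    """Per-method gene ranking tables (id, p) for one trait, plus raw records."""
    from .pipeline import _gene_level_frame

    mlm = run_mlm_gwas(panel, trait, K)
    single = run_twas_single(tensor, "kernel", trait, cov)
    comb = combine_pipeline(mlm, single, genes, trait.name,
                            top_fraction=top_snp_fraction)
    tables = {
        "gwas_mlm": _gene_level_frame(mlm, genes, top_snp_fraction),
        "twas_single": twas_records_to_frame(single)[["id", "p"]],
        "FisherGWASTWAS": combined_to_frame(comb)[["id", "p"]],
    }
    return tables, {"mlm": mlm, "single": single, "comb": comb}


# ---------------------------------------------------------------------------
# null calibration (type-I error and genomic inflation)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    rejection_rates: dict[str, float]
    n_tests: dict[str, int]
    lambda_glm_structured: float
    lambda_mlm_structured: float


def null_calibration(seed: int, n_seeds: int = 20, n_panel: int = 300,
                     n_variants: int = 2000, n_genes: int = 200,
                     alpha: float = 0.05) -> CalibrationResult:
    """Type-I error of GLM / MLM / single- and multi-tissue TWAS on null
    traits, and the GLM-vs-MLM inflation contrast on structured null traits.

    The null trait is pure Gaussian noise; the structured trait adds a
    subpopulation mean shift, which inflates the naive GLM but not the
    kinship-aware mixed model.
    """
    hits: dict[str, list[bool]] = {"glm": [], "mlm": [], "twas_single": [], "twas_multi": []}
    lam_glm, lam_mlm = [], []
    for s in range(n_seeds):
        cfg = SimulationConfig(seed=seed + s, n_panel=n_panel, n_variants=n_variants,
                               n_genes=n_genes, n_causal_regulatory=0,
                               n_causal_coding=0, h2_target=0.0)
        panel, subpops, genes, tensor, cis, meta, K, cov = _associate(cfg, s)
        trait, _ = simulate_trait(cfg, panel, genes, cis, meta, subpops=subpops)
        hits["glm"] += [r.p < alpha for r in run_glm_gwas(panel, trait)]
        hits["mlm"] += [r.p < alpha for r in run_mlm_gwas(panel, trait, K)]
        hits["twas_single"] += [r.p < alpha
                                for r in run_twas_single(tensor, "kernel", trait, cov)]
        hits["twas_multi"] += [r.p < alpha
                               for r in run_twas_multitissue(tensor, trait, cov,
                                                             min_n_warn=0)]
        rng = np.random.default_rng(np.random.SeedSequence((seed + s, 77)))
        codes = (subpops == subpops.unique()[-1]).astype(float).to_numpy()
        y = codes + rng.normal(scale=0.7, size=len(codes))
        structured = TraitTable("null_structured",
                                pd.Series(y, index=panel.individuals))
        lam_glm.append(genomic_inflation(run_glm_gwas(panel, structured)))
        lam_mlm.append(genomic_inflation(run_mlm_gwas(panel, structured, K)))
    return CalibrationResult(
        rejection_rates={k: float(np.mean(v)) for k, v in hits.items()},
        n_tests={k: len(v) for k, v in hits.items()},
        lambda_glm_structured=float(np.mean(lam_glm)),
        lambda_mlm_structured=float(np.mean(lam_mlm)),
    )


# ---------------------------------------------------------------------------
# detection-power ordering (Tables 1-2 analogue)
# ---------------------------------------------------------------------------

@dataclass
class PowerResult:
    per_replicate: pd.DataFrame  # columns: replicate, gwas, twas, fisher, twas_only_regulatory
    n_traits: int

    @property
    def fisher_ge_gwas_fraction(self) -> float:
        d = self.per_replicate
        return float((d["fisher"] >= d["gwas"]).mean())

    @property
    def fisher_ge_twas_fraction(self) -> float:
        d = self.per_replicate
        return float((d["fisher"] >= d["twas"]).mean())

    @property
    def twas_only_regulatory_total(self) -> int:
        return int(self.per_replicate["twas_only_regulatory"].sum())


def power_ordering(seed: int, n_replicates: int = 10, n_traits: int = 20,
                   h2: float = 0.6, n_causal_regulatory: int = 5,
                   n_causal_coding: int = 5,
                   detection_fraction: float = 0.01) -> PowerResult:
    """Mean top-1% causal-gene detections per method over replicate trait sets.

    Each replicate simulates a fresh panel/expression dataset and ``n_traits``
    traits with the given causal architecture, then counts causal genes
    recovered in the top 1% of each method's gene ranking.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = SimulationConfig(seed=seed + 1000 * rep, h2_target=h2,
                               n_causal_regulatory=n_causal_regulatory,
                               n_causal_coding=n_causal_coding)
        panel, subpops, genes, tensor, cis, meta, K, cov = _associate(cfg, rep)
        det = {"gwas": 0, "twas": 0, "fisher": 0}
        twas_only_reg = 0
        for t in range(n_traits):
            trait, truth = simulate_trait(cfg, panel, genes, cis, meta,
                                          subpops=subpops, stream=500 + t)
            known = KnownGeneList("causal", set(truth.causal_genes["gene"]))
            regulatory = set(truth.causal_genes.query("mechanism == 'regulatory'")["gene"])
            tables, _ = gene_level_tables(panel, genes, tensor, K, cov, trait)
            d_g = count_detections(rank_genes(tables["gwas_mlm"]), known, detection_fraction)
            d_t = count_detections(rank_genes(tables["twas_single"]), known, detection_fraction)
            d_c = count_detections(rank_genes(tables["FisherGWASTWAS"]), known, detection_fraction)
            det["gwas"] += len(d_g)
            det["twas"] += len(d_t)
            det["fisher"] += len(d_c)
            twas_only_reg += len((d_t & regulatory) - d_g)
        rows.append({"replicate": rep, **det, "twas_only_regulatory": twas_only_reg})
    return PowerResult(pd.DataFrame(rows), n_traits)


# ---------------------------------------------------------------------------
# REML recovery
# ---------------------------------------------------------------------------

def reml_recovery(seed: int, n_seeds: int = 20, n: int = 500,
                  h2_levels=(0.2, 0.5, 0.8)) -> pd.DataFrame:
    """Mean REML h2 estimate for traits drawn from a known kinship.

    y = sqrt(h2) L z1 + sqrt(1 - h2) z2 with L the Cholesky factor of the
    panel kinship, so the generating covariance is exactly the model the
    solver fits.
    """
    cfg = SimulationConfig(seed=seed, n_panel=n, n_variants=1500, n_genes=100)
    panel, _ = simulate_panel(cfg)
    K = compute_kinship(panel)
    L = np.linalg.cholesky(K.values + 1e-8 * np.eye(n))
    rows = []
    for h2 in h2_levels:
        ests = []
        for s in range(n_seeds):
            rng = np.random.default_rng(np.random.SeedSequence((seed, int(h2 * 100), s)))
            y = (np.sqrt(h2) * (L @ rng.normal(size=n))
                 + np.sqrt(1.0 - h2) * rng.normal(size=n))
            trait = TraitTable("t", pd.Series(y, index=panel.individuals))
            ests.append(reml_h2(trait, K).h2)
        rows.append({"h2_true": h2, "h2_mean_estimate": float(np.mean(ests)),
                     "n_seeds": n_seeds})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variance-partition discrimination (Fig 4/5 analogue)
# ---------------------------------------------------------------------------

@dataclass
class DiscriminationResult:
    pooled_wins: int
    summed_wins: int
    n_seeds: int
    mean_pooled_causal: float
    mean_pooled_random: float


def varpart_discrimination(seed: int, n_seeds: int = 50, n_panel: int = 60,
                           n_families: int = 4, n_per_family: int = 100,
                           h2: float = 0.6) -> DiscriminationResult:
    """Causal-gene windows versus random non-causal windows in a NAM-like
    validation population, pooled and per family (summed heritability)."""
    pooled_wins = summed_wins = 0
    pooled_c, pooled_r = [], []
    for s in range(n_seeds):
        cfg = SimulationConfig(seed=seed + s, n_panel=n_panel,
                               n_families=n_families, n_per_family=n_per_family,
                               h2_target=h2)
        panel, subpops = simulate_panel(cfg)
        genes = place_genes(cfg)
        tensor, cis, meta = simulate_expression(cfg, panel, genes, subpops)
        _, truth = simulate_trait(cfg, panel, genes, cis, meta, subpops=subpops)
        nam, fams = simulate_nam_families(cfg, panel)
        y = apply_trait_to_panel(truth, nam, h2, seed=seed + s, name="t")
        causal_ids = set(truth.causal_genes["gene"])
        causal = [g for g in genes if g.id in causal_ids]
        rng = np.random.default_rng(np.random.SeedSequence((seed + s, 3)))
        random_set = list(rng.choice([g for g in genes if g.id not in causal_ids],
                                     size=len(causal), replace=False))
        c_comps, c_sum = partition_by_family(y, nam, fams, causal)
        r_comps, r_sum = partition_by_family(y, nam, fams, random_set)
        c_pool = next(c.h2 for c in c_comps if c.subset == "all")
        r_pool = next(c.h2 for c in r_comps if c.subset == "all")
        pooled_wins += c_pool > r_pool
        summed_wins += c_sum > r_sum
        pooled_c.append(c_pool)
        pooled_r.append(r_pool)
    return DiscriminationResult(pooled_wins, summed_wins, n_seeds,
                                float(np.mean(pooled_c)), float(np.mean(pooled_r)))
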