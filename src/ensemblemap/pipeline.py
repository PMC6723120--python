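"""End-to-end orchestration: simulate, associate, combine, score, partition.

`run_simulate` writes a complete synthetic dataset (genotypes, expression,
traits, annotation, truth) through the I/O layer; `run_full` consumes such a
directory (or any real dataset in the same formats) and writes every result
table plus a machine-readable run manifest.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .containers import GenotypePanel, TraitTable
from .covariates import CovariateSet, compute_kinship, compute_mds_pcs, estimate_hidden_factors, write_matrix_tsv
from .ensemble import combine_pipeline, combined_to_frame, manhattan_frame
from .evaluation import tally_methods, tally_to_frame
from .gwas import records_to_frame, run_glm_gwas, run_mlm_gwas
from .simulate import (
    SimulationConfig,
    apply_trait_to_panel,
    place_genes,
    simulate_expression,
    simulate_nam_families,
    simulate_panel,
    simulate_trait,
    write_truth,
)
from .twas import run_twas_multitissue, run_twas_single, twas_records_to_frame
from .varpart import (
    components_to_frame,
    genomewide_h2,
    partition_by_family,
    select_top_genes_gwas,
    select_top_genes_twas,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline constants; defaults are the study's settings."""

    genotypes: str = ""
    expression_dir: str = ""
    traits: str = ""
    annotation: str = ""
    known_genes: str = ""
    validation_genotypes: str = ""   # NAM-like population, disjoint from discovery
    validation_traits: str = ""
    families: str = ""               # TSV individual -> family for the validation set
    maf_threshold: float = 0.05
    n_pcs: int = 5
    n_factors: int = 25
    top_snp_fraction: float = 0.10
    detection_fraction: float = 0.01
    top_genes: int = 10
    window_radius: int = 500_000
    seed: int = 1
    primary_tissue: str = "kernel"
    run_glm: bool = True
    run_varpart: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "top_snp_fraction", "detection_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} = {v} outside (0, 1]")
        if self.window_radius <= 0:
            raise ValueError("window_radius must be > 0")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_simulate(config: SimulationConfig, out_dir, n_traits: int = 1) -> Path:
    """Generate and write a full synthetic dataset directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, subpops = simulate_panel(config)
    genes = place_genes(config)
    tensor, cis, meta = simulate_expression(config, panel, genes, subpops)
    traits, truths = [], []
    for t in range(n_traits):
        trait, truth = simulate_trait(config, panel, genes, cis, meta,
                                      name=f"trait{t + 1}", subpops=subpops,
                                      stream=100 + t)
        traits.append(trait)
        truths.append(truth)
    nam, families = simulate_nam_families(config, panel)
    nam_traits = [
        apply_trait_to_panel(truth, nam, config.h2_target, seed=config.seed + t,
                             name=trait.name)
        for t, (trait, truth) in enumerate(zip(traits, truths))
    ]
    io.write_traits(nam_traits, out / "nam_traits.tsv")
    io.write_vcf(panel, out / "panel.vcf")
    io.write_dosage_tsv(panel, out / "panel_dosages.tsv")
    io.write_dosage_tsv(nam, out / "nam_dosages.tsv")
    io.write_annotation(genes, out / "genes.gff3")
    io.write_expression(tensor, out / "expression")
    io.write_traits(traits, out / "traits.tsv")
    subpops.to_frame().to_csv(out / "subpopulations.tsv", sep="\t")
    families.to_frame().to_csv(out / "families.tsv", sep="\t")
    rows = []
    for trait, truth in zip(traits, truths):
        df = truth.causal_genes.copy()
        df.insert(0, "trait", trait.name)
        df["realized_h2"] = truth.realized_h2
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest = {"config": config.to_dict(), "n_traits": n_traits,
                "stage": "simulate"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def run_full(config: PipelineConfig, out_dir) -> Path:
    """Run the full analysis over an on-disk dataset directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for field_name in ("genotypes", "traits", "annotation"):
        p = getattr(config, field_name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"config field {field_name!r}: missing input {p!r}")
    panel = io.read_genotypes(config.genotypes, format="dosage_tsv"
                              if str(config.genotypes).endswith(".tsv") else "vcf")
    panel = io.filter_maf(panel, config.maf_threshold)
    genes = io.read_annotation(config.annotation)
    traits = io.read_traits(config.traits)
    expr_paths = {}
    if config.expression_dir:
        for p in sorted(Path(config.expression_dir).glob("expression_*.tsv")):
            expr_paths[p.stem.replace("expression_", "")] = p
    tensor = io.read_expression(expr_paths) if expr_paths else None

    kinship = compute_kinship(panel)
    write_matrix_tsv(kinship, out / "kinship.tsv")
    pcs = compute_mds_pcs(panel, k=config.n_pcs)
    covset = CovariateSet(panel.individuals, pcs=pcs)
    if tensor is not None:
        for tissue in tensor.tissue_names:
            expr = tensor.matrix(tissue)
            shared = [i for i in expr.columns if i in pcs.index]
            k_f = min(config.n_factors, len(shared) - config.n_pcs - 2,
                      expr.shape[0] - 1)
            covset.factors[tissue] = estimate_hidden_factors(
                expr[shared], known_covariates=pcs.reindex(shared), k=max(k_f, 1))

    known = io.read_gene_list(config.known_genes) if config.known_genes else None
    if known is not None:
        known, dropped = known.resolve(genes)
        if dropped:
            log.warning("known-gene list: dropped unresolvable ids %s", dropped)

    by_method_trait: dict[str, dict[str, pd.DataFrame]] = {}
    gwas_frames, twas_frames, combined_frames = [], [], []
    per_trait_records = {}
    for trait in traits:
        trait.check_runnable()
        mlm = run_mlm_gwas(panel, trait, kinship)
        gwas_frames.append(records_to_frame(mlm, trait.name, "mlm"))
        if config.run_glm:
            glm = run_glm_gwas(panel, trait)
            gwas_frames.append(records_to_frame(glm, trait.name, "glm"))
        stage = {"mlm": mlm}
        if tensor is not None:
            single = run_twas_single(tensor, config.primary_tissue, trait, covset)
            multi = run_twas_multitissue(tensor, trait, covset)
            twas_frames.append(twas_records_to_frame(single, "twas_single"))
            twas_frames.append(twas_records_to_frame(multi, "twas_multi"))
            comb_s = combine_pipeline(mlm, single, genes, trait.name, mode="single",
                                      top_fraction=config.top_snp_fraction)
            comb_m = combine_pipeline(mlm, multi, genes, trait.name, mode="multi",
                                      top_fraction=config.top_snp_fraction)
            combined_frames += [combined_to_frame(comb_s), combined_to_frame(comb_m)]
            stage.update(single=single, multi=multi, comb_s=comb_s, comb_m=comb_m)
            gene_tables = {
                "twas_single": twas_records_to_frame(single)[["id", "p"]],
                "twas_multi": twas_records_to_frame(multi)[["id", "p"]],
                "gwas_mlm": _gene_level_frame(mlm, genes, config.top_snp_fraction),
                "FisherGWASTWAS": combined_to_frame(comb_s)[["id", "p"]],
                "FisherGWASmultiTWAS": combined_to_frame(comb_m)[["id", "p"]],
            }
            for m, tbl in gene_tables.items():
                by_method_trait.setdefault(m, {})[trait.name] = tbl
        per_trait_records[trait.name] = stage

    io.write_assoc_table(pd.concat(gwas_frames, ignore_index=True), out / "gwas.tsv")
    if twas_frames:
        io.write_assoc_table(pd.concat(twas_frames, ignore_index=True), out / "twas.tsv")
    if combined_frames:
        pd.concat(combined_frames, ignore_index=True).to_csv(
            out / "combined.tsv", sep="\t", index=False)
        first = traits[0]
        manhattan_frame(per_trait_records[first.name]["mlm"],
                        per_trait_records[first.name].get("single", []),
                        genes).to_csv(out / "manhattan.tsv", sep="\t", index=False)
    if known is not None and by_method_trait:
        tallies = tally_methods(by_method_trait, known, config.detection_fraction)
        tally_to_frame(tallies).to_csv(out / "tally.tsv", sep="\t", index=False)

    if (config.run_varpart and config.families and config.validation_genotypes
            and config.validation_traits and by_method_trait):
        nam = io.read_genotypes(config.validation_genotypes, format="dosage_tsv")
        overlap = set(nam.individuals) & set(panel.individuals)
        if overlap:
            raise ValueError(
                f"validation population shares {len(overlap)} individuals with discovery"
            )
        fam = pd.read_csv(config.families, sep="\t", index_col=0).iloc[:, 0]
        nam_traits = {t.name: t for t in io.read_traits(config.validation_traits)}
        gene_by_id = {g.id: g for g in genes}
        rows = []
        for trait in traits:
            if trait.name not in nam_traits:
                log.warning("varpart: no validation phenotype for trait %s", trait.name)
                continue
            stage = per_trait_records[trait.name]
            selections = {
                "twas_single": select_top_genes_twas(
                    by_method_trait["twas_single"][trait.name], config.top_genes),
                "gwas_mlm": select_top_genes_gwas(
                    stage["mlm"], genes, config.top_genes, config.window_radius),
                "FisherGWASTWAS": select_top_genes_twas(
                    by_method_trait["FisherGWASTWAS"][trait.name], config.top_genes),
            }
            for m, sel in selections.items():
                gset = [gene_by_id[g] for g in sel.genes if g in gene_by_id]
                if not gset:
                    continue
                comps, summed = partition_by_family(
                    nam_traits[trait.name], nam, fam.reindex(nam.individuals), gset,
                    radius=config.window_radius)
                df = components_to_frame(comps, m, trait.name)
                df["summed_h2"] = summed
                rows.append(df)
            gw = genomewide_h2(nam_traits[trait.name], nam)
            gw_df = components_to_frame([gw], "all_snps", trait.name)
            gw_df["summed_h2"] = float("nan")
            rows.append(gw_df)
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(out / "varpart.tsv", sep="\t", index=False)

    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "n_traits": len(traits),
        "n_variants": panel.n_variants,
        "n_individuals": panel.n_individuals,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _gene_level_frame(mlm_records, genes, top_fraction) -> pd.DataFrame:
    """Gene-level GWAS ranking table: all annotated genes, min assigned top-SNP
    p (p = 1 when untouched)."""
    from .ensemble import gene_level_gwas_p, select_top_fraction

    top = select_top_fraction(mlm_records, top_fraction)
    by_gene = {r.gene_id: r.p for r in gene_level_gwas_p(top, genes)}
    return pd.DataFrame({
        "id": [g.id for g in genes],
        "p": [by_gene.get(g.id, 1.0) for g in genes],
    })
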