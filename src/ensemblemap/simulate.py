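"""Synthetic genotype / expression / phenotype triplets with ground truth.

The generator emulates the data context of a maize association study at desk
scale: a structured diversity panel of ~300 inbred lines, several biparental
RIL families sharing a common parent (NAM-like), multi-tissue expression with
cis genetic regulation, hidden expression-wide confounders and dropout, and
traits driven by a mix of regulatory genes (acting through the genetic
component of expression) and coding genes (acting directly through genotype)
on top of a polygenic background.

Linkage disequilibrium is induced by a Markov founder-copying process along
each chromosome rather than a coalescent model: each inbred chromosome copies
one of a finite set of founder haplotypes and switches founders between
adjacent variants with the configured recombination probability.  This gives
controllable LD block lengths with no external dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionTensor, GeneModel, GenotypePanel, TraitTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_panel",
    "simulate_nam_families",
    "place_genes",
    "simulate_expression",
    "simulate_trait",
    "apply_trait_to_panel",
    "write_truth",
    "read_truth",
]


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` is mandatory.

    Defaults are desk-scale analogues of the study design: a ~300-line
    structured panel, 5 RIL families of 200 lines, a few thousand variants
    over 5 chromosomes, a few hundred genes, 7 tissues.
    """

    seed: int
    n_panel: int = 300
    n_families: int = 5
    n_per_family: int = 200
    n_chromosomes: int = 5
    n_variants: int = 4000
    n_genes: int = 500
    n_subpopulations: int = 2
    n_founders: int = 20            # founder haplotypes per subpopulation
    recomb_prob: float = 0.05       # founder-switch probability per adjacent-variant step
    maf_beta_a: float = 0.8         # ancestral allele-frequency spectrum Beta(a, b)
    maf_beta_b: float = 0.8
    fst: float = 0.1                # subpopulation divergence of allele frequencies
    chrom_length: int = 50_000_000  # bp per chromosome
    gene_length: int = 3_000        # bp per gene body
    # expression
    n_tissues: int = 7
    cis_window: int = 50_000        # bp around the gene body contributing cis variants
    n_cis_per_gene: int = 2
    cis_eqtl_effect_size: float = 1.0   # sd units of the lead cis effect
    n_hidden_confounders: int = 10
    confounder_sd: float = 0.7
    subpop_expr_shift_sd: float = 0.5
    expr_noise_sd: float = 1.0
    dropout_rate: float = 0.05
    frac_low_expressed: float = 0.10    # genes expressed in fewer than half of individuals
    tissue_sharing: float = 0.7         # probability a non-primary tissue shares the cis effect
    # trait
    n_causal_regulatory: int = 5
    n_causal_coding: int = 5
    h2_target: float = 0.6
    polygenic_fraction: float = 0.3     # share of genetic variance from the polygenic background
    n_polygenic: int = 200
    effect_distribution: str = "normal"  # regulatory/coding effect sizes ~ N(0, 1)

    def __post_init__(self) -> None:
        counts = (self.n_panel, self.n_families, self.n_per_family, self.n_chromosomes,
                  self.n_variants, self.n_genes, self.n_subpopulations, self.n_tissues)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError(f"h2_target must be in [0, 1], got {self.h2_target}")
        if self.n_causal_regulatory + self.n_causal_coding > self.n_genes:
            raise ValueError("causal gene counts exceed n_genes")
        if not (0.0 <= self.recomb_prob <= 1.0):
            raise ValueError("recomb_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulationTruth:
    """Ground-truth labels written alongside every simulated trait."""

    causal_genes: pd.DataFrame  # columns: gene, mechanism {regulatory, coding}, effect, variant
    causal_tissues: dict[str, list[str]] = field(default_factory=dict)
    realized_h2: float = 0.0
    subpopulations: pd.Series | None = None  # individual -> subpop label
    # the genetic component is linear in dosage; these weights re-express the
    # trait in any other panel (e.g. the NAM validation families)
    variant_weights: pd.Series | None = None

    def __post_init__(self) -> None:
        mech = set(self.causal_genes["mechanism"])
        if not mech <= {"regulatory", "coding"}:
            raise ValueError(f"unknown mechanism labels {mech - {'regulatory', 'coding'}}")
        if self.causal_genes["gene"].duplicated().any():
            raise ValueError("a causal gene carries two mechanism labels")
        if not (0.0 <= self.realized_h2 <= 1.0):
            raise ValueError("realized h2 outside [0, 1]")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic substream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _variant_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per_chrom[: config.n_variants % config.n_chromosomes] += 1
    frames = []
    for c in range(config.n_chromosomes):
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length + 1), size=per_chrom[c], replace=False))
        frames.append(pd.DataFrame({
            "id": [f"chr{c + 1}_{p}" for p in pos],
            "chrom": f"chr{c + 1}",
            "pos": pos,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, pd.Series]:
    """Simulate the structured inbred diversity panel.

    Returns the panel plus a Series mapping individual id -> subpopulation
    label.  Dosages are fully inbred ({0, 2}).
    """
    if config.n_variants < config.n_genes:
        raise ValueError("need at least as many variants as genes")
    rng = _rng(config, stream=1)
    variants = _variant_table(config, rng)
    m = len(variants)
    # ancestral frequencies, then subpopulation-diverged frequencies
    p0 = rng.beta(config.maf_beta_a, config.maf_beta_b, size=m).clip(0.02, 0.98)
    if config.fst > 0 and config.n_subpopulations > 1:
        c = (1.0 - config.fst) / config.fst
        sub_freq = rng.beta(
            np.maximum(p0 * c, 1e-3), np.maximum((1.0 - p0) * c, 1e-3),
            size=(config.n_subpopulations, m),
        )
    else:
        sub_freq = np.tile(p0, (config.n_subpopulations, 1))
    # founder haplotypes per subpopulation
    founders = (rng.random((config.n_subpopulations, config.n_founders, m))
                < sub_freq[:, None, :]).astype(float)
    chrom_codes = pd.factorize(variants["chrom"])[0]
    new_chrom = np.r_[True, np.diff(chrom_codes) != 0]
    subpop = np.repeat(np.arange(config.n_subpopulations),
                       -(-config.n_panel // config.n_subpopulations))[: config.n_panel]
    dosages = np.empty((config.n_panel, m))
    for i in range(config.n_panel):
        path = _founder_path(rng, m, config.n_founders, config.recomb_prob, new_chrom)
        dosages[i] = 2.0 * founders[subpop[i], path, np.arange(m)]
    individuals = [f"P{i + 1:04d}" for i in range(config.n_panel)]
    labels = pd.Series([f"subpop{s + 1}" for s in subpop], index=individuals, name="subpopulation")
    return GenotypePanel(individuals, variants, dosages), labels


def _founder_path(rng, m, n_founders, recomb_prob, new_chrom) -> np.ndarray:
    """Markov founder index along the genome, resetting at chromosome starts."""
    switch = rng.random(m) < recomb_prob
    switch |= new_chrom
    picks = rng.integers(0, n_founders, size=m)
    idx = np.maximum.accumulate(np.where(switch, np.arange(m), -1))
    return picks[idx]


def simulate_nam_families(
    config: SimulationConfig, founders: GenotypePanel
) -> tuple[GenotypePanel, pd.Series]:
    """Simulate NAM-like biparental RIL families from inbred founders.

    Founder 0 is the common parent crossed to each of the next
    ``n_families`` founders.  Each RIL chromosome is a Markov mosaic of its
    two parents' haplotypes; the output is fully inbred ({0, 2}).
    """
    if founders.n_individuals < config.n_families + 1:
        raise ValueError(
            f"need >= {config.n_families + 1} founders, got {founders.n_individuals}"
        )
    d = founders.dosages
    if np.any(d[~np.isnan(d)] == 1.0):
        raise ValueError("founders must be fully inbred (dosages in {0, 2})")
    rng = _rng(config, stream=2)
    m = founders.n_variants
    chrom_codes = pd.factorize(founders.variants["chrom"])[0]
    new_chrom = np.r_[True, np.diff(chrom_codes) != 0]
    common = d[0]
    ids, rows, fams = [], [], []
    for f in range(config.n_families):
        other = d[f + 1]
        parents = np.vstack([common, other])  # 2 x m
        for k in range(config.n_per_family):
            path = _founder_path(rng, m, 2, config.recomb_prob, new_chrom)
            geno = parents[path, np.arange(m)]
            # missing parent call propagates as missing
            rows.append(geno)
            ids.append(f"F{f + 1:02d}_{k + 1:04d}")
            fams.append(f"fam{f + 1:02d}")
    panel = GenotypePanel(ids, founders.variants.drop(columns="maf", errors="ignore"),
                          np.array(rows))
    return panel, pd.Series(fams, index=ids, name="family")


def place_genes(config: SimulationConfig) -> list[GeneModel]:
    """Assign non-overlapping gene intervals across the chromosomes."""
    rng = _rng(config, stream=3)
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    genes = []
    g_id = 0
    for c in range(config.n_chromosomes):
        n = per_chrom[c]
        if n == 0:
            continue
        slot = config.chrom_length // n
        if slot <= config.gene_length:
            raise ValueError("chromosome too short for non-overlapping genes")
        for k in range(n):
            start = int(k * slot + rng.integers(1, slot - config.gene_length))
            genes.append(GeneModel(
                id=f"gene{g_id + 1:04d}",
                chromosome=f"chr{c + 1}",
                start=start,
                end=start + config.gene_length - 1,
                strand="+" if rng.random() < 0.5 else "-",
            ))
            g_id += 1
    return genes


def _cis_genetic_values(
    config: SimulationConfig,
    panel: GenotypePanel,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Per-gene cis genetic component (n_genes x n_ind) and lead-variant map."""
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()
    d = panel.imputed_dosages()
    sd = d.std(axis=0)
    z = (d - d.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    values = np.zeros((len(genes), panel.n_individuals))
    cis_map: dict[str, list[str]] = {}
    for gi, gene in enumerate(genes):
        in_win = (chrom == gene.chromosome) & (pos >= gene.start - config.cis_window) \
            & (pos <= gene.end + config.cis_window) & (sd > 0)
        idx = np.flatnonzero(in_win)
        if idx.size == 0:
            cis_map[gene.id] = []
            continue
        k = min(config.n_cis_per_gene, idx.size)
        chosen = rng.choice(idx, size=k, replace=False)
        # exponential decay of effect size from the lead variant
        w = config.cis_eqtl_effect_size * 0.5 ** np.arange(k) * rng.choice([-1.0, 1.0], size=k)
        values[gi] = z[:, chosen] @ w
        # store weights on the raw-dosage scale so they port to other panels
        cis_map[gene.id] = [
            (panel.variants["id"].iloc[j], float(w[t] / sd[j]))
            for t, j in enumerate(chosen)
        ]
    return values, cis_map


def simulate_expression(
    config: SimulationConfig,
    panel: GenotypePanel,
    genes: list[GeneModel],
    subpops: pd.Series | None = None,
) -> tuple[ExpressionTensor, np.ndarray, dict]:
    """Simulate the multi-tissue expression tensor.

    Per gene g and tissue t::

        x = s_gt * cis_g + subpop shift + Lambda @ hidden + noise

    then shifted so observed values are non-negative, with dropout applied
    missing-at-random plus a per-gene "barely expressed in this tissue" mode
    that leaves more than half the individuals at zero abundance.

    Returns (tensor, cis genetic values (genes x individuals), meta) where
    ``meta`` records the cis variant ids and the tissue-activity flags.
    """
    rng = _rng(config, stream=4)
    n = panel.n_individuals
    cis, cis_map = _cis_genetic_values(config, panel, genes, rng)
    gene_ids = [g.id for g in genes]
    if subpops is not None:
        sub_codes = pd.factorize(subpops.reindex(panel.individuals).fillna("?"))[0]
    else:
        sub_codes = np.zeros(n, dtype=int)
    n_sub = sub_codes.max() + 1
    tissue_active: dict[str, np.ndarray] = {}
    tissues: dict[str, pd.DataFrame] = {}
    hidden = rng.normal(size=(n, config.n_hidden_confounders))
    for t in range(config.n_tissues):
        name = "kernel" if t == 0 else f"tissue{t + 1}"
        # the primary (kernel) tissue always carries the cis effect
        active = np.ones(len(genes), dtype=bool) if t == 0 else (
            rng.random(len(genes)) < config.tissue_sharing
        )
        shift = rng.normal(scale=config.subpop_expr_shift_sd, size=(len(genes), n_sub))
        loadings = rng.normal(scale=config.confounder_sd,
                              size=(len(genes), config.n_hidden_confounders))
        x = (active[:, None] * cis
             + shift[:, sub_codes]
             + loadings @ hidden.T
             + rng.normal(scale=config.expr_noise_sd, size=(len(genes), n)))
        x = x - x.min(axis=1, keepdims=True)  # non-negative abundance scale
        # low-expression mode: > half of individuals at zero
        n_low = int(round(config.frac_low_expressed * len(genes)))
        low = rng.choice(len(genes), size=n_low, replace=False) if n_low else np.array([], int)
        for gi in low:
            z_ind = rng.choice(n, size=(n // 2) + 1 + rng.integers(0, max(n // 4, 1)), replace=False)
            x[gi, z_ind] = 0.0
        mask = rng.random(x.shape) < config.dropout_rate
        x = np.where(mask, np.nan, x)
        tissues[name] = pd.DataFrame(x, index=gene_ids, columns=panel.individuals)
        tissue_active[name] = active
    meta = {"cis_variants": cis_map, "tissue_active": tissue_active}
    return ExpressionTensor(tissues), cis, meta


def simulate_trait(
    config: SimulationConfig,
    panel: GenotypePanel,
    genes: list[GeneModel],
    cis_values: np.ndarray,
    meta: dict,
    name: str = "trait1",
    subpops: pd.Series | None = None,
    stream: int = 5,
) -> tuple[TraitTable, SimulationTruth]:
    """Simulate one trait with regulatory + coding causal genes.

    y = sum_reg beta_g * cis_g  +  sum_cod alpha_s * dosage_s  +  polygenic
        + Gaussian noise, with the noise variance set so the genetic fraction
    of variance hits ``h2_target`` in expectation.  Regulatory genes act
    through the *genetic* component of expression, so both TWAS and GWAS can
    in principle see them; coding genes act through a variant inside the
    gene and are invisible to expression.
    """
    rng = _rng(config, stream=stream)
    n = panel.n_individuals
    cis_var = cis_values.var(axis=1)
    eligible_reg = np.flatnonzero(cis_var > 1e-12)
    if config.n_causal_regulatory > eligible_reg.size:
        raise ValueError("not enough genes with cis genetic variance for regulatory causals")
    reg_idx = rng.choice(eligible_reg, size=config.n_causal_regulatory, replace=False)
    remaining = np.setdiff1d(np.arange(len(genes)), reg_idx)
    cod_idx = rng.choice(remaining, size=config.n_causal_coding, replace=False)

    d = panel.imputed_dosages()
    sd = d.std(axis=0)
    pos = panel.variants["pos"].to_numpy()
    chrom = panel.variants["chrom"].to_numpy()

    m = panel.n_variants
    vid_index = {vid: j for j, vid in enumerate(panel.variants["id"])}
    records = []
    g_reg = np.zeros(n)
    w_reg_vec = np.zeros(m)
    for gi in reg_idx:
        beta = rng.normal()
        x = cis_values[gi]
        s = x.std()
        g_reg += beta * (x - x.mean()) / s
        for vid, wr in meta["cis_variants"][genes[gi].id]:
            w_reg_vec[vid_index[vid]] += beta * wr / s
        records.append((genes[gi].id, "regulatory", beta, ""))
    g_cod = np.zeros(n)
    w_cod_vec = np.zeros(m)
    for gi in cod_idx:
        gene = genes[gi]
        near = (chrom == gene.chromosome) & (sd > 0) & \
            (np.abs((pos - (gene.start + gene.end) / 2)) < config.cis_window)
        idx = np.flatnonzero(near)
        if idx.size == 0:
            idx = np.flatnonzero((chrom == gene.chromosome) & (sd > 0))
        j = idx[np.argmin(np.abs(pos[idx] - (gene.start + gene.end) / 2))]
        alpha = rng.normal()
        g_cod += alpha * (d[:, j] - d[:, j].mean()) / sd[j]
        w_cod_vec[j] += alpha / sd[j]
        records.append((gene.id, "coding", alpha, panel.variants["id"].iloc[j]))
    poly_idx = rng.choice(np.flatnonzero(sd > 0),
                          size=min(config.n_polygenic, int((sd > 0).sum())), replace=False)
    u = rng.normal(size=poly_idx.size) / np.sqrt(max(poly_idx.size, 1))
    g_poly = ((d[:, poly_idx] - d[:, poly_idx].mean(axis=0)) / sd[poly_idx]) @ u
    w_poly_vec = np.zeros(m)
    w_poly_vec[poly_idx] = u / sd[poly_idx]

    def _scale_factor(v: np.ndarray, target_var: float) -> float:
        s = v.std()
        return float(np.sqrt(target_var) / s) if s > 0 else 0.0

    p_frac = config.polygenic_fraction
    n_caus = config.n_causal_regulatory + config.n_causal_coding
    if n_caus > 0:
        w_reg = (1 - p_frac) * config.n_causal_regulatory / n_caus
        w_cod = (1 - p_frac) * config.n_causal_coding / n_caus
    else:
        w_reg = w_cod = 0.0
        p_frac = 1.0 if config.h2_target > 0 else 0.0
    f_reg = _scale_factor(g_reg, w_reg)
    f_cod = _scale_factor(g_cod, w_cod)
    f_poly = _scale_factor(g_poly, p_frac)
    g = f_reg * g_reg + f_cod * g_cod + f_poly * g_poly
    w_total = f_reg * w_reg_vec + f_cod * w_cod_vec + f_poly * w_poly_vec
    if config.h2_target >= 1.0 and g.std() == 0:
        raise ValueError("h2_target = 1 requires at least one causal effect")
    if config.h2_target == 0 or g.std() == 0:
        y = rng.normal(size=n)
        g = np.zeros(n)
        w_total = np.zeros(m)
    else:
        f_tot = 1.0 / g.std()
        g = g * f_tot  # unit genetic variance
        w_total = w_total * f_tot
        noise_sd = np.sqrt((1.0 - config.h2_target) / config.h2_target)
        y = g + rng.normal(scale=noise_sd, size=n)
    realized = float(g.var() / y.var()) if y.var() > 0 else 0.0
    truth = SimulationTruth(
        causal_genes=pd.DataFrame(records, columns=["gene", "mechanism", "effect", "variant"]),
        causal_tissues={
            genes[gi].id: [t for t, act in meta["tissue_active"].items() if act[gi]]
            for gi in reg_idx
        },
        realized_h2=min(realized, 1.0),
        subpopulations=subpops,
        variant_weights=pd.Series(w_total, index=panel.variants["id"].to_numpy()),
    )
    trait = TraitTable(name=name, values=pd.Series(y, index=panel.individuals, name=name))
    return trait, truth


def apply_trait_to_panel(
    truth: SimulationTruth,
    panel: GenotypePanel,
    h2: float,
    seed: int,
    name: str,
) -> TraitTable:
    """Re-express a simulated trait in another panel (e.g. NAM families).

    Applies the truth's per-variant weights to the new panel's dosages and
    adds Gaussian noise so the genetic variance fraction is ``h2`` in the
    new population.
    """
    if truth.variant_weights is None:
        raise ValueError("truth carries no variant weights")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    w = truth.variant_weights.reindex(panel.variants["id"]).fillna(0.0).to_numpy()
    d = panel.imputed_dosages()
    g = (d - d.mean(axis=0)) @ w
    n = panel.n_individuals
    if h2 <= 0 or g.std() == 0:
        y = rng.normal(size=n)
    else:
        g = g / g.std()
        y = g + rng.normal(scale=np.sqrt((1.0 - h2) / h2), size=n)
    return TraitTable(name=name, values=pd.Series(y, index=panel.individuals, name=name))


def write_truth(truth: SimulationTruth, path) -> None:
    df = truth.causal_genes.copy()
    df["realized_h2"] = truth.realized_h2
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "mechanism": str})
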