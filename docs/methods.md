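# Methods

## Scope and design

The package implements a gene-mapping ensemble for quantitative traits in
inbred plant panels: per-variant GWAS (naive GLM and kinship-aware mixed
model), per-gene TWAS (single- and multi-tissue), a gene-level Fisher
combination of the two, rank-based detection scoring against known-gene
lists, and independent validation by windowed-kinship REML variance
partitioning in NAM-like RIL families. Because the real data resources this
design targets (a genotyped diversity panel, multi-tissue 3′ mRNA-seq
quantifications, NAM phenotypes) are far beyond desk scale, every stage is
exercised on synthetic data whose generator is itself first-class, tested
code with ground-truth labels.

## The synthetic generator

**Genotypes.** Fully inbred individuals (dosages in {0, 2}) in a panel of
`n_panel = 300` lines split over `n_subpopulations = 2` subpopulations with
allele-frequency divergence `fst = 0.1`. Linkage disequilibrium comes from a
Markov founder-copying process: each chromosome copies one of
`n_founders = 20` founder haplotypes and switches to a random founder
between adjacent variants with probability `recomb_prob = 0.05`. This gives
controllable LD block lengths with two useful limits — `recomb_prob = 0`
reproduces founder haplotypes exactly, `recomb_prob = 0.5` leaves adjacent
variants essentially uncorrelated. It is not a coalescent model: allele
frequency spectra and long-range LD decay are stylized, so tests passing
here say nothing about, e.g., rare-variant behaviour in real maize.

**Scale.** Defaults are `n_variants = 4000`, `n_genes = 500` on 5
chromosomes of 50 Mb. The gene count matters for detection scoring: the
top-1% cut is `k = ceil(0.01 · n_genes)`. With few genes (k ≤ 2) a strong
GWAS fills every slot with causal genes and the comparison of methods
degenerates to tie-or-lose at a ceiling; at 500 genes (k = 5) the slots do
not bind, matching the regime of real panels where the 1% cut is hundreds
of genes and never saturates. This is a property of the study design the
generator emulates, not a tuning of any method.

**Expression.** Per gene and tissue:
`x = s·cis + subpop shift + Λh + ε`, shifted to a non-negative scale, where
`cis` is a weighted sum of 1–2 genotyped variants within ±50 kb of the gene
(lead effect `cis_eqtl_effect_size = 1` sd, second variant halved),
`h` are `n_hidden_confounders = 10` standard-normal hidden factors with
loadings of sd 0.7, and ε has sd 1. The primary ("kernel") tissue always
carries the cis effect; other tissues share it with probability
`tissue_sharing = 0.7`. Missingness is missing-at-random dropout at rate
0.05 plus a "barely expressed" mode: 10% of genes are zeroed in more than
half of individuals so the at-least-half expression filter has real work to
do.

**Traits.** `y = Σ βg·cis_g + Σ αs·dosage_s + polygenic + ε` with
regulatory genes acting through the *genetic* component of expression (so
both layers can in principle see them), coding genes acting through a
variant inside the gene (invisible to expression), a 200-variant polygenic
background carrying 30% of genetic variance, and Gaussian effects
throughout (no empirical effect-size distribution is claimed). Noise is
scaled so the genetic variance fraction hits `h2_target` in expectation;
the realized fraction is recorded in the truth output. The whole genetic
component is linear in dosage, and the truth stores the per-variant weight
vector, which is how the same trait is re-expressed in the NAM validation
families (fresh noise, same architecture).

**NAM families.** Founder 0 of the panel is crossed to each of
`n_families = 5` other founders; each RIL chromosome is a Markov mosaic of
its two parents (single-gamete approximation of repeated selfing), fully
inbred. Validation and discovery populations are disjoint by construction
and the pipeline enforces this.

## Numerical choices

- **Dosage coding** counts the minor allele; re-orientation happens in the
  file readers, not in the container constructor, so subsets and RIL
  offspring keep codings comparable with their source panel. MAF counts
  observed alleles only; "above 5%" is a strict inequality.
- **Kinship** is VanRaden method 1, `K = WWᵀ/Σ 2p(1−p)`, missing dosages
  mean-imputed at algebra time only. For fully inbred material the diagonal
  mean is ≈ 2 (= 1 + F); no LD-based SNP weighting is applied.
- **MDS coordinates** come from double-centering `−D²/2` with
  `D = 1 − IBS`; eigenvector signs are fixed so each column's
  largest-magnitude entry is positive, making output deterministic.
- **Hidden expression factors** are residualized truncated-SVD factors:
  per-gene z-scores (missing → 0), residualized on intercept + genetic PCs,
  top-k left singular vectors. This is a deterministic surrogate for
  variational PEER; the pipeline consumes factors only as fixed covariates
  and accepts precomputed factor tables, so true PEER output can be dropped
  in.
- **Mixed model** uses a single REML δ from the null model (P3D/EMMAX);
  per-variant GLS then runs vectorized through the eigenbasis of K. A
  per-variant exact-δ mode exists for cross-checks. The default MLM uses
  kinship only (no fixed PCs), matching the design it emulates.
- **REML h²** is maximized on h² ∈ [0, 1] by bounded scalar search over the
  rotated likelihood with the total variance profiled out; endpoints are
  checked, boundary optima allowed, and a flat-likelihood flag fires when
  the restricted likelihood is constant in h² (e.g. K = I, where σ²k and
  σ²e are not separately identifiable).
- **p-values** are floored at 1e−300 before logs; the Fisher combination
  uses the df = 4 closed form `e^(−X/2)(1 + X/2)`.
- **Aggregation decisions** the source design leaves open: multiple top
  SNPs mapping to one gene take the minimum p (a Manhattan peak read off at
  its best SNP; Fisher over LD-correlated SNPs would inflate); genes never
  hit by a top-10% SNP enter the combination at p = 1, mirroring the p = 1
  rule for TWAS-untested genes; the top-1% denominator is the set of genes
  a method actually ranked, with a `common_universe` option to force a
  shared denominator.
- **Complete-case analysis** per gene in TWAS; the multi-tissue model uses
  the intersection of individuals across included tissues and warns when it
  falls below 50. "Expressed" means strictly positive normalized abundance.

## Problem sizes

Experiments are sized for a single CPU: null calibration uses 10–20
simulated panels of 300 × 2000; power ordering 5–10 replicate sets of 20
traits over 300 × 4000 panels; REML recovery n = 500 with 10–20 draws per
heritability level; window discrimination 25–50 NAM simulations of 4 × 100
RILs. The analysis scripts and the acceptance script print the sizes they
used alongside every number.

## Known limitations

- The LD process is stylized (geometric block lengths, no mutation or
  gene-conversion structure); genomic-control behaviour on real data will
  differ quantitatively.
- The multi-tissue TWAS follows the PCs-only covariate design, so its test
  statistics are correlated across genes through shared hidden confounders;
  its empirical type-I error estimates are noisier than the single-tissue
  test's even though the per-gene F test is exactly calibrated.
- Heritability partitioning reports point estimates only, and the REML
  solver fits a single kinship component — no multi-component or
  LD-weighted variants.
- No epistasis, dominance (inbred material), or genotype-by-environment
  structure is simulated.
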