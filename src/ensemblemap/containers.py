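"""Typed in-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* genotype dosages count copies of the **minor** allele (0, 1, 2) with
  ``NaN`` marking missing calls; fully inbred material uses {0, 2};
* genomic coordinates are 1-based and inclusive on both ends (GFF3
  convention), so a SNP lies inside a gene iff ``start <= pos <= end``;
* expression matrices are genes x individuals with ``NaN`` marking
  unobserved (dropout) entries; observed values are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "GenotypePanel",
    "GeneModel",
    "ExpressionTensor",
    "TraitTable",
    "KnownGeneList",
    "minor_allele_frequency",
]


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Minor-allele frequency from a dosage vector, counting observed alleles only.

    Missing calls (NaN) contribute neither to the allele count nor to the
    denominator.  Returns 0.0 for an all-missing column.
    """
    d = np.asarray(dosages, dtype=float)
    obs = ~np.isnan(d)
    if not obs.any():
        return 0.0
    f = float(d[obs].sum()) / (2.0 * int(obs.sum()))
    return min(f, 1.0 - f)


@dataclass(frozen=True)
class Variant:
    """A biallelic site with its panel-wide minor-allele frequency."""

    id: str
    chromosome: str
    position: int  # 1-based bp
    ref: str = "A"
    alt: str = "T"
    maf: float = 0.0

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1, got {self.position}")
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval from the annotation (1-based inclusive)."""

    id: str
    chromosome: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.id}: start must be >= 1")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance_to(self, pos: int) -> int:
        """Gap in bp from a position to this interval; 0 if inside."""
        if self.contains(pos):
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))


class GenotypePanel:
    """Individuals x biallelic variants with minor-allele dosage coding.

    Parameters
    ----------
    individuals
        Ordered unique individual ids (rows of ``dosages``).
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (one row per
        column of ``dosages``); sorted by (chrom, pos) on construction.
    dosages
        float array of shape (n_individuals, n_variants) with entries in
        {0, 1, 2, NaN}.
    """

    def __init__(self, individuals, variants: pd.DataFrame, dosages: np.ndarray):
        individuals = list(individuals)
        if len(set(individuals)) != len(individuals):
            raise ValueError("duplicate individual ids")
        variants = variants.reset_index(drop=True).copy()
        required = {"id", "chrom", "pos"}
        if not required.issubset(variants.columns):
            raise ValueError(f"variant table missing columns {required - set(variants.columns)}")
        if variants["id"].duplicated().any():
            dup = variants.loc[variants["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(individuals), len(variants)):
            raise ValueError(
                f"dosage shape {dosages.shape} != ({len(individuals)}, {len(variants)})"
            )
        ok = np.isnan(dosages) | np.isin(dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = dosages[~ok][0]
            raise ValueError(f"dosage entries must be in {{0,1,2,NaN}}; found {bad}")
        # canonical order: chromosome, then position
        order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
        variants = variants.iloc[order].reset_index(drop=True)
        dosages = dosages[:, order]
        self.individuals: list[str] = individuals
        self.variants: pd.DataFrame = variants
        self.dosages: np.ndarray = dosages
        self.variants["maf"] = self.maf()

    # -- basic queries -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency over observed calls."""
        d = self.dosages
        obs = ~np.isnan(d)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n_obs > 0, np.nansum(d, axis=0) / (2.0 * np.maximum(n_obs, 1)), 0.0)
        return np.minimum(f, 1.0 - f)

    def variant_objects(self) -> list[Variant]:
        maf = self.maf()
        return [
            Variant(
                id=row.id,
                chromosome=str(row.chrom),
                position=int(row.pos),
                ref=str(getattr(row, "ref", "A")),
                alt=str(getattr(row, "alt", "T")),
                maf=float(maf[i]),
            )
            for i, row in enumerate(self.variants.itertuples(index=False))
        ]

    def minor_oriented(self) -> "GenotypePanel":
        """A copy whose dosages count this panel's minor allele per column.

        Applied by the genotype readers so file input satisfies the
        minor-allele coding contract; internal constructions (subsets, RIL
        offspring) keep their inherited coding so dosages stay comparable
        across related panels.
        """
        d = self.dosages
        with np.errstate(invalid="ignore"):
            obs = (~np.isnan(d)).sum(axis=0)
            freq = np.where(obs > 0, np.nansum(d, axis=0) / (2.0 * np.maximum(obs, 1)), 0.0)
        flip = freq > 0.5
        if not flip.any():
            return self
        d = d.copy()
        d[:, flip] = 2.0 - d[:, flip]
        variants = self.variants.drop(columns="maf").copy()
        if {"ref", "alt"}.issubset(variants.columns):
            r = variants.loc[flip, "ref"].copy()
            variants.loc[flip, "ref"] = variants.loc[flip, "alt"]
            variants.loc[flip, "alt"] = r
        return GenotypePanel(self.individuals, variants, d)

    # -- subsetting ----------------------------------------------------
    def subset_individuals(self, ids) -> "GenotypePanel":
        ids = list(ids)
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"individuals not in panel: {missing[:5]}")
        rows = [pos[i] for i in ids]
        return GenotypePanel(ids, self.variants.drop(columns="maf"), self.dosages[rows])

    def subset_variants(self, variant_ids) -> "GenotypePanel":
        wanted = set(variant_ids)
        mask = self.variants["id"].isin(wanted).to_numpy()
        return GenotypePanel(
            self.individuals,
            self.variants.loc[mask].drop(columns="maf"),
            self.dosages[:, mask],
        )

    def imputed_dosages(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-variant mean.

        Used only at matrix-algebra time (kinship, association scans); the
        stored matrix keeps its NaNs.
        """
        d = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return d


class ExpressionTensor:
    """Per-tissue gene x individual abundance matrices with dropout masks.

    Each tissue holds a DataFrame (rows = genes, columns = individuals);
    NaN entries are unobserved (dropout), observed values are >= 0.
    """

    def __init__(self, tissues: dict[str, pd.DataFrame]):
        self.tissues: dict[str, pd.DataFrame] = {}
        for name, df in tissues.items():
            df = df.copy()
            vals = df.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(f"tissue {name!r}: observed abundance must be >= 0")
            self.tissues[name] = df

    @property
    def tissue_names(self) -> list[str]:
        return list(self.tissues)

    def matrix(self, tissue: str) -> pd.DataFrame:
        return self.tissues[tissue]

    def individuals(self, tissue: str) -> list[str]:
        return list(self.tissues[tissue].columns)

    def genes(self, tissue: str) -> list[str]:
        return list(self.tissues[tissue].index)

    def intersection_report(self, panel_individuals) -> dict[str, list[str]]:
        """Per tissue, the expression individuals absent from the genotype panel."""
        pset = set(panel_individuals)
        return {t: [i for i in df.columns if i not in pset] for t, df in self.tissues.items()}


@dataclass
class TraitTable:
    """One quantitative trait (BLUP-like values) keyed by individual id."""

    name: str
    values: pd.Series  # index = individual id, float, NaN allowed
    min_n: int = 30

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.duplicated().any():
            raise ValueError(f"trait {self.name}: duplicate individual ids")

    def observed(self) -> pd.Series:
        return self.values.dropna()

    def check_runnable(self) -> None:
        n = len(self.observed())
        if n < self.min_n:
            raise ValueError(
                f"trait {self.name}: only {n} non-missing values (< floor {self.min_n})"
            )


@dataclass
class KnownGeneList:
    """Positive-control gene ids for one trait class."""

    trait_class: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"known-gene list {self.trait_class!r} is empty")

    def resolve(self, annotation: list[GeneModel]) -> tuple["KnownGeneList", list[str]]:
        """Drop ids absent from the annotation; return (resolved list, dropped ids)."""
        known_ids = {g.id for g in annotation}
        kept = self.genes & known_ids
        dropped = sorted(self.genes - known_ids)
        if not kept:
            raise ValueError(f"known-gene list {self.trait_class!r}: no id resolves")
        return KnownGeneList(self.trait_class, kept), dropped
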