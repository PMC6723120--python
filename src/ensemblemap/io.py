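"""Readers and writers for the standard formats the pipeline touches.

Genotypes come in as VCF (via :mod:`cyvcf2`), HapMap-style tables, or plain
dosage TSVs; gene models come from GFF3 (via :mod:`gffutils`); expression,
traits, known-gene lists and result tables are tab-delimited text.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionTensor,
    GeneModel,
    GenotypePanel,
    KnownGeneList,
    TraitTable,
)

log = logging.getLogger(__name__)

ASSOC_COLUMNS = ["id", "chrom", "pos_or_interval", "method", "trait", "effect", "r", "stat", "p", "rank"]

__all__ = [
    "read_genotypes",
    "write_dosage_tsv",
    "write_vcf",
    "filter_maf",
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
    "read_traits",
    "write_traits",
    "read_gene_list",
    "write_gene_list",
    "read_assoc_table",
    "write_assoc_table",
    "ASSOC_COLUMNS",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | os.PathLike, format: str = "vcf") -> GenotypePanel:
    """Read a genotype file into a :class:`GenotypePanel`.

    Parameters
    ----------
    format
        One of ``vcf`` (v4.x with GT field), ``hapmap`` (HapMap-style
        tab-delimited, IUPAC single-letter calls), or ``dosage_tsv``
        (variants x individuals numeric table with id/chrom/pos columns).

    Multiallelic VCF records are dropped with a logged count; dosages are
    re-oriented to count the minor allele.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"vcf": _read_vcf, "hapmap": _read_hapmap, "dosage_tsv": _read_dosage_tsv}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}")
    return readers[format](path).minor_oriented()


def _read_vcf(path: Path) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_multi = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gts = np.array(rec.gt_types, dtype=float)
        gts[gts == 2] = np.nan
        gts[gts == 3] = 2.0
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(gts)
    if n_multi:
        log.warning("read_genotypes: dropped %d multiallelic records from %s", n_multi, path)
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if variants["id"].duplicated().any():
        dup = variants.loc[variants["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate variant id {dup!r}")
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(individuals), 0))
    return GenotypePanel(individuals, variants, dosages)


_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def _read_hapmap(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["rs#", "alleles", "chrom", "pos", "strand", "assembly#", "center",
             "protLSID", "assayLSID", "panelLSID", "QCcode"]
    for col in ("rs#", "alleles", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: HapMap header missing column {col!r}")
    individuals = [c for c in df.columns if c not in fixed]
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for line_no in range(len(df)):
        rec = df.iloc[line_no]
        alleles = str(rec["alleles"]).split("/")
        if len(alleles) != 2:
            log.warning("%s line %d: non-biallelic alleles field %r dropped",
                        path, line_no + 2, rec["alleles"])
            continue
        a, b = alleles
        vals = []
        for cell in rec[individuals]:
            c = str(cell).upper()
            if c in ("N", "NA", "NAN", "NONE", "-"):
                vals.append(np.nan)
            elif c in (a + a, a):
                vals.append(0.0)
            elif c in (b + b, b):
                vals.append(2.0)
            elif c in (a + b, b + a) or (c in _IUPAC_HET and set(_IUPAC_HET[c]) == {a, b}):
                vals.append(1.0)
            else:
                raise ValueError(
                    f"{path} line {line_no + 2}: cannot parse call {cell!r} for alleles {a}/{b}"
                )
        ids.append(str(rec["rs#"]))
        chroms.append(str(rec["chrom"]))
        poss.append(int(rec["pos"]))
        refs.append(a)
        alts.append(b)
        rows.append(vals)
    variants = pd.DataFrame({"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(individuals), 0))
    return GenotypePanel(individuals, variants, dosages)


def _read_dosage_tsv(path: Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
    for col in ("id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: dosage TSV missing column {col!r}")
    meta_cols = [c for c in ("id", "chrom", "pos", "ref", "alt") if c in df.columns]
    individuals = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    variants["pos"] = variants["pos"].astype(int)
    dosages = df[individuals].to_numpy(dtype=float).T
    return GenotypePanel(individuals, variants, dosages)


def write_dosage_tsv(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Write variants x individuals dosage TSV (NaN as NA)."""
    meta = panel.variants[[c for c in ("id", "chrom", "pos", "ref", "alt") if c in panel.variants.columns]]
    body = pd.DataFrame(panel.dosages.T, columns=panel.individuals)
    out = pd.concat([meta.reset_index(drop=True), body], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    """Emit a minimal VCF v4.2 with GT calls from the dosage matrix."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = panel.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.individuals) + "\n")
        for j, row in enumerate(panel.variants.itertuples(index=False)):
            calls = [
                "./." if np.isnan(d) else gt_map[float(d)] for d in panel.dosages[:, j]
            ]
            ref = getattr(row, "ref", "A")
            alt = getattr(row, "alt", "T")
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def filter_maf(panel: GenotypePanel, threshold: float) -> GenotypePanel:
    """Keep variants with minor-allele frequency strictly above ``threshold``.

    "Above" is a strict inequality: a variant at exactly the threshold is
    removed.  The individual set is unchanged; the result may hold zero
    variants.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError(f"threshold must be in [0, 0.5), got {threshold}")
    keep = panel.maf() > threshold
    return GenotypePanel(
        panel.individuals,
        panel.variants.loc[keep].drop(columns="maf"),
        panel.dosages[:, keep],
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene features from a GFF3 file (1-based inclusive coordinates)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise ValueError(f"{path}: gene feature at {feat.seqid}:{feat.start} lacks an ID attribute")
        genes.append(
            GeneModel(
                id=feat.attributes["ID"][0],
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else None,
            )
        )
    return genes


def write_annotation(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.strand or "."
            fh.write(
                f"{g.chromosome}\tensemblemap\tgene\t{g.start}\t{g.end}\t.\t{strand}\t.\tID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# expression / traits / gene lists
# ---------------------------------------------------------------------------

def read_expression(paths: dict[str, str | os.PathLike]) -> ExpressionTensor:
    """Read per-tissue gene x individual TSVs; NA cells become dropout mask."""
    tissues = {}
    for tissue, p in paths.items():
        df = pd.read_csv(p, sep="\t", index_col=0)
        bad = df.apply(lambda s: pd.to_numeric(s, errors="coerce"))
        non_numeric = df.notna() & bad.isna()
        if non_numeric.any().any():
            r, c = np.argwhere(non_numeric.to_numpy())[0]
            raise ValueError(
                f"{p}: non-numeric cell at gene {df.index[r]!r}, individual {df.columns[c]!r}"
            )
        tissues[tissue] = bad.astype(float)
    return ExpressionTensor(tissues)


def write_expression(tensor: ExpressionTensor, directory: str | os.PathLike) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tissue, df in tensor.tissues.items():
        p = directory / f"expression_{tissue}.tsv"
        df.to_csv(p, sep="\t", na_rep="NA")
        paths[tissue] = p
    return paths


def read_traits(path: str | os.PathLike, min_n: int = 30) -> list[TraitTable]:
    """Read a traits TSV (first column = individual id, one column per trait)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    traits = []
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        non_numeric = df[col].notna() & vals.isna()
        if non_numeric.any():
            ind = df.index[non_numeric][0]
            raise ValueError(f"{path}: non-numeric cell at individual {ind!r}, trait {col!r}")
        traits.append(TraitTable(name=col, values=vals, min_n=min_n))
    return traits


def write_traits(traits: list[TraitTable], path: str | os.PathLike) -> None:
    df = pd.concat({t.name: t.values for t in traits}, axis=1)
    df.index.name = "individual"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_gene_list(path: str | os.PathLike, trait_class: str | None = None) -> KnownGeneList:
    """One gene id per line; blank lines and '#' comments ignored."""
    path = Path(path)
    genes = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return KnownGeneList(trait_class or path.stem, genes)


def write_gene_list(gene_list: KnownGeneList, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_list.genes):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------

def write_assoc_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an association table with the fixed column contract.

    Columns: id, chrom, pos_or_interval, method, trait, effect, r, stat, p,
    rank.  p is formatted with >= 6 significant digits.
    """
    df = records.copy()
    for col in ASSOC_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[ASSOC_COLUMNS]
    df["p"] = df["p"].map(lambda v: "" if pd.isna(v) else format(float(v), ".8g"))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_assoc_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "trait": str, "method": str})
    return df
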