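"""Transcriptome-wide association: single-tissue and multi-tissue models.

Single-tissue: for each gene passing the expression filter, ordinary least
squares of the trait on [intercept, expression, genetic PCs, hidden factors]
over complete-case individuals; the reported p is the two-sided t test on
the expression coefficient, and the reported r is the marginal Pearson
correlation between trait and expression.

Multi-tissue: a reduced model (intercept + PCs) is compared by a nested
F test (ANOVA) to a full model that adds one expression term per tissue in
which the gene is eligible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionTensor, TraitTable
from .covariates import CovariateSet

log = logging.getLogger(__name__)

P_FLOOR = 1e-300

__all__ = [
    "TwasRecord",
    "expression_filter",
    "run_twas_single",
    "run_twas_multitissue",
    "twas_records_to_frame",
]


@dataclass(frozen=True)
class TwasRecord:
    gene_id: str
    trait: str
    tissue: str  # tissue name or "multi"
    r: float     # marginal Pearson correlation (NaN for multi-tissue)
    p: float
    n: int
    covariate_tag: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.gene_id}: p = {self.p} outside (0, 1]")
        if not (math.isnan(self.r) or abs(self.r) <= 1.0 + 1e-12):
            raise ValueError(f"{self.gene_id}: |r| > 1")


def expression_filter(tensor: ExpressionTensor, tissue: str) -> list[str]:
    """Genes expressed (observed and > 0) in at least half of the tissue's
    individuals ("at least half" is inclusive: ceil(n/2))."""
    df = tensor.matrix(tissue)
    n = df.shape[1]
    need = math.ceil(n / 2)
    vals = df.to_numpy(dtype=float)
    expressed = (~np.isnan(vals)) & (vals > 0)
    keep = expressed.sum(axis=1) >= need
    return [g for g, k in zip(df.index, keep) if k]


def _ols_pvalue_last(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(beta, t, p) for the last column of X in OLS of y on X."""
    n, q = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < q:
        raise np.linalg.LinAlgError("rank-deficient design")
    r = y - X @ coef
    df = n - q
    sigma2 = float(r @ r) / df
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(max(sigma2 * XtX_inv[-1, -1], 1e-300))
    t = coef[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(coef[-1]), float(t), float(max(p, P_FLOOR))


def run_twas_single(
    tensor: ExpressionTensor,
    tissue: str,
    trait: TraitTable,
    covariates: CovariateSet | None = None,
    min_n_floor: int | None = None,
) -> list[TwasRecord]:
    """Per-gene expression association in one tissue (complete-case OLS)."""
    df = tensor.matrix(tissue)
    eligible = expression_filter(tensor, tissue)
    y_all = trait.observed()
    records = []
    k_cov = 0
    cov_all = None
    if covariates is not None:
        shared = [i for i in df.columns if i in y_all.index]
        cov_all = pd.DataFrame(
            covariates.design(shared, tissue=tissue), index=shared
        )
        k_cov = cov_all.shape[1]
    tag = f"pcs+factors[{k_cov}]" if k_cov else "none"
    min_needed = max(k_cov + 3, 3)
    for gene in eligible:
        x = df.loc[gene]
        mask = (~x.isna()) & x.index.isin(y_all.index)
        ids = list(x.index[mask])
        if cov_all is not None:
            cov_g = cov_all.reindex(ids)
            ok = ~cov_g.isna().any(axis=1)
            ids = list(cov_g.index[ok])
        if len(ids) < min_needed:
            log.info("run_twas_single: gene %s skipped (n=%d < %d)", gene, len(ids), min_needed)
            continue
        xv = x.reindex(ids).to_numpy(dtype=float)
        yv = y_all.reindex(ids).to_numpy(dtype=float)
        blocks = [np.ones((len(ids), 1))]
        if cov_all is not None and k_cov:
            blocks.append(cov_all.reindex(ids).to_numpy(dtype=float))
        blocks.append(xv[:, None])
        X = np.hstack(blocks)
        try:
            _, t, p = _ols_pvalue_last(X, yv)
        except np.linalg.LinAlgError:
            log.info("run_twas_single: gene %s skipped (rank-deficient design)", gene)
            continue
        if xv.std() > 0 and yv.std() > 0:
            r = float(np.corrcoef(xv, yv)[0, 1])
        else:
            r = float("nan")
        records.append(TwasRecord(gene, trait.name, tissue, r, p, len(ids), tag))
    return records


def run_twas_multitissue(
    tensor: ExpressionTensor,
    trait: TraitTable,
    covariates: CovariateSet | None = None,
    min_n_warn: int = 50,
) -> list[TwasRecord]:
    """Multi-tissue TWAS by nested-ANOVA model comparison.

    Reduced model: trait ~ 1 + PCs.  Full model adds one expression term per
    tissue in which the gene passes the expression filter.  Individuals are
    the complete-case intersection across the included tissues; a warning
    fires when that intersection drops below ``min_n_warn``.
    """
    y_all = trait.observed()
    eligible = {t: set(expression_filter(tensor, t)) for t in tensor.tissue_names}
    genes = sorted(set().union(*eligible.values())) if eligible else []
    records = []
    for gene in genes:
        tissues = [t for t in tensor.tissue_names if gene in eligible[t]]
        ids = set(y_all.index)
        for t in tissues:
            x = tensor.matrix(t).loc[gene]
            ids &= set(x.index[~x.isna()])
        ids = sorted(ids)
        k_pc = 0
        C = np.ones((len(ids), 1))
        if covariates is not None and covariates.pcs is not None:
            pcs = covariates.pcs.reindex(ids)
            ok = ~pcs.isna().any(axis=1)
            ids = list(pcs.index[ok])
            C = np.hstack([np.ones((len(ids), 1)), pcs.reindex(ids).to_numpy(dtype=float)])
            k_pc = pcs.shape[1]
        df1 = len(tissues)
        df2 = len(ids) - (1 + k_pc + df1)
        if df2 < 3:
            log.info("run_twas_multitissue: gene %s skipped (df2=%d)", gene, df2)
            continue
        if len(ids) < min_n_warn:
            log.warning(
                "run_twas_multitissue: gene %s tested on only %d individuals", gene, len(ids)
            )
        yv = y_all.reindex(ids).to_numpy(dtype=float)
        Xg = np.column_stack(
            [tensor.matrix(t).loc[gene].reindex(ids).to_numpy(dtype=float) for t in tissues]
        )
        X_full = np.hstack([C, Xg])
        coef_r, _, _, _ = np.linalg.lstsq(C, yv, rcond=None)
        rss_r = float(np.sum((yv - C @ coef_r) ** 2))
        coef_f, _, rank_f, _ = np.linalg.lstsq(X_full, yv, rcond=None)
        if rank_f < X_full.shape[1]:
            log.info("run_twas_multitissue: gene %s skipped (rank-deficient design)", gene)
            continue
        rss_f = float(np.sum((yv - X_full @ coef_f) ** 2))
        F = ((rss_r - rss_f) / df1) / (rss_f / df2)
        p = float(max(stats.f.sf(max(F, 0.0), df1, df2), P_FLOOR))
        records.append(TwasRecord(gene, trait.name, "multi", float("nan"), p,
                                  len(ids), f"pcs[{k_pc}]"))
    return records


def twas_records_to_frame(records: list[TwasRecord], method: str | None = None) -> pd.DataFrame:
    """Flatten TWAS records into the association-table column contract."""
    p = np.array([r.p for r in records], dtype=float)
    return pd.DataFrame({
        "id": [r.gene_id for r in records],
        "chrom": np.nan,
        "pos_or_interval": np.nan,
        "method": [method or ("twas_multi" if r.tissue == "multi" else f"twas_{r.tissue}")
                   for r in records],
        "trait": [r.trait for r in records],
        "effect": np.nan,
        "r": [r.r for r in records],
        "stat": np.nan,
        "p": p,
        "rank": (np.argsort(np.argsort(p)) + 1) if len(records) else [],
    })
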