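"""Per-variant association scans: naive GLM and kinship-aware mixed model.

The mixed linear model is y = X b + g + e with g ~ N(0, sg^2 K),
e ~ N(0, se^2 I).  The variance ratio delta = se^2 / sg^2 is estimated once
by REML under the no-SNP null (the P3D / EMMAX approximation), then every
variant is tested by generalized least squares through the eigendecomposition
of K.  An exact mode re-estimates delta per variant for cross-checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import GenotypePanel, TraitTable
from .covariates import KinshipMatrix

log = logging.getLogger(__name__)

P_FLOOR = 1e-300

__all__ = [
    "SnpAssocRecord",
    "run_glm_gwas",
    "run_mlm_gwas",
    "genomic_inflation",
    "records_to_frame",
]


@dataclass(frozen=True)
class SnpAssocRecord:
    variant_id: str
    chromosome: str
    position: int
    beta: float
    se: float
    stat: float
    p: float
    method: str  # "glm" | "mlm"

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant_id}: p = {self.p} outside (0, 1]")
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")


def _aligned(panel: GenotypePanel, trait: TraitTable, covariates):
    """Shared individuals with observed trait; returns (ids, y, G, C)."""
    obs = trait.observed()
    ids = [i for i in panel.individuals if i in obs.index]
    if covariates is not None:
        cov = np.asarray(pd.DataFrame(covariates).reindex(ids), dtype=float)
        keep = ~np.isnan(cov).any(axis=1)
        ids = [i for i, k in zip(ids, keep) if k]
    if len(ids) < 10:
        raise ValueError(f"only {len(ids)} shared individuals (< 10)")
    sub = panel.subset_individuals(ids)
    y = obs.reindex(ids).to_numpy(dtype=float)
    G = sub.imputed_dosages()
    C = np.ones((len(ids), 1))
    if covariates is not None:
        C = np.hstack([C, np.asarray(pd.DataFrame(covariates).reindex(ids), dtype=float)])
    return ids, y, G, C, sub


def _records(sub: GenotypePanel, beta, se, tstat, p, df, method, keep) -> list[SnpAssocRecord]:
    out = []
    var = sub.variants
    for j in np.flatnonzero(keep):
        out.append(SnpAssocRecord(
            variant_id=str(var["id"].iloc[j]),
            chromosome=str(var["chrom"].iloc[j]),
            position=int(var["pos"].iloc[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            stat=float(tstat[j]),
            p=float(max(p[j], P_FLOOR)),
            method=method,
        ))
    return out


def run_glm_gwas(
    panel: GenotypePanel,
    trait: TraitTable,
    covariates=None,
) -> list[SnpAssocRecord]:
    """Ordinary least squares of the trait on each variant's dosage.

    Covariates (plus an intercept) are projected out of both the trait and
    the dosages (Frisch–Waugh), which reproduces the full-model slope, t
    statistic and two-sided p exactly.  Variants with constant dosage in
    the analysis set are skipped with a log entry.
    """
    ids, y, G, C, sub = _aligned(panel, trait, covariates)
    n, q = C.shape
    proj = np.linalg.lstsq(C, np.column_stack([y, G]), rcond=None)[0]
    resid = np.column_stack([y, G]) - C @ proj
    yr, Gr = resid[:, 0], resid[:, 1:]
    gss = (Gr ** 2).sum(axis=0)
    keep = gss > 1e-12 * n
    n_skip = int((~keep).sum())
    if n_skip:
        log.info("run_glm_gwas: skipped %d constant-dosage variants", n_skip)
    df = n - q - 1
    gy = Gr.T @ yr
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = gy / gss
        rss = (yr ** 2).sum() - beta * gy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(np.maximum(sigma2 / gss, 1e-300))
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    return _records(sub, beta, se, tstat, p, df, "glm", keep)


def _reml_neg_loglik_delta(log_delta, S, Xs, ys):
    """Negative restricted log-likelihood in the rotated basis, profile sg^2."""
    delta = np.exp(log_delta)
    w = 1.0 / (S + delta)
    Xw = Xs * w[:, None]
    A = Xs.T @ Xw
    b = Xw.T @ ys
    coef = np.linalg.solve(A, b)
    r = ys - Xs @ coef
    rss = float(np.sum(w * r * r))
    n, q = Xs.shape
    df = n - q
    sg2 = rss / df
    _, logdet_A = np.linalg.slogdet(A)
    ll = -0.5 * (df * np.log(sg2) + np.sum(np.log(S + delta)) + logdet_A + df)
    return -ll


def run_mlm_gwas(
    panel: GenotypePanel,
    trait: TraitTable,
    kinship: KinshipMatrix,
    covariates=None,
    exact_delta: bool = False,
) -> list[SnpAssocRecord]:
    """Mixed-model association scan with a single REML variance ratio.

    ``exact_delta=True`` re-estimates delta per variant (slow; used for
    cross-checks).
    """
    ids, y, G, C, sub = _aligned(panel, trait, covariates)
    K = kinship.subset(ids).values
    S, U = np.linalg.eigh(K)
    if S[0] < -1e-6:
        raise ValueError(f"kinship has eigenvalue {S[0]:.3g} beyond ridge tolerance")
    S = np.clip(S, 0.0, None)
    ys = U.T @ y
    Cs = U.T @ C
    Gs = U.T @ G
    res = optimize.minimize_scalar(
        _reml_neg_loglik_delta, bounds=(-12.0, 12.0), method="bounded",
        args=(S, Cs, ys), options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    n, q = Cs.shape
    df = n - q - 1

    gss_raw = ((G - G.mean(axis=0)) ** 2).sum(axis=0)
    keep = gss_raw > 1e-12 * n
    n_skip = int((~keep).sum())
    if n_skip:
        log.info("run_mlm_gwas: skipped %d constant-dosage variants", n_skip)

    if exact_delta:
        beta = np.zeros(G.shape[1]); se = np.ones(G.shape[1])
        tstat = np.zeros(G.shape[1]); p = np.ones(G.shape[1])
        for j in np.flatnonzero(keep):
            Xs = np.column_stack([Cs, Gs[:, j]])
            r = optimize.minimize_scalar(
                _reml_neg_loglik_delta, bounds=(-12.0, 12.0), method="bounded",
                args=(S, Xs, ys), options={"xatol": 1e-8},
            )
            b, s_, t_, p_ = _gls_single(S, float(np.exp(r.x)), Cs, Gs[:, j], ys)
            beta[j], se[j], tstat[j], p[j] = b, s_, t_, p_
        return _records(sub, beta, se, tstat, p, df, "mlm", keep)

    w = 1.0 / (S + delta)
    Cw = Cs * w[:, None]
    A = Cs.T @ Cw                      # q x q
    Ainv = np.linalg.inv(A)
    b0 = Cw.T @ ys                     # q
    yy = float(np.sum(w * ys * ys))
    rss0 = yy - b0 @ Ainv @ b0
    ug = Cw.T @ Gs                     # q x m
    dg = np.sum(w[:, None] * Gs * Gs, axis=0)
    cg = Gs.T @ (w * ys)
    v = Ainv @ ug                      # q x m
    denom = dg - np.sum(ug * v, axis=0)
    num = cg - b0 @ v
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = num / denom
        rss = np.maximum(rss0 - num * num / denom, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2 / denom, 1e-300))
        tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
    keep &= denom > 1e-12
    return _records(sub, beta, se, tstat, p, df, "mlm", keep)


def _gls_single(S, delta, Cs, gs, ys):
    w = 1.0 / (S + delta)
    Xs = np.column_stack([Cs, gs])
    Xw = Xs * w[:, None]
    A = Xs.T @ Xw
    coef = np.linalg.solve(A, Xw.T @ ys)
    r = ys - Xs @ coef
    rss = float(np.sum(w * r * r))
    n, q = Xs.shape
    df = n - q
    sigma2 = rss / df
    Ainv = np.linalg.inv(A)
    se = float(np.sqrt(sigma2 * Ainv[-1, -1]))
    t = coef[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(coef[-1]), se, float(t), float(p)


def genomic_inflation(records: list[SnpAssocRecord] | np.ndarray) -> float:
    """Genomic inflation factor: median association chi^2 over its null median."""
    if isinstance(records, (list, tuple)):
        p = np.array([r.p for r in records], dtype=float)
    else:
        p = np.asarray(records, dtype=float)
    if p.size < 100:
        raise ValueError(f"need >= 100 records, got {p.size}")
    if np.any(p <= 0):
        raise ValueError("non-positive p-value")
    chi2 = stats.chi2.isf(np.minimum(p, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def records_to_frame(records: list[SnpAssocRecord], trait: str, method: str | None = None) -> pd.DataFrame:
    """Flatten records into the association-table column contract."""
    return pd.DataFrame({
        "id": [r.variant_id for r in records],
        "chrom": [r.chromosome for r in records],
        "pos_or_interval": [r.position for r in records],
        "method": [method or r.method for r in records],
        "trait": trait,
        "effect": [r.beta for r in records],
        "r": np.nan,
        "stat": [r.stat for r in records],
        "p": [r.p for r in records],
        "rank": np.argsort(np.argsort([r.p for r in records])) + 1,
    })
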