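"""Kinship matrices, genetic MDS principal coordinates, hidden expression factors.

The kinship is the VanRaden method-1 genomic relationship matrix
K = W W' / c with W the column-centred dosage matrix and
c = sum_j 2 p_j (1 - p_j).  Population-structure covariates are classical
MDS principal coordinates of the 1 - IBS genotype distance matrix.  Hidden
expression-wide confounders are estimated as residualized truncated-SVD
factors — a deterministic surrogate for PEER that the downstream models
consume identically (as fixed covariates); precomputed factors can be
substituted via the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypePanel

__all__ = [
    "KinshipMatrix",
    "CovariateSet",
    "compute_kinship",
    "compute_mds_pcs",
    "estimate_hidden_factors",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


@dataclass
class KinshipMatrix:
    individuals: list[str]
    values: np.ndarray  # (n, n) symmetric PSD

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.individuals), len(self.individuals)):
            raise ValueError("kinship shape does not match individual count")
        if np.abs(v - v.T).max(initial=0.0) > 1e-10:
            raise ValueError("kinship matrix not symmetric within 1e-10")
        self.values = (v + v.T) / 2.0

    def subset(self, ids) -> "KinshipMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        rows = [pos[i] for i in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(rows, rows)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class CovariateSet:
    """Fixed covariates for the association models.

    ``pcs`` holds genetic MDS principal coordinates (n x k_pc);
    ``factors`` holds per-tissue hidden expression factors (n x k_f each).
    All columns are centred.
    """

    individuals: list[str]
    pcs: pd.DataFrame | None = None                       # index = individuals
    factors: dict[str, pd.DataFrame] = field(default_factory=dict)

    def design(self, ids, tissue: str | None = None) -> np.ndarray:
        """Covariate block (no intercept) aligned to ``ids``; NaN where unknown."""
        blocks = []
        if self.pcs is not None:
            blocks.append(self.pcs.reindex(ids).to_numpy())
        if tissue is not None and tissue in self.factors:
            blocks.append(self.factors[tissue].reindex(ids).to_numpy())
        if not blocks:
            return np.empty((len(ids), 0))
        return np.hstack(blocks)


def compute_kinship(panel: GenotypePanel, variant_subset=None) -> KinshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are mean-imputed per variant for the matrix algebra
    only.  Raises if every included variant is monomorphic (denominator 0).
    """
    if variant_subset is not None:
        panel = panel.subset_variants(variant_subset)
    if panel.n_variants < 1:
        raise ValueError("kinship requires at least one variant")
    d = panel.imputed_dosages()
    p = d.mean(axis=0) / 2.0
    c = float(np.sum(2.0 * p * (1.0 - p)))
    if c <= 0:
        raise ValueError("all included variants are monomorphic (VanRaden denominator 0)")
    w = d - 2.0 * p
    k = (w @ w.T) / c
    return KinshipMatrix(list(panel.individuals), k)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: each column's largest-|entry| is positive."""
    coords = coords.copy()
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def ibs_distance(panel: GenotypePanel) -> np.ndarray:
    """1 - IBS distance matrix; IBS is the mean shared-allele fraction over
    pairwise non-missing variants."""
    d = panel.dosages
    n = panel.n_individuals
    obs = ~np.isnan(d)
    d0 = np.where(obs, d, 0.0)
    dist = np.zeros((n, n))
    # |d_i - d_j| / 2 averaged over shared non-missing sites
    for i in range(n):
        diff = np.abs(d0[i] - d0)          # (n, m)
        shared = obs[i] & obs
        num = np.where(shared, diff, 0.0).sum(axis=1)
        den = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.where(den > 0, num / (2.0 * den), 0.0)
    return (dist + dist.T) / 2.0


def compute_mds_pcs(panel: GenotypePanel, k: int = 5,
                    distance: np.ndarray | None = None) -> pd.DataFrame:
    """Classical MDS principal coordinates of the 1 - IBS distance matrix.

    Double-centres -D^2/2 and eigendecomposes; coordinates are ordered by
    eigenvalue with a deterministic sign convention.
    """
    n = panel.n_individuals
    if n < 3:
        raise ValueError("MDS requires at least 3 individuals")
    if k > n - 1:
        raise ValueError(f"k = {k} exceeds n - 1 = {n - 1}")
    D = ibs_distance(panel) if distance is None else np.asarray(distance, dtype=float)
    B = D ** 2
    B = -0.5 * (B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean())
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    coords = _fix_signs(coords)
    return pd.DataFrame(coords, index=panel.individuals,
                        columns=[f"PC{i + 1}" for i in range(k)])


def estimate_hidden_factors(
    expression: pd.DataFrame,
    known_covariates: np.ndarray | pd.DataFrame | None = None,
    k: int = 25,
) -> pd.DataFrame:
    """Hidden expression-wide factors for one tissue.

    Genes are z-scored over observed entries (missing set to 0 after
    standardization), the matrix is residualized on the known covariates,
    and the top-k left singular vectors of the individuals x genes matrix
    are returned.  Deterministic; sign convention as in MDS.

    Parameters
    ----------
    expression
        genes x individuals matrix (NaN = unobserved).
    known_covariates
        optional n x q block (e.g. genetic PCs) projected out first.
    k
        number of factors; must not exceed the matrix rank.
    """
    X = expression.to_numpy(dtype=float).T  # individuals x genes
    individuals = list(expression.columns)
    obs = ~np.isnan(X)
    keep = obs.sum(axis=0) >= 3
    X = X[:, keep]
    obs = obs[:, keep]
    n = X.shape[0]
    if k > min(n, X.shape[1]) - 1:
        raise ValueError(f"k = {k} exceeds min(n, genes) - 1")
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd
    Z[~obs] = 0.0
    # always residualize on the intercept so factors are exactly centred
    C = np.ones((n, 1))
    if known_covariates is not None:
        C = np.hstack([C, np.asarray(known_covariates, dtype=float)])
    Z = Z - C @ np.linalg.lstsq(C, Z, rcond=None)[0]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    if k > int((s > s[0] * 1e-12).sum() if s.size else 0):
        raise ValueError(f"k = {k} exceeds the rank of the residualized matrix")
    F = _fix_signs(U[:, :k])
    return pd.DataFrame(F, index=individuals, columns=[f"factor{i + 1}" for i in range(k)])


def write_matrix_tsv(df_or_kinship, path) -> None:
    if isinstance(df_or_kinship, KinshipMatrix):
        df = pd.DataFrame(df_or_kinship.values,
                          index=df_or_kinship.individuals,
                          columns=df_or_kinship.individuals)
    else:
        df = df_or_kinship
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
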