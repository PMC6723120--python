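"""Shared fixtures: small deterministic synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensemblemap.containers import GenotypePanel, TraitTable
from ensemblemap.covariates import CovariateSet, compute_kinship, compute_mds_pcs, estimate_hidden_factors
from ensemblemap.simulate import (
    SimulationConfig,
    place_genes,
    simulate_expression,
    simulate_panel,
    simulate_trait,
)


def random_panel(rng: np.random.Generator, n: int = 20, m: int = 50,
                 inbred: bool = True, missing_rate: float = 0.0) -> GenotypePanel:
    """Small random panel for oracle-style tests (not the generator)."""
    if inbred:
        d = rng.choice([0.0, 2.0], size=(n, m))
    else:
        d = rng.choice([0.0, 1.0, 2.0], size=(n, m))
    if missing_rate > 0:
        d[rng.random((n, m)) < missing_rate] = np.nan
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(m)],
        "chrom": [f"chr{1 + j % 2}" for j in range(m)],
        "pos": [100 + 10 * j for j in range(m)],
        "ref": "A",
        "alt": "T",
    })
    return GenotypePanel([f"i{k}" for k in range(n)], variants, d)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        seed=42, n_panel=120, n_variants=600, n_genes=60, n_tissues=3,
        n_per_family=60, n_families=3, n_causal_regulatory=3, n_causal_coding=3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """Panel + genes + expression + one trait with truth, simulated once."""
    panel, subpops = simulate_panel(small_cfg)
    genes = place_genes(small_cfg)
    tensor, cis, meta = simulate_expression(small_cfg, panel, genes, subpops)
    trait, truth = simulate_trait(small_cfg, panel, genes, cis, meta, subpops=subpops)
    return {
        "cfg": small_cfg, "panel": panel, "subpops": subpops, "genes": genes,
        "tensor": tensor, "cis": cis, "meta": meta, "trait": trait, "truth": truth,
    }


@pytest.fixture(scope="session")
def small_covariates(small_dataset):
    panel = small_dataset["panel"]
    tensor = small_dataset["tensor"]
    pcs = compute_mds_pcs(panel, k=5)
    factors = {t: estimate_hidden_factors(tensor.matrix(t), pcs, k=10)
               for t in tensor.tissue_names}
    return CovariateSet(panel.individuals, pcs=pcs, factors=factors)


@pytest.fixture(scope="session")
def small_kinship(small_dataset):
    return compute_kinship(small_dataset["panel"])
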