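#!/usr/bin/env python
"""Simulate the study-scale synthetic dataset used by the downstream steps.

Emulates the study design at desk scale: a structured diversity panel of 300
inbred lines genotyped at 4,000 variants, expression for 500 genes in 7
tissues with cis regulation / hidden confounders / dropout, 5 traits with a
half-regulatory half-coding causal architecture at h2 = 0.6, and 5 NAM-like
RIL families of 200 lines for independent validation.

Writes results/dataset/ (genotypes, expression, traits, annotation, truth).
"""

from pathlib import Path

import pandas as pd

from ensemblemap.pipeline import run_simulate
from ensemblemap.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "dataset"


def main() -> None:
    cfg = SimulationConfig(seed=2001)
    out = run_simulate(cfg, OUT, n_traits=5)
    truth = pd.read_csv(out / "truth.tsv", sep="\t")
    print(f"dataset written to {out}")
    print(f"  panel: {cfg.n_panel} inbreds, {cfg.n_variants} variants, "
          f"{cfg.n_genes} genes, {cfg.n_tissues} tissues")
    print(f"  NAM: {cfg.n_families} families x {cfg.n_per_family} RILs")
    print(f"  traits: {truth['trait'].nunique()}, causal genes per trait: "
          f"{truth.groupby('trait').size().iloc[0]}")
    print(f"  realized h2 by trait:\n{truth.groupby('trait')['realized_h2'].first()}")


if __name__ == "__main__":
    main()
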