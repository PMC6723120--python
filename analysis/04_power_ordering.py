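#!/usr/bin/env python
"""Detection-power comparison: Fisher ensemble vs GWAS alone vs TWAS alone.

Simulates replicate sets of 20 traits (10 causal genes each, half regulatory
and half coding, h2 = 0.6) and counts causal genes recovered in the top 1%
of each method's gene ranking — the synthetic analogue of the known-gene
detection tables.

Writes results/power_ordering.tsv.
"""

from pathlib import Path

from ensemblemap.experiments import power_ordering

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    power = power_ordering(seed=4001, n_replicates=5, n_traits=20)
    out = ROOT / "results" / "power_ordering.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    power.per_replicate.to_csv(out, sep="\t", index=False)
    d = power.per_replicate
    print(d.to_string(index=False))
    print(f"\nmean detections per 20-trait set: "
          f"GWAS {d['gwas'].mean():.1f}, TWAS {d['twas'].mean():.1f}, "
          f"Fisher {d['fisher'].mean():.1f}")
    print(f"Fisher >= GWAS in {power.fisher_ge_gwas_fraction:.0%} of sets; "
          f"Fisher >= TWAS in {power.fisher_ge_twas_fraction:.0%}")
    print(f"regulatory causal genes found by TWAS but missed by GWAS: "
          f"{power.twas_only_regulatory_total}")


if __name__ == "__main__":
    main()
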