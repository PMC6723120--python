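"""Rank-based scoring: recovery of known genes in the top 1% of associations.

Detection is deliberately rank-based rather than threshold-based: a known
gene counts as detected each time it appears in the top 1% of the genes a
method ranked for a trait, which keeps differently powered tests comparable
without comparing p-values across methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .containers import KnownGeneList

__all__ = ["DetectionTally", "rank_genes", "count_detections", "tally_methods"]


@dataclass
class DetectionTally:
    method: str
    trait_class: str
    total: int
    unique_genes: set[str]
    per_trait: dict[str, set[str]] = field(default_factory=dict)

    @property
    def unique(self) -> int:
        return len(self.unique_genes)


def rank_genes(records: pd.DataFrame) -> list[str]:
    """Gene ids ordered by ascending p, ties broken by gene id.

    ``records`` needs columns ``id`` and ``p`` with one row per gene.
    """
    if records["id"].duplicated().any():
        dup = records.loc[records["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r} in ranking input")
    ordered = records.sort_values(["p", "id"], kind="mergesort")
    return list(ordered["id"])


def count_detections(
    ranked_genes: list[str], known: KnownGeneList, top_fraction: float = 0.01
) -> set[str]:
    """Known genes inside the top ceil(top_fraction * n) of the ranking
    (minimum top-set size 1)."""
    if not ranked_genes:
        raise ValueError("ranked gene list is empty")
    k = max(math.ceil(top_fraction * len(ranked_genes)), 1)
    return set(ranked_genes[:k]) & known.genes


def tally_methods(
    records_by_method_trait: dict[str, dict[str, pd.DataFrame]],
    known: KnownGeneList,
    top_fraction: float = 0.01,
    common_universe: bool = False,
) -> dict[str, DetectionTally]:
    """Total and unique known-gene detections per method across traits.

    ``records_by_method_trait[method][trait]`` is a per-gene table with
    columns ``id, p``.  All methods must cover the same trait set.  With
    ``common_universe=True`` every method is restricted to the genes ranked
    by *all* methods for that trait, so the top-1% cut k is identical.
    """
    methods = list(records_by_method_trait)
    trait_sets = {m: set(records_by_method_trait[m]) for m in methods}
    all_traits = set().union(*trait_sets.values()) if methods else set()
    for m in methods:
        missing = all_traits - trait_sets[m]
        if missing:
            raise ValueError(f"method {m!r} missing trait(s) {sorted(missing)}")
    tallies = {}
    for m in methods:
        total = 0
        uniq: set[str] = set()
        per_trait = {}
        for trait in sorted(all_traits):
            recs = records_by_method_trait[m][trait]
            if common_universe:
                universe = set(recs["id"])
                for m2 in methods:
                    universe &= set(records_by_method_trait[m2][trait]["id"])
                recs = recs[recs["id"].isin(universe)]
            detected = count_detections(rank_genes(recs), known, top_fraction)
            total += len(detected)
            uniq |= detected
            per_trait[trait] = detected
        tallies[m] = DetectionTally(m, known.trait_class, total, uniq, per_trait)
    return tallies


def tally_to_frame(tallies: dict[str, DetectionTally]) -> pd.DataFrame:
    return pd.DataFrame({
        "method": list(tallies),
        "trait_class": [t.trait_class for t in tallies.values()],
        "total_detections": [t.total for t in tallies.values()],
        "unique_genes": [t.unique for t in tallies.values()],
    })
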