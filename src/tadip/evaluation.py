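"""Rank-level scoring of read assignments against simulator truth.

At each taxonomic rank a read counts as a true positive when any of its
assigned genomes shares the true genome's taxon at that rank, and as a
false positive when any assigned genome's taxon differs.  Both fractions
are taken over the total number of reads, so a multiply-assigned read can
contribute to both counts and TP + FP can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .alignment_io import RANKS, TaxonomyTable
from .synthetic_data import TruthTable

__all__ = ["RankReport", "confusion_at_ranks"]


@dataclass
class RankReport:
    """TP/FP fractions per taxonomic rank."""

    tp: dict[str, float]
    fp: dict[str, float]
    n_reads: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": list(RANKS),
                "tp": [self.tp[r] for r in RANKS],
                "fp": [self.fp[r] for r in RANKS],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def confusion_at_ranks(
    assignments: Mapping[str, Mapping[str, float]],
    truth: TruthTable,
    taxonomy: TaxonomyTable,
) -> RankReport:
    """Score assignments against truth at every rank.

    ``assignments`` maps each read to its assigned genome(s) (posterior
    values are ignored here; membership is what counts).  An ``"unknown"``
    taxon never matches anything, at either end: it always scores as an
    incorrect assignment.
    """
    for read_id, genome_id in truth.true_genome.items():
        if genome_id not in taxonomy:
            raise KeyError(f"true genome {genome_id!r} missing from taxonomy")
    n = len(truth)
    if n == 0:
        raise ValueError("empty truth table")
    tp_counts = {r: 0 for r in RANKS}
    fp_counts = {r: 0 for r in RANKS}
    for read_id, genome_id in truth.true_genome.items():
        true_lineage = taxonomy.lineage(genome_id)
        assigned = assignments.get(read_id, {})
        assigned_lineages = []
        for g in assigned:
            if g not in taxonomy:
                raise KeyError(f"assigned genome {g!r} missing from taxonomy")
            assigned_lineages.append(taxonomy.lineage(g))
        for ri, rank in enumerate(RANKS):
            true_taxon = true_lineage[ri]
            hit = any(
                lin[ri] == true_taxon and true_taxon != "unknown"
                for lin in assigned_lineages
            )
            miss = any(
                lin[ri] != true_taxon or true_taxon == "unknown"
                for lin in assigned_lineages
            )
            if hit:
                tp_counts[rank] += 1
            if miss:
                fp_counts[rank] += 1
    return RankReport(
        tp={r: tp_counts[r] / n for r in RANKS},
        fp={r: fp_counts[r] / n for r in RANKS},
        n_reads=n,
    )
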