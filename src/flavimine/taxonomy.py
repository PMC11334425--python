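"""Taxonomic distribution tables for mined features.

Counts are per genome: a genome with four candidate proteins contributes
one to its phylum's numerator, matching distribution-over-taxa panels.
Protein-level counts are emitted alongside for transparency.
"""

from __future__ import annotations

from typing import Callable

import pandas as pd

from .genome_io import RANKS, GenomeRecord


def tabulate(
    genomes: list[GenomeRecord],
    feature_counts: dict[str, int] | Callable[[GenomeRecord], int],
    rank: str = "phylum",
) -> pd.DataFrame:
    """Per-taxon genome counts for a feature.

    ``feature_counts`` maps genome_id to the number of feature occurrences
    (or is a callable computing it); a genome counts toward ``n_with``
    when the count is positive, once, regardless of copy number.
    Columns: taxon, n_genomes_with_feature, n_genomes_total, fraction,
    n_feature_proteins.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown taxonomic rank {rank!r}")
    counter = (
        feature_counts
        if callable(feature_counts)
        else lambda g: feature_counts.get(g.genome_id, 0)
    )
    rows: dict[str, dict[str, int]] = {}
    for genome in genomes:
        taxon = genome.rank(rank)
        entry = rows.setdefault(
            taxon, {"n_with": 0, "n_total": 0, "n_proteins": 0}
        )
        n = counter(genome)
        entry["n_total"] += 1
        entry["n_proteins"] += n
        if n > 0:
            entry["n_with"] += 1
    table = pd.DataFrame(
        [
            {
                "rank": rank,
                "taxon": taxon,
                "n_genomes_with_feature": e["n_with"],
                "n_genomes_total": e["n_total"],
                "fraction": e["n_with"] / e["n_total"],
                "n_feature_proteins": e["n_proteins"],
            }
            for taxon, e in sorted(rows.items())
        ],
        columns=[
            "rank", "taxon", "n_genomes_with_feature", "n_genomes_total",
            "fraction", "n_feature_proteins",
        ],
    )
    return table
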