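"""Per-column conservation statistics from a multiple sequence alignment.

Information content per column is log2(20) - H(p), with p the residue
frequencies among non-gap characters — the quantity drawn as letter
heights in a sequence logo.  Near-invariant columns of a chosen residue
type (the conserved heme-coordinating histidines of transmembrane
cytochromes, the flavinylated threonines of Nqr/Rnf membrane subunits)
are located with `top_conserved` and mapped back to ungapped residue
numbers of a reference sequence for structural cross-referencing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

MAX_IC_BITS = float(np.log2(20))
GAP_CHARS = set("-.")
LOW_OCCUPANCY = 0.5


@dataclass
class AlignmentColumn:
    index: int  # 1-based column number
    counts: dict[str, int]
    gap_count: int
    occupancy: float
    ic_bits: float | None  # None when the column is all-gap
    consensus: str | None
    low_occupancy: bool


def read_msa(path: str | Path) -> dict[str, str]:
    """Aligned FASTA -> {row id: aligned sequence (upper-case)}."""
    alignment = AlignIO.read(str(path), "fasta")
    rows = {rec.id: str(rec.seq).upper() for rec in alignment}
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    return rows


def column_stats(msa: dict[str, str], column: int) -> AlignmentColumn:
    """Statistics for one 1-based column.

    Gaps are excluded from the frequency vector (not a 21st symbol).
    Consensus is the most frequent residue, ties broken alphabetically.
    """
    chars = [row[column - 1] for row in msa.values()]
    residues = [c for c in chars if c not in GAP_CHARS and c != "X"]
    gap_count = len(chars) - len(residues)
    occupancy = len(residues) / len(chars) if chars else 0.0
    counts = Counter(residues)
    if not residues:
        return AlignmentColumn(column, {}, gap_count, 0.0, None, None, True)
    freqs = np.array(list(counts.values()), dtype=float)
    freqs /= freqs.sum()
    entropy = -np.sum(freqs * np.log2(freqs))
    ic = MAX_IC_BITS - float(entropy)
    consensus = min(counts, key=lambda aa: (-counts[aa], aa))
    return AlignmentColumn(
        index=column,
        counts=dict(counts),
        gap_count=gap_count,
        occupancy=occupancy,
        ic_bits=ic,
        consensus=consensus,
        low_occupancy=occupancy < LOW_OCCUPANCY,
    )


def all_column_stats(msa: dict[str, str]) -> list[AlignmentColumn]:
    n_cols = len(next(iter(msa.values()))) if msa else 0
    return [column_stats(msa, c) for c in range(1, n_cols + 1)]


def top_conserved(
    msa: dict[str, str],
    residue_filter: set[str],
    min_ic: float = 3.0,
    min_occupancy: float = LOW_OCCUPANCY,
) -> list[int]:
    """Column indices whose consensus is in the filter and whose IC and
    occupancy clear the thresholds, sorted by IC descending."""
    keep = [
        col
        for col in all_column_stats(msa)
        if col.ic_bits is not None
        and col.consensus in residue_filter
        and col.ic_bits >= min_ic
        and col.occupancy >= min_occupancy
    ]
    keep.sort(key=lambda c: (-c.ic_bits, c.index))
    return [c.index for c in keep]


def map_column_to_structure(
    msa: dict[str, str], reference_id: str, column: int
) -> int | None:
    """Ungapped 1-based residue index of an alignment column in the
    reference row; None where the reference is gapped."""
    if reference_id not in msa:
        raise KeyError(f"reference row {reference_id!r} not in alignment")
    row = msa[reference_id]
    if row[column - 1] in GAP_CHARS:
        return None
    return sum(1 for c in row[:column] if c not in GAP_CHARS)


def stats_to_frame(columns: list[AlignmentColumn]) -> pd.DataFrame:
    rows = [
        {
            "column": c.index,
            "occupancy": round(c.occupancy, 6),
            "ic_bits": round(c.ic_bits, 6) if c.ic_bits is not None else float("nan"),
            "consensus": c.consensus or ".",
            "low_occupancy": c.low_occupancy,
        }
        for c in columns
    ]
    return pd.DataFrame(rows, columns=["column", "occupancy", "ic_bits", "consensus", "low_occupancy"])


def plot_logo(columns: list[AlignmentColumn], path: str | Path) -> None:
    """Logo-style stacked-bar plot: per column, residue letters scaled by
    their share of the column's information content."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, len(columns) * 0.25), 3))
    for col in columns:
        if col.ic_bits is None:
            continue
        total = sum(col.counts.values())
        bottom = 0.0
        for aa, n in sorted(col.counts.items(), key=lambda kv: kv[1]):
            height = col.ic_bits * n / total
            ax.bar(col.index, height, bottom=bottom, width=0.9)
            if height > 0.4:
                ax.text(col.index, bottom + height / 2, aa, ha="center",
                        va="center", fontsize=7)
            bottom += height
    ax.set_xlabel("alignment column")
    ax.set_ylabel("information (bits)")
    ax.set_ylim(0, MAX_IC_BITS)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
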