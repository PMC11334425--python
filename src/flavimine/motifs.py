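"""Flavinylation-motif scanning and candidate substrate calling.

ApbE flavinylates the final serine/threonine of a degenerate
[S/T]GA[S/T] motif.  This module finds all motif matches in protein
sequences (overlaps allowed), promotes co-localized motif-bearing
proteins of the right family to candidate flavinylation substrates, and
supports the in-silico analogue of the alanine point mutation used to
ablate a predicted site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .neighborhood import NeighborhoodCluster

MULTI_FLAVINYLATION_MIN_SITES = 3  # ">2 FMN-bind domains" convention


@dataclass
class MotifPattern:
    """Degenerate motif: one allowed-residue set per position.

    ``flavinylated_offset`` indexes the covalently modified residue within
    the match (default: the final S/T of [S/T]GA[S/T]).
    """

    pattern_id: str = "STGAST"
    positions: list[frozenset[str]] = field(
        default_factory=lambda: [
            frozenset("ST"), frozenset("G"), frozenset("A"), frozenset("ST"),
        ]
    )
    flavinylated_offset: int = 3

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pattern needs at least one position")
        if not 0 <= self.flavinylated_offset < len(self.positions):
            raise ValueError("flavinylated_offset outside pattern")
        self.positions = [frozenset(p) for p in self.positions]

    def __len__(self) -> int:
        return len(self.positions)

    def matches(self, window: str) -> bool:
        return len(window) == len(self.positions) and all(
            aa in allowed for aa, allowed in zip(window, self.positions)
        )


@dataclass(frozen=True)
class MotifSite:
    """One motif match; positions are 1-based on the protein."""

    protein_id: str
    start: int
    matched: str
    flavinylated_pos: int


@dataclass
class CandidateCall:
    """A protein promoted to candidate flavinylation substrate."""

    protein_id: str
    accession: str
    n_sites: int
    cluster_idx: int
    genome_id: str
    anchor_gene: str
    multi_flavinylated: bool = False

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("a candidate must carry at least one motif site")
        self.multi_flavinylated = self.n_sites >= MULTI_FLAVINYLATION_MIN_SITES


def scan_motifs(
    seq: str, pattern: MotifPattern | None = None, protein_id: str = ""
) -> list[MotifSite]:
    """All motif matches at step 1, overlaps allowed, ascending start.

    'X' (or any letter outside a position's allowed set) never matches.
    """
    if pattern is None:
        pattern = MotifPattern()
    seq = seq.upper()
    length = len(pattern)
    sites = []
    for i in range(len(seq) - length + 1):
        if pattern.matches(seq[i : i + length]):
            sites.append(
                MotifSite(
                    protein_id=protein_id,
                    start=i + 1,
                    matched=seq[i : i + length],
                    flavinylated_pos=i + 1 + pattern.flavinylated_offset,
                )
            )
    return sites


def scan_proteome(
    proteome: dict[str, str], pattern: MotifPattern | None = None
) -> dict[str, list[MotifSite]]:
    return {
        pid: sites
        for pid, seq in proteome.items()
        if (sites := scan_motifs(seq, pattern, protein_id=pid))
    }


def call_candidates(
    clusters: list[NeighborhoodCluster],
    sites_by_protein: dict[str, list[MotifSite]],
    target_families: set[str],
) -> list[CandidateCall]:
    """Promote proteins to candidates: in an anchor window, best-match
    family among the targets, and at least one motif site.

    A protein in several windows yields one call per window (clusters are
    never merged); callers deduplicate by protein_id when counting unique
    candidates.
    """
    calls: list[CandidateCall] = []
    for idx, cluster in enumerate(clusters):
        for family in sorted(target_families):
            for pid in cluster.family_content.get(family, []):
                sites = sites_by_protein.get(pid, [])
                if not sites:
                    continue
                calls.append(
                    CandidateCall(
                        protein_id=pid,
                        accession=family,
                        n_sites=len(sites),
                        cluster_idx=idx,
                        genome_id=cluster.genome_id,
                        anchor_gene=cluster.anchor.gene_id,
                    )
                )
    return calls


def mutate_site(seq: str, site: MotifSite, replacement: str = "A") -> str:
    """Substitute the flavinylated residue (alanine by default).

    Re-scanning the mutant yields no match at the site's start as long as
    the replacement is outside the allowed set at that motif position.
    """
    pos = site.flavinylated_pos
    if not 1 <= pos <= len(seq):
        raise ValueError(f"site position {pos} outside sequence (len {len(seq)})")
    return seq[: pos - 1] + replacement + seq[pos:]


def sites_to_frame(sites_by_protein: dict[str, list[MotifSite]]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": s.protein_id,
            "start": s.start,
            "matched": s.matched,
            "flavinylated_pos": s.flavinylated_pos,
        }
        for sites in sites_by_protein.values()
        for s in sites
    ]
    return pd.DataFrame(rows, columns=["protein_id", "start", "matched", "flavinylated_pos"])


def candidates_to_frame(calls: list[CandidateCall]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": c.protein_id,
            "family": c.accession,
            "n_sites": c.n_sites,
            "multi_flavinylated": c.multi_flavinylated,
            "cluster_idx": c.cluster_idx,
            "genome_id": c.genome_id,
            "anchor_gene": c.anchor_gene,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "family", "n_sites", "multi_flavinylated",
            "cluster_idx", "genome_id", "anchor_gene",
        ],
    )
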