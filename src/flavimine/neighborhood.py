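"""Gene-neighborhood mining: +/-k windows around anchor-family genes.

The core comparative-genomics operation: for every gene whose protein is
annotated with the anchor family (canonically the FMN transferase ApbE,
or any candidate family when anchoring the other way around), collect the
k genes upstream and downstream on the same contig (default k=5) and
flag which target families occur in the window.  Windows are counted in
genes, clipped at contig ends, and never merged when they overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .domain_annotation import DomainHit
from .genome_io import GeneRecord, GenomeRecord

DEFAULT_WINDOW_K = 5


@dataclass
class NeighborhoodCluster:
    """An anchor gene with its ordinal-contiguous +/-k window."""

    genome_id: str
    contig_id: str
    anchor: GeneRecord
    members: list[GeneRecord]
    window_k: int
    family_content: dict[str, list[str]] = field(default_factory=dict)

    def contains_family(self, accession: str) -> bool:
        return bool(self.family_content.get(accession))

    def member_ids(self) -> list[str]:
        return [g.gene_id for g in self.members]


def extract_window(
    contig_genes: list[GeneRecord], anchor_ordinal: int, k: int = DEFAULT_WINDOW_K
) -> list[GeneRecord]:
    """Genes at ordinals [max(0, a-k) .. min(n-1, a+k)], anchor included."""
    n = len(contig_genes)
    if not 0 <= anchor_ordinal < n:
        raise ValueError(f"anchor ordinal {anchor_ordinal} not on contig (n={n})")
    lo = max(0, anchor_ordinal - k)
    hi = min(n - 1, anchor_ordinal + k)
    return contig_genes[lo : hi + 1]


def find_colocalized(
    genomes: list[GenomeRecord],
    annotations: dict[str, DomainHit],
    anchor_family: str,
    target_families: set[str],
    k: int = DEFAULT_WINDOW_K,
) -> list[NeighborhoodCluster]:
    """One cluster per anchor-family gene, with window family content.

    ``annotations`` maps protein_id to its best-match DomainHit (module
    domain_annotation).  Each cluster's ``family_content`` records, for the
    anchor family and every target family, the member proteins annotated
    with it.  Overlapping windows around distinct anchors stay separate.
    """
    known = {h.accession for h in annotations.values()}
    if anchor_family not in known:
        raise ValueError(f"anchor family {anchor_family!r} not in annotations")
    wanted = {anchor_family} | set(target_families)
    clusters: list[NeighborhoodCluster] = []
    for genome in genomes:
        for contig_id, contig_genes in genome.contigs.items():
            for gene in contig_genes:
                if _family_of(gene, annotations) != anchor_family:
                    continue
                members = extract_window(contig_genes, gene.ordinal, k)
                content: dict[str, list[str]] = {}
                for member in members:
                    fam = _family_of(member, annotations)
                    if fam in wanted and member.protein_id is not None:
                        content.setdefault(fam, []).append(member.protein_id)
                clusters.append(
                    NeighborhoodCluster(
                        genome_id=genome.genome_id,
                        contig_id=contig_id,
                        anchor=gene,
                        members=members,
                        window_k=k,
                        family_content=content,
                    )
                )
    return clusters


def _family_of(gene: GeneRecord, annotations: dict[str, DomainHit]) -> str | None:
    if gene.protein_id is None:
        return None
    hit = annotations.get(gene.protein_id)
    return hit.accession if hit is not None else None


def colocalization_frequency(
    clusters: list[NeighborhoodCluster],
    target_family: str,
    genomes: list[GenomeRecord] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of anchor windows containing the target family.

    Returns the overall fraction plus a per-phylum table when genomes
    (for lineage lookup) are supplied.  Undefined on an empty cluster
    list.
    """
    if not clusters:
        raise ValueError("co-localization frequency undefined for zero clusters")
    hits = [c.contains_family(target_family) for c in clusters]
    overall = sum(hits) / len(hits)

    rows = []
    if genomes is not None:
        phylum_of = {g.genome_id: g.rank("phylum") for g in genomes}
        by_phylum: dict[str, list[bool]] = {}
        for cluster, hit in zip(clusters, hits):
            by_phylum.setdefault(phylum_of.get(cluster.genome_id, ""), []).append(hit)
        for phylum in sorted(by_phylum):
            flags = by_phylum[phylum]
            rows.append(
                {
                    "phylum": phylum,
                    "n_windows": len(flags),
                    "n_with_target": sum(flags),
                    "fraction": sum(flags) / len(flags),
                }
            )
    table = pd.DataFrame(rows, columns=["phylum", "n_windows", "n_with_target", "fraction"])
    return overall, table


def clusters_to_frame(clusters: list[NeighborhoodCluster]) -> pd.DataFrame:
    """Long-form member table: one row per (cluster, member gene)."""
    rows = []
    for i, cluster in enumerate(clusters):
        fam_by_protein = {
            pid: fam for fam, pids in cluster.family_content.items() for pid in pids
        }
        for member in cluster.members:
            rows.append(
                {
                    "cluster_idx": i,
                    "genome_id": cluster.genome_id,
                    "contig_id": cluster.contig_id,
                    "anchor_gene": cluster.anchor.gene_id,
                    "member_gene": member.gene_id,
                    "member_ordinal": member.ordinal,
                    "member_protein": member.protein_id or ".",
                    "member_family": fam_by_protein.get(member.protein_id, "."),
                    "strand": member.strand,
                }
            )
    return pd.DataFrame(rows)
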