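"""Genome input: gene tables, proteomes and GTDB-style lineage strings.

A genome is represented as contigs of ordered, stranded genes plus a
proteome (protein_id -> amino-acid sequence) and a parsed taxonomic
lineage.  Gene order along a contig is captured by a dense 0-based
``ordinal`` assigned after sorting by start coordinate; all neighborhood
arithmetic downstream works in ordinals (genes), never base pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

_TSV_COLUMNS = ("gene_id", "contig_id", "start", "end", "strand", "protein_id")


class GenomeIOError(ValueError):
    """Raised for malformed gene tables, proteomes or lineage input."""


@dataclass
class GeneRecord:
    """One gene on a contig.

    Coordinates are 1-based inclusive (GFF3 convention); ``ordinal`` is the
    0-based rank of the gene along its contig by start coordinate and is
    assigned at indexing time.  ``protein_id`` is ``None`` for rows without
    a protein product.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_id: str | None = None
    ordinal: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """A genome: ordered genes per contig, proteome, and lineage."""

    genome_id: str
    contigs: dict[str, list[GeneRecord]] = field(default_factory=dict)
    proteome: dict[str, str] = field(default_factory=dict)
    lineage: list[str] = field(default_factory=lambda: [""] * len(RANKS))

    def genes(self) -> Iterable[GeneRecord]:
        for contig in self.contigs.values():
            yield from contig

    def rank(self, name: str) -> str:
        if name not in RANKS:
            raise GenomeIOError(f"unknown taxonomic rank {name!r}")
        return self.lineage[RANKS.index(name)]

    def validate(self) -> None:
        """Check cross-references: every gene protein_id must be in the proteome."""
        for gene in self.genes():
            if gene.protein_id is not None and gene.protein_id not in self.proteome:
                raise GenomeIOError(
                    f"genome {self.genome_id}: gene {gene.gene_id} references "
                    f"missing protein {gene.protein_id}"
                )


def _index_contigs(genes: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Sort genes by (contig, start) and assign dense per-contig ordinals."""
    contigs: dict[str, list[GeneRecord]] = {}
    for gene in sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id)):
        contigs.setdefault(gene.contig_id, []).append(gene)
    for contig_genes in contigs.values():
        for i, gene in enumerate(contig_genes):
            gene.ordinal = i
    return contigs


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_table(path: str | Path, genome_id: str) -> GenomeRecord:
    """Read a gene table (GFF3 or plain TSV) into a genes-only GenomeRecord.

    GFF3 input keeps CDS features only; the protein identifier is taken
    from the ``protein_id`` attribute, falling back to ``ID``.  TSV input
    must carry a header with columns gene_id, contig_id, start, end,
    strand, protein_id ('.' or empty for none).  Ordinals are assigned per
    contig after sorting by start, so input row order never matters.
    """
    path = Path(path)
    text = path.read_text()
    first_data = next(
        (ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")), ""
    )
    is_gff = path.suffix.lower() in (".gff", ".gff3") or first_data.count("\t") == 8
    genes = _read_gff3(text, path) if is_gff else _read_tsv(text, path)
    seen: set[str] = set()
    for gene in genes:
        if gene.gene_id in seen:
            raise GenomeIOError(f"{path}: duplicate gene_id {gene.gene_id!r}")
        seen.add(gene.gene_id)
    return GenomeRecord(genome_id=genome_id, contigs=_index_contigs(genes))


def _read_gff3(text: str, path: Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GenomeIOError(
                f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        seqid, _source, ftype, start, end, _score, strand, _phase, attr_text = fields
        if ftype != "CDS":
            continue
        attrs = _parse_gff_attributes(attr_text)
        gene_id = attrs.get("ID") or attrs.get("protein_id")
        if gene_id is None:
            raise GenomeIOError(f"{path}:{lineno}: CDS without ID/protein_id attribute")
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise GenomeIOError(f"{path}:{lineno}: bad coordinates") from exc
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                contig_id=seqid,
                start=start_i,
                end=end_i,
                strand=strand,
                protein_id=attrs.get("protein_id") or attrs.get("ID"),
            )
        )
    return genes


def _read_tsv(text: str, path: Path) -> list[GeneRecord]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    reader = csv.DictReader(lines, delimiter="\t")
    missing = set(_TSV_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise GenomeIOError(f"{path}: missing TSV columns {sorted(missing)}")
    genes: list[GeneRecord] = []
    for lineno, row in enumerate(reader, start=2):
        try:
            start_i, end_i = int(row["start"]), int(row["end"])
        except (ValueError, TypeError) as exc:
            raise GenomeIOError(f"{path}:{lineno}: bad coordinates") from exc
        protein = row["protein_id"] or None
        if protein in (".", "-"):
            protein = None
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                contig_id=row["contig_id"],
                start=start_i,
                end=end_i,
                strand=row["strand"],
                protein_id=protein,
            )
        )
    return genes


def write_gene_table(genome: GenomeRecord, path: str | Path) -> None:
    """Write genes as the canonical TSV (round-trips through read_gene_table)."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for contig_id in sorted(genome.contigs):
        for g in genome.contigs[contig_id]:
            lines.append(
                "\t".join(
                    [g.gene_id, g.contig_id, str(g.start), str(g.end), g.strand,
                     g.protein_id or "."]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into {protein_id: sequence}.

    Sequences are upper-cased and terminal stop characters ('*') stripped.
    Duplicate identifiers are an error.
    """
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise GenomeIOError(f"{path}: duplicate protein id {record.id!r}")
        proteome[record.id] = str(record.seq).upper().rstrip("*")
    return proteome


def write_proteome(proteome: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in proteome:
            fh.write(f">{pid}\n{proteome[pid]}\n")


def parse_lineage(s: str) -> list[str]:
    """Parse a GTDB-style lineage string into the 7 canonical rank names.

    ``"d__Bacteria;p__Firmicutes"`` -> ``["Bacteria", "Firmicutes", "", ...]``.
    Rank prefixes are stripped; missing trailing ranks are empty strings.
    """
    ranks = [""] * len(RANKS)
    if not s.strip():
        return ranks
    parts = [p.strip() for p in s.split(";")]
    if len(parts) > len(RANKS):
        raise GenomeIOError(f"lineage has more than {len(RANKS)} ranks: {s!r}")
    for i, part in enumerate(parts):
        for prefix in _RANK_PREFIXES:
            if part.startswith(prefix):
                part = part[len(prefix):]
                break
        ranks[i] = part
    return ranks


def read_genome(
    gene_table: str | Path,
    proteome_fasta: str | Path,
    genome_id: str,
    lineage: str = "",
) -> GenomeRecord:
    """Assemble a full GenomeRecord from its on-disk pieces and validate it."""
    genome = read_gene_table(gene_table, genome_id)
    genome.proteome = read_proteome(proteome_fasta)
    genome.lineage = parse_lineage(lineage)
    genome.validate()
    return genome
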