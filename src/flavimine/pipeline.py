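"""End-to-end runs: mine (annotation -> neighborhoods -> motifs ->
candidates -> taxonomy) and structure feature reports.

All tabular output is TSV (header row, UTF-8, '.' decimal); a JSON
manifest records parameters, seed and input checksums.  Outputs are
computed fully in memory, then written through temporary files and
atomic renames so a failed run never leaves partial tables behind.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import all_column_stats, read_msa, stats_to_frame, top_conserved
from .domain_annotation import (
    DomainHit,
    annotate_with_profiles,
    assign_best,
    read_profile_tsv,
    read_tblout,
)
from .genome_io import GenomeRecord, read_genome
from .motifs import (
    MotifPattern,
    call_candidates,
    candidates_to_frame,
    scan_proteome,
    sites_to_frame,
)
from .neighborhood import (
    clusters_to_frame,
    colocalization_frequency,
    find_colocalized,
)
from .structure import (
    detect_heme_his_pairs,
    detect_tm_segments,
    read_pdb,
)
from .taxonomy import tabulate

logger = logging.getLogger("flavimine")


@dataclass
class RunConfig:
    """Parameters and paths for a pipeline run.

    Defaults follow the mining conventions the pipeline is built around:
    +/-5 gene windows, E-value cutoff 0.001 for best-match annotation,
    the [S/T]GA[S/T] flavinylation motif, a 6.0 A bis-His distance
    cutoff, Kyte-Doolittle window 19 / threshold 1.6, and 3.0-bit
    minimum information content for conserved columns.
    """

    genomes_dir: str = ""
    lineages: str = ""
    tblout: str = ""
    profiles_dir: str = ""
    structures_dir: str = ""
    msa_files: list[str] = field(default_factory=list)
    out_dir: str = "out"
    anchor_family: str = "PF02424"
    target_families: list[str] = field(
        default_factory=lambda: ["PF12682", "PF03358", "PF14358"]
    )
    window_k: int = 5
    evalue_cutoff: float = 1e-3
    motif_positions: list[str] = field(default_factory=lambda: ["ST", "G", "A", "ST"])
    motif_flavinylated_offset: int = 3
    heme_max_dist: float = 6.0
    heme_min_seq_sep: int = 10
    tm_window: int = 19
    tm_threshold: float = 1.6
    min_ic: float = 3.0
    min_occupancy: float = 0.5
    taxonomy_rank: str = "phylum"
    seed: int = 0
    log_level: str = "INFO"

    def motif_pattern(self) -> MotifPattern:
        return MotifPattern(
            pattern_id="".join(f"[{p}]" if len(p) > 1 else p for p in self.motif_positions),
            positions=[frozenset(p) for p in self.motif_positions],
            flavinylated_offset=self.motif_flavinylated_offset,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def load_genomes(genomes_dir: str | Path, lineages_path: str | Path | None) -> list[GenomeRecord]:
    """Read every <id>.genes.tsv / <id>.faa pair in a directory."""
    genomes_dir = Path(genomes_dir)
    lineage_map: dict[str, str] = {}
    if lineages_path and Path(lineages_path).exists():
        frame = pd.read_csv(lineages_path, sep="\t", dtype=str)
        lineage_map = dict(zip(frame["genome_id"], frame["lineage"]))
    genomes = []
    for gene_table in sorted(genomes_dir.glob("*.genes.tsv")):
        genome_id = gene_table.name.removesuffix(".genes.tsv")
        faa = genomes_dir / f"{genome_id}.faa"
        if not faa.exists():
            raise FileNotFoundError(f"missing proteome for {genome_id}: {faa}")
        genomes.append(
            read_genome(gene_table, faa, genome_id, lineage_map.get(genome_id, ""))
        )
    return genomes


def _annotate(config: RunConfig, genomes: list[GenomeRecord]) -> dict[str, DomainHit]:
    if config.tblout:
        hits = read_tblout(config.tblout)
        return assign_best(hits, evalue_cutoff=config.evalue_cutoff)
    if config.profiles_dir:
        profiles = [
            read_profile_tsv(p) for p in sorted(Path(config.profiles_dir).glob("*.tsv"))
        ]
        merged: dict[str, DomainHit] = {}
        for genome in genomes:
            merged.update(
                annotate_with_profiles(
                    genome.proteome, profiles,
                    evalue_cutoff=config.evalue_cutoff, seed=config.seed,
                )
            )
        return merged
    raise ValueError("config needs either 'tblout' or 'profiles_dir' for annotation")


def _write_tables(
    out_dir: Path, tables: dict[str, pd.DataFrame], manifest: dict
) -> None:
    """Write all outputs via temp files + atomic renames."""
    out_dir.mkdir(parents=True, exist_ok=True)
    staged: list[tuple[str, str]] = []
    try:
        for name, frame in tables.items():
            fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
            with os.fdopen(fd, "w") as fh:
                frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
            staged.append((tmp, str(out_dir / name)))
        fd, tmp = tempfile.mkstemp(dir=out_dir, suffix=".tmp")
        with os.fdopen(fd, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        staged.append((tmp, str(out_dir / "manifest.json")))
    except BaseException:
        for tmp, _ in staged:
            os.unlink(tmp)
        raise
    for tmp, final in staged:
        os.replace(tmp, final)


def _check_inputs(paths: list[str]) -> list[Path]:
    missing = [p for p in paths if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    return [Path(p) for p in paths if p]


def run_mine(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Full mining run; returns the output tables (also written to disk)."""
    inputs = _check_inputs(
        [config.genomes_dir, config.lineages, config.tblout, config.profiles_dir]
    )
    logger.info("loading genomes from %s", config.genomes_dir)
    genomes = load_genomes(config.genomes_dir, config.lineages or None)
    annotations = _annotate(config, genomes)
    logger.info("annotated %d proteins", len(annotations))

    clusters = find_colocalized(
        genomes, annotations, config.anchor_family,
        set(config.target_families), k=config.window_k,
    )
    logger.info("found %d anchor windows", len(clusters))

    pattern = config.motif_pattern()
    sites: dict = {}
    for genome in genomes:
        sites.update(scan_proteome(genome.proteome, pattern))
    calls = call_candidates(clusters, sites, set(config.target_families))
    logger.info("called %d candidate substrates", len(calls))

    coloc_rows = []
    for family in config.target_families:
        if clusters:
            overall, per_phylum = colocalization_frequency(clusters, family, genomes)
            coloc_rows.append(
                {"target_family": family, "scope": "overall",
                 "n_windows": len(clusters),
                 "n_with_target": sum(c.contains_family(family) for c in clusters),
                 "fraction": overall}
            )
            for _, row in per_phylum.iterrows():
                coloc_rows.append(
                    {"target_family": family, "scope": f"p__{row['phylum']}",
                     "n_windows": row["n_windows"],
                     "n_with_target": row["n_with_target"],
                     "fraction": row["fraction"]}
                )
    coloc = pd.DataFrame(
        coloc_rows,
        columns=["target_family", "scope", "n_windows", "n_with_target", "fraction"],
    )

    counts: dict[str, int] = {}
    for call in calls:
        counts[call.genome_id] = counts.get(call.genome_id, 0) + 1
    taxonomy = tabulate(genomes, counts, rank=config.taxonomy_rank)

    summary_rows = []
    for i, cluster in enumerate(clusters):
        row = {
            "cluster_idx": i,
            "genome_id": cluster.genome_id,
            "contig_id": cluster.contig_id,
            "anchor_gene": cluster.anchor.gene_id,
            "anchor_protein": cluster.anchor.protein_id or ".",
            "n_members": len(cluster.members),
        }
        for family in config.target_families:
            row[f"has_{family}"] = cluster.contains_family(family)
        summary_rows.append(row)
    summary = pd.DataFrame(
        summary_rows,
        columns=["cluster_idx", "genome_id", "contig_id", "anchor_gene",
                 "anchor_protein", "n_members"]
        + [f"has_{f}" for f in config.target_families],
    )

    tables = {
        "clusters.tsv": clusters_to_frame(clusters),
        "cluster_summary.tsv": summary,
        "motif_sites.tsv": sites_to_frame(sites),
        "candidates.tsv": candidates_to_frame(calls),
        "colocalization.tsv": coloc,
        "taxonomy.tsv": taxonomy,
    }
    manifest = {
        "tool": "flavimine",
        "version": __version__,
        "command": "mine",
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "inputs": {str(p): _input_checksum(p) for p in inputs},
        "n_genomes": len(genomes),
        "n_clusters": len(clusters),
        "n_candidates": len(calls),
    }
    _write_tables(Path(config.out_dir), tables, manifest)
    return tables


def _input_checksum(path: Path) -> str:
    if path.is_file():
        return _sha256(path)
    parts = [f"{p.name}:{_sha256(p)}" for p in sorted(path.rglob("*")) if p.is_file()]
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


def run_structure(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-structure feature report over a directory of PDB files."""
    _check_inputs([config.structures_dir])
    pdbs = sorted(Path(config.structures_dir).glob("*.pdb"))
    if not pdbs:
        raise FileNotFoundError(f"no .pdb files in {config.structures_dir}")
    seg_rows, heme_rows = [], []
    for pdb in pdbs:
        model = read_pdb(pdb)
        for chain_id in sorted(model.chains):
            for seg in detect_tm_segments(
                model.sequence(chain_id), chain=chain_id,
                window=config.tm_window, threshold=config.tm_threshold,
            ):
                seg_rows.append(
                    {"structure": model.name, "chain": seg.chain,
                     "start": seg.start, "end": seg.end,
                     "peak_hydropathy": seg.mean_hydropathy}
                )
        for pair in detect_heme_his_pairs(
            model, max_dist=config.heme_max_dist, min_seq_sep=config.heme_min_seq_sep
        ):
            heme_rows.append(
                {"structure": model.name,
                 "chain_a": pair.chain_a, "res_a": pair.res_a,
                 "chain_b": pair.chain_b, "res_b": pair.res_b,
                 "atom": pair.coordinating_atom,
                 "distance": pair.inter_atom_distance,
                 "same_chain": pair.same_chain,
                 "seq_separation": pair.sequence_separation
                 if pair.sequence_separation is not None else -1}
            )
    tables = {
        "tm_segments.tsv": pd.DataFrame(
            seg_rows, columns=["structure", "chain", "start", "end", "peak_hydropathy"]
        ),
        "heme_pairs.tsv": pd.DataFrame(
            heme_rows,
            columns=["structure", "chain_a", "res_a", "chain_b", "res_b",
                     "atom", "distance", "same_chain", "seq_separation"],
        ),
    }
    manifest = {
        "tool": "flavimine",
        "version": __version__,
        "command": "structure",
        "parameters": dataclasses.asdict(config),
        "inputs": {str(p): _sha256(p) for p in pdbs},
        "n_structures": len(pdbs),
    }
    _write_tables(Path(config.out_dir), tables, manifest)
    return tables


def run_conservation(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-column conservation tables for each configured alignment."""
    _check_inputs(list(config.msa_files))
    tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for msa_path in config.msa_files:
        msa = read_msa(msa_path)
        stats = all_column_stats(msa)
        name = Path(msa_path).stem
        tables[f"conservation_{name}.tsv"] = stats_to_frame(stats)
        for residue_set, label in ((set("H"), "His"), (set("T"), "Thr")):
            for col in top_conserved(
                msa, residue_set, min_ic=config.min_ic,
                min_occupancy=config.min_occupancy,
            ):
                summary_rows.append(
                    {"msa": name, "residue": label, "column": col}
                )
    tables["conserved_columns.tsv"] = pd.DataFrame(
        summary_rows, columns=["msa", "residue", "column"]
    )
    manifest = {
        "tool": "flavimine",
        "version": __version__,
        "command": "conservation",
        "parameters": dataclasses.asdict(config),
        "inputs": {p: _sha256(Path(p)) for p in config.msa_files},
    }
    _write_tables(Path(config.out_dir), tables, manifest)
    return tables
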