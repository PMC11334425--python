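"""Seeded synthetic fixtures with ground-truth manifests.

Generates the three kinds of input the pipeline consumes, in the same
on-disk formats it reads from real data:

* genomes — ordered gene tables and proteomes in which every genome
  carries one anchor-family (ApbE-like) gene and, with probability
  ``p_cluster``, a target-family gene planted at a nonzero offset within
  the +/-k window, its protein carrying a known number of [S/T]GA[S/T]
  motifs.  Background proteins are rejection-sampled to be motif- and
  signature-free, so planted features are exact ground truth (a
  deliberate bias relative to nature).  Planted domains are realized both
  as high-scoring windows for the PSSM scanner (each family has a fixed
  signature peptide and a matching profile) and as rows of an
  hmmsearch-style tblout table.
* MSAs — alignment columns drawing a designated residue with probability
  ``planted_conservation`` at planted positions, uniform elsewhere.
* structures — CA traces laid out as ideal helices (rise 1.5 A,
  100 degrees per residue) with explicit NE2 pseudo-atoms for planted
  histidine pairs at exact coordinates; minimal by design, sufficient
  for the geometric detectors.

All randomness flows from ``SimConfig.seed`` through independent named
streams; identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.SeqUtils import seq3

from .domain_annotation import AMINO_ACIDS, DomainProfile, write_profile_tsv
from .genome_io import GeneRecord, GenomeRecord, _index_contigs
from .motifs import MotifPattern, scan_motifs

ANCHOR_FAMILY = "PF02424"  # ApbE FMN transferase
TARGET_FAMILIES = ("PF12682", "PF03358", "PF14358")  # Flavodoxin_4, FMN_red, DUF4405
FAMILY_NAMES = {
    "PF02424": "ApbE",
    "PF12682": "Flavodoxin_4",
    "PF03358": "FMN_red",
    "PF14358": "DUF4405",
}
# Fixed, motif-free signature peptides that realize each family as a
# high-scoring ungapped window (one per family, length 12).
FAMILY_SIGNATURES = {
    "PF02424": "WQNDKEHRYWFM",
    "PF12682": "FYHKDEQNWRCM",
    "PF03358": "MWRYEKDHQNFC",
    "PF14358": "CHNWYQDREKFM",
}

# Kyte-Doolittle-strongly-hydrophobic vs hydrophilic residues used for
# planted transmembrane topologies.
HYDROPHOBIC = "ILVF"
HYDROPHILIC = "DEKRNQ"

_PHYLA = ["Firmicutes", "Proteobacteria", "Bacteroidota", "Actinobacteriota"]
_PHYLUM_WEIGHTS = [0.6, 0.25, 0.1, 0.05]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 1
    # genomes
    n_genomes: int = 200
    genes_per_contig: int = 40
    p_cluster: float = 0.5
    window_k: int = 5  # target offset drawn uniformly from [-k, k] \ {0}
    n_motif_sites: int = 1  # per planted target (3-13 for multi-flavinylated)
    protein_len_range: tuple[int, int] = (150, 400)
    background_freqs: dict[str, float] | None = None  # default: uniform over 20
    # MSA
    msa_rows: int = 200
    msa_columns: int = 60
    planted_columns: dict[int, str] = field(default_factory=dict)  # 1-based col -> residue
    planted_conservation: float = 0.95
    # structures
    structure_chains: dict[str, str] = field(default_factory=dict)  # chain -> sequence
    planted_his: list[tuple[str, int, tuple[float, float, float]]] = field(
        default_factory=list
    )  # (chain, 1-based seq position, NE2 xyz)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_cluster <= 1.0:
            raise ValueError("p_cluster must be in [0, 1]")
        if self.window_k < 1:
            raise ValueError("window_k must be >= 1 to place a distinct target")
        if self.n_motif_sites < 1:
            raise ValueError("planted targets need at least one motif site")


@dataclass
class GroundTruth:
    """Manifest of every planted feature, retrievable by ID."""

    anchors: list[dict] = field(default_factory=list)
    pairs: list[dict] = field(default_factory=list)
    motif_sites: dict[str, list[int]] = field(default_factory=dict)
    msa_planted_columns: dict[int, str] = field(default_factory=dict)
    structure_his: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["msa_planted_columns"] = {
            str(k): v for k, v in self.msa_planted_columns.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["msa_planted_columns"] = {
            int(k): v for k, v in payload.get("msa_planted_columns", {}).items()
        }
        payload["structure_his"] = [dict(d) for d in payload.get("structure_his", [])]
        return cls(**payload)


def _background_probs(cfg: SimConfig) -> np.ndarray:
    if cfg.background_freqs is None:
        return np.full(20, 1 / 20)
    probs = np.array([cfg.background_freqs.get(aa, 0.0) for aa in AMINO_ACIDS])
    return probs / probs.sum()


def _random_peptide(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _is_clean(seq: str, pattern: MotifPattern) -> bool:
    if scan_motifs(seq, pattern):
        return False
    return not any(sig in seq for sig in FAMILY_SIGNATURES.values())


def _background_protein(
    rng: np.random.Generator, length: int, probs: np.ndarray, pattern: MotifPattern
) -> str:
    for _ in range(1000):
        seq = _random_peptide(rng, length, probs)
        if _is_clean(seq, pattern):
            return seq
    raise RuntimeError("rejection sampling failed to produce a clean sequence")


def _planted_protein(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    pattern: MotifPattern,
    family: str,
    n_motifs: int,
) -> tuple[str, list[int]]:
    """A protein containing the family signature once and exactly
    ``n_motifs`` motif matches, at known positions."""
    signature = FAMILY_SIGNATURES[family]
    motif_strs = [
        "".join(rng.choice(sorted(allowed)) for allowed in pattern.positions)
        for _ in range(n_motifs)
    ]
    inserts = [signature] + motif_strs
    n_flanks = len(inserts) + 1
    flank_total = max(length - sum(len(s) for s in inserts), n_flanks * 8)
    for _ in range(1000):
        cuts = sorted(rng.integers(0, flank_total + 1, size=n_flanks - 1))
        flank_lens = np.diff([0, *cuts, flank_total])
        flanks = [_random_peptide(rng, int(fl), probs) for fl in flank_lens]
        parts: list[str] = []
        motif_starts: list[int] = []
        pos = 0
        for flank, insert in zip(flanks, inserts + [""]):
            parts.append(flank)
            pos += len(flank)
            if insert:
                parts.append(insert)
                if insert != signature:
                    motif_starts.append(pos + 1)  # 1-based
                pos += len(insert)
        seq = "".join(parts)
        found = [s.start for s in scan_motifs(seq, pattern)]
        if found == sorted(motif_starts) and seq.count(signature) == 1:
            return seq, sorted(motif_starts)
    raise RuntimeError("failed to assemble a planted protein without junction artifacts")


def family_profiles(match_score: float = 2.0, mismatch_score: float = -1.0) -> list[DomainProfile]:
    """One ungapped profile per family, scoring its signature peptide."""
    profiles = []
    for accession, signature in FAMILY_SIGNATURES.items():
        columns = np.full((len(signature), 20), mismatch_score)
        for k, aa in enumerate(signature):
            columns[k, AMINO_ACIDS.index(aa)] = match_score
        profiles.append(
            DomainProfile(accession=accession, name=FAMILY_NAMES[accession], columns=columns)
        )
    return profiles


def simulate_genomes(cfg: SimConfig) -> tuple[list[GenomeRecord], GroundTruth]:
    """Genomes with one planted anchor each and p_cluster-probability
    planted (anchor, target) pairs; see module docstring."""
    rng = np.random.default_rng([cfg.seed, 101])
    probs = _background_probs(cfg)
    pattern = MotifPattern()
    truth = GroundTruth()
    genomes: list[GenomeRecord] = []
    k = cfg.window_k
    n = cfg.genes_per_contig
    lo_len, hi_len = cfg.protein_len_range

    for gi in range(cfg.n_genomes):
        genome_id = f"G{gi:04d}"
        phylum = _PHYLA[rng.choice(len(_PHYLA), p=_PHYLUM_WEIGHTS)]
        anchor_ord = int(rng.integers(0, n))
        plant_target = bool(rng.random() < cfg.p_cluster)
        target_ord = None
        family = None
        if plant_target:
            offsets = [
                o for o in range(-k, k + 1)
                if o != 0 and 0 <= anchor_ord + o < n
            ]
            target_ord = anchor_ord + int(rng.choice(offsets))
            family = str(rng.choice(TARGET_FAMILIES))

        genes: list[GeneRecord] = []
        proteome: dict[str, str] = {}
        for ordinal in range(n):
            gene_id = f"{genome_id}_g{ordinal:03d}"
            pid = f"{genome_id}_p{ordinal:03d}"
            length = int(rng.integers(lo_len, hi_len + 1))
            if ordinal == anchor_ord:
                seq = _background_protein(rng, length, probs, pattern)
                pos = int(rng.integers(0, len(seq) - 12 + 1))
                seq = seq[:pos] + FAMILY_SIGNATURES[ANCHOR_FAMILY] + seq[pos + 12:]
                if not _plant_ok(seq, pattern, ANCHOR_FAMILY):
                    seq = _background_protein(rng, length - 12, probs, pattern) \
                        + FAMILY_SIGNATURES[ANCHOR_FAMILY]
                truth.anchors.append(
                    {"genome_id": genome_id, "gene_id": gene_id, "protein_id": pid}
                )
            elif target_ord is not None and ordinal == target_ord:
                seq, starts = _planted_protein(
                    rng, length, probs, pattern, family, cfg.n_motif_sites
                )
                truth.motif_sites[pid] = starts
                truth.pairs.append(
                    {
                        "genome_id": genome_id,
                        "anchor_gene": f"{genome_id}_g{anchor_ord:03d}",
                        "target_gene": gene_id,
                        "target_protein": pid,
                        "family": family,
                        "offset": target_ord - anchor_ord,
                        "n_motif_sites": cfg.n_motif_sites,
                    }
                )
            else:
                seq = _background_protein(rng, length, probs, pattern)
            proteome[pid] = seq
            start = ordinal * 1000 + 1
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig_id="contig_1",
                    start=start,
                    end=start + 3 * len(seq) + 2,
                    strand="+" if rng.random() < 0.5 else "-",
                    protein_id=pid,
                )
            )
        lineage = ["Bacteria", phylum, "", "", "", "", ""]
        genome = GenomeRecord(
            genome_id=genome_id,
            contigs=_index_contigs(genes),
            proteome=proteome,
            lineage=lineage,
        )
        genomes.append(genome)
    return genomes, truth


def _plant_ok(seq: str, pattern: MotifPattern, family: str) -> bool:
    return not scan_motifs(seq, pattern) and sum(
        seq.count(sig) for sig in FAMILY_SIGNATURES.values()
    ) == 1


def planted_annotations(genomes: list[GenomeRecord], truth: GroundTruth) -> dict[str, str]:
    """Ground-truth protein -> family map for planted genes."""
    out = {a["protein_id"]: ANCHOR_FAMILY for a in truth.anchors}
    out.update({p["target_protein"]: p["family"] for p in truth.pairs})
    return out


def write_tblout(
    annotations: dict[str, str], path: str | Path, evalue: float = 1e-20,
    score: float = 150.0,
) -> None:
    """Emit planted annotations as an hmmsearch-style --tblout table."""
    lines = [
        "#                                                               --- full sequence ---- --- best 1 domain ---- --- dom ---",
        "# target name        accession  query name           accession    E-value  score  bias   E-value  score  bias   exp reg clu  ov env dom rep inc description of target",
        "#------------------- ---------- -------------------- ---------- --------- ------ ----- --------- ------ ----- ----- --- --- --- --- --- --- --- ---------------------",
    ]
    for pid in sorted(annotations):
        fam = annotations[pid]
        lines.append(
            f"{pid:<20} -          {FAMILY_NAMES[fam]:<20} {fam:<10} "
            f"{evalue:9.2g} {score:6.1f}   0.0 {evalue:9.2g} {score:6.1f}   0.0 "
            f"  1.0   1   0   0   1   1   1   1 planted"
        )
    lines.append("#")
    Path(path).write_text("\n".join(lines) + "\n")


def write_genome_set(
    genomes: list[GenomeRecord],
    truth: GroundTruth,
    out_dir: str | Path,
    emit_tblout: bool = True,
    emit_profiles: bool = True,
) -> Path:
    """Write the full fixture set: per-genome gene TSV + proteome FASTA,
    a lineage table, a tblout annotation table, scanner profiles, and the
    ground-truth manifest.  Returns the output directory."""
    from .genome_io import write_gene_table, write_proteome

    out = Path(out_dir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    lineage_lines = ["genome_id\tlineage"]
    for genome in genomes:
        write_gene_table(genome, out / "genomes" / f"{genome.genome_id}.genes.tsv")
        write_proteome(genome.proteome, out / "genomes" / f"{genome.genome_id}.faa")
        ranks = ["d__" + genome.lineage[0], "p__" + genome.lineage[1],
                 "c__" + genome.lineage[2], "o__" + genome.lineage[3],
                 "f__" + genome.lineage[4], "g__" + genome.lineage[5],
                 "s__" + genome.lineage[6]]
        lineage_lines.append(f"{genome.genome_id}\t{';'.join(ranks)}")
    (out / "lineages.tsv").write_text("\n".join(lineage_lines) + "\n")
    if emit_tblout:
        write_tblout(planted_annotations(genomes, truth), out / "annotations.tblout")
    if emit_profiles:
        (out / "profiles").mkdir(exist_ok=True)
        for profile in family_profiles():
            write_profile_tsv(profile, out / "profiles" / f"{profile.accession}.tsv")
    truth.to_json(out / "ground_truth.json")
    return out


def simulate_msa(cfg: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Alignment with near-invariant planted columns among uniform noise."""
    rng = np.random.default_rng([cfg.seed, 202])
    truth = GroundTruth(msa_planted_columns=dict(cfg.planted_columns))
    aa = np.array(list(AMINO_ACIDS))
    block = rng.choice(20, size=(cfg.msa_rows, cfg.msa_columns))
    rows = block.astype(object)
    for col, residue in cfg.planted_columns.items():
        if not 1 <= col <= cfg.msa_columns:
            raise ValueError(f"planted column {col} outside alignment")
        keep = rng.random(cfg.msa_rows) < cfg.planted_conservation
        rows[keep, col - 1] = -1  # sentinel: planted residue
    msa = {}
    for r in range(cfg.msa_rows):
        chars = []
        for c in range(cfg.msa_columns):
            v = rows[r, c]
            chars.append(cfg.planted_columns[c + 1] if v == -1 else aa[v])
        msa[f"seq{r:04d}"] = "".join(chars)
    return msa, truth


def write_msa(msa: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in msa.items():
            fh.write(f">{rid}\n{seq}\n")


def tm_test_sequence(
    n_helices: int = 6, helix_len: int = 21, loop_len: int = 30, seed: int = 0
) -> str:
    """Sequence with ``n_helices`` planted hydrophobic stretches separated
    (and flanked) by strongly hydrophilic loops."""
    rng = np.random.default_rng([seed, 303])
    parts = [_pick(rng, HYDROPHILIC, loop_len)]
    for _ in range(n_helices):
        parts.append(_pick(rng, HYDROPHOBIC, helix_len))
        parts.append(_pick(rng, HYDROPHILIC, loop_len))
    return "".join(parts)


def _pick(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def simulate_structure(cfg: SimConfig) -> tuple[gemmi.Structure, GroundTruth]:
    """Toy coordinate model: CA traces as ideal helices plus exact NE2
    pseudo-atoms for planted histidines.

    Chains are laid out as straight ideal alpha-helices along z (rise
    1.5 A per residue, 100 degrees twist, radius 2.3 A), successive
    chains offset in x.  Residues listed in ``cfg.planted_his`` become
    HIS and carry an NE2 atom at the exact configured coordinate; their
    CA is placed 2.0 A from the NE2.
    """
    truth = GroundTruth()
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    planted = {(c, p): xyz for c, p, xyz in cfg.planted_his}
    for ci, (chain_id, sequence) in enumerate(sorted(cfg.structure_chains.items())):
        chain = gemmi.Chain(chain_id)
        x_off = 30.0 * ci
        seen: set[int] = set()
        for i, aa in enumerate(sequence):
            resnum = i + 1
            if resnum in seen:
                raise ValueError(f"clashing residue number {resnum} in chain {chain_id}")
            seen.add(resnum)
            is_planted = (chain_id, resnum) in planted
            name3 = "HIS" if is_planted else seq3(aa).upper()
            res = gemmi.Residue()
            res.name = name3
            res.seqid = gemmi.SeqId(resnum, " ")
            angle = np.deg2rad(100.0 * i)
            ca = np.array(
                [x_off + 2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * i]
            )
            if is_planted:
                ne2 = np.array(planted[(chain_id, resnum)], dtype=float)
                ca = ne2 + np.array([2.0, 0.0, 0.0])
                res.add_atom(_atom("NE2", ne2, "N"))
                truth.structure_his.append(
                    {"chain": chain_id, "resnum": resnum, "ne2": list(map(float, ne2))}
                )
            res.add_atom(_atom("CA", ca, "C"))
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st, truth


def _atom(name: str, xyz: np.ndarray, element: str) -> gemmi.Atom:
    atom = gemmi.Atom()
    atom.name = name
    atom.pos = gemmi.Position(*map(float, xyz))
    atom.occ = 1.0
    atom.b_iso = 0.0
    atom.element = gemmi.Element(element)
    return atom


def write_structure(st: gemmi.Structure, path: str | Path) -> None:
    st.setup_entities()
    st.write_pdb(str(path))
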