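"""Structure-level signatures in coordinate models (PDB input).

Detectors for the features that mark flavinylation-associated electron
transfer machinery in predicted structures:

* transmembrane helices, called from sequence by sliding-window
  Kyte-Doolittle hydropathy (window 19, threshold 1.6);
* candidate bis-His heme sites: histidine pairs whose NE2 atoms (ND1
  fallback) sit within axial-coordination distance of a shared heme iron
  (default 6.0 A), within a chain or across chains of a homodimer;
* least-squares rigid superposition (Kabsch) with RMSD, given a residue
  correspondence;
* distance from a predicted flavinylated Ser/Thr to a flavin-binding
  pocket (named residues' CA centroid or a bound ligand's heavy-atom
  centroid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio.SeqUtils import seq1
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

TM_WINDOW = 19
TM_THRESHOLD = 1.6
HEME_MAX_DIST = 6.0  # axial NE2-Fe-NE2 span across a heme iron is ~4.2 A
HEME_MIN_SEQ_SEP = 10
POCKET_PROXIMAL_CUTOFF = 15.0


@dataclass
class Atom:
    name: str
    xyz: np.ndarray
    occupancy: float = 1.0


@dataclass
class Residue:
    number: int
    name: str  # 3-letter
    atoms: dict[str, Atom] = field(default_factory=dict)
    het: bool = False

    def coord(self, atom_name: str) -> np.ndarray | None:
        atom = self.atoms.get(atom_name)
        return atom.xyz if atom is not None else None


@dataclass
class StructureModel:
    name: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[tuple[str, Residue]] = field(default_factory=list)  # (chain, residue)

    def sequence(self, chain_id: str) -> str:
        return "".join(
            seq1(r.name, undef_code="X") for r in self.chains.get(chain_id, [])
        )

    def residue(self, chain_id: str, number: int) -> Residue | None:
        for r in self.chains.get(chain_id, []):
            if r.number == number:
                return r
        return None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy with every coordinate mapped x -> R x + t."""
        out = StructureModel(name=self.name)
        for cid, residues in self.chains.items():
            out.chains[cid] = [_transform_residue(r, rotation, translation) for r in residues]
        out.ligands = [
            (cid, _transform_residue(r, rotation, translation)) for cid, r in self.ligands
        ]
        return out


def _transform_residue(r: Residue, rot: np.ndarray, trans: np.ndarray) -> Residue:
    return Residue(
        number=r.number,
        name=r.name,
        het=r.het,
        atoms={
            n: Atom(a.name, rot @ a.xyz + trans, a.occupancy) for n, a in r.atoms.items()
        },
    )


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB file: first MODEL only, highest-occupancy altloc kept,
    HETATM ligands (FMN, HEM, ...) collected separately from the chains."""
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    out = StructureModel(name=Path(path).stem)
    n_atoms = 0
    for chain in model:
        for res in chain:
            residue = Residue(
                number=res.seqid.num, name=res.name.strip(),
                het=res.het_flag == "H",
            )
            for atom in res:
                n_atoms += 1
                prev = residue.atoms.get(atom.name)
                if prev is None or atom.occ > prev.occupancy:
                    residue.atoms[atom.name] = Atom(
                        atom.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        atom.occ,
                    )
            is_water = residue.name in ("HOH", "WAT")
            if residue.het and residue.name not in _STANDARD_AA and not is_water:
                out.ligands.append((chain.name, residue))
            elif not is_water:
                out.chains.setdefault(chain.name, []).append(residue)
    if n_atoms == 0:
        raise ValueError(f"{path}: no ATOM records")
    for residues in out.chains.values():
        residues.sort(key=lambda r: r.number)
    return out


_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class TMSegment:
    """A candidate transmembrane helix: the union of overlapping
    hydropathy windows clearing the threshold.  ``mean_hydropathy`` is the
    peak sliding-window mean within the segment."""

    chain: str
    start: int  # 1-based residue positions in the chain sequence
    end: int
    mean_hydropathy: float


def detect_tm_segments(
    sequence: str,
    chain: str = "A",
    window: int = TM_WINDOW,
    threshold: float = TM_THRESHOLD,
) -> list[TMSegment]:
    """Sliding-window Kyte-Doolittle transmembrane-helix caller.

    Every length-``window`` stretch whose mean hydropathy clears
    ``threshold`` marks its residues as membrane-spanning; overlapping
    qualifying windows merge into maximal segments.  Returns an empty
    list for sequences shorter than the window.
    """
    n = len(sequence)
    if n < window:
        return []
    values = np.array([KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence.upper()])
    sums = np.convolve(values, np.ones(window), mode="valid")
    means = sums / window
    qualifying = np.where(means >= threshold)[0]
    if qualifying.size == 0:
        return []
    segments: list[TMSegment] = []
    run_start = qualifying[0]
    prev = qualifying[0]
    for idx in qualifying[1:]:
        if idx >= prev + window:  # windows no longer overlap: close the run
            segments.append(_make_segment(chain, run_start, prev, window, means))
            run_start = idx
        prev = idx
    segments.append(_make_segment(chain, run_start, prev, window, means))
    return segments


def _make_segment(
    chain: str, first_win: int, last_win: int, window: int, means: np.ndarray
) -> TMSegment:
    return TMSegment(
        chain=chain,
        start=first_win + 1,
        end=last_win + window,
        mean_hydropathy=float(means[first_win : last_win + 1].max()),
    )


@dataclass
class HemeSiteCandidate:
    """Two histidines positioned to axially coordinate one heme iron."""

    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    coordinating_atom: str
    inter_atom_distance: float
    same_chain: bool
    sequence_separation: int | None  # None for cross-chain pairs


def _his_coordination_atom(res: Residue) -> tuple[str, np.ndarray] | None:
    for name in ("NE2", "ND1"):
        xyz = res.coord(name)
        if xyz is not None:
            return name, xyz
    return None


def detect_heme_his_pairs(
    structure: StructureModel,
    max_dist: float = HEME_MAX_DIST,
    min_seq_sep: int = HEME_MIN_SEQ_SEP,
) -> list[HemeSiteCandidate]:
    """All His pairs whose coordinating N atoms lie within ``max_dist``.

    Same-chain pairs must additionally be ``min_seq_sep`` residues apart
    (adjacent histidines cannot flank a heme).  Cross-chain pairs support
    homodimer sites.  Sorted by distance.
    """
    his: list[tuple[str, Residue, str, np.ndarray]] = []
    for chain_id, residues in structure.chains.items():
        for res in residues:
            if res.name == "HIS":
                found = _his_coordination_atom(res)
                if found is not None:
                    his.append((chain_id, res, found[0], found[1]))
    candidates: list[HemeSiteCandidate] = []
    for i in range(len(his)):
        for j in range(i + 1, len(his)):
            ca, ra, atom_a, xa = his[i]
            cb, rb, atom_b, xb = his[j]
            dist = float(np.linalg.norm(xa - xb))
            if dist > max_dist:
                continue
            same = ca == cb
            sep = abs(ra.number - rb.number) if same else None
            if same and sep < min_seq_sep:
                continue
            candidates.append(
                HemeSiteCandidate(
                    chain_a=ca, res_a=ra.number, chain_b=cb, res_b=rb.number,
                    coordinating_atom=atom_a if atom_a == atom_b else f"{atom_a}/{atom_b}",
                    inter_atom_distance=dist, same_chain=same,
                    sequence_separation=sep,
                )
            )
    candidates.sort(key=lambda c: c.inter_atom_distance)
    return candidates


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Finds the proper rotation R (det +1) and translation t minimizing
    ||R a + t - b|| over the given correspondence, via SVD of the
    cross-covariance (Kabsch).  Returns (R, t, rmsd).  Requires at least
    three non-collinear pairs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if np.linalg.matrix_rank(a0, tol=1e-9) < 2:
        raise ValueError("points are collinear; rotation underdetermined")
    h = a0.T @ b0
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cb - rotation @ ca
    moved = (rotation @ a.T).T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rotation, translation, rmsd


def motif_pocket_distance(
    structure: StructureModel,
    motif_chain: str,
    motif_resnum: int,
    pocket_residues: list[tuple[str, int]] | None = None,
    ligand_name: str | None = None,
    proximal_cutoff: float = POCKET_PROXIMAL_CUTOFF,
) -> tuple[float, bool]:
    """Distance from a motif Ser/Thr hydroxyl to a flavin pocket centroid.

    The motif residue contributes its OG/OG1 atom (CA fallback); the
    pocket is the centroid of the named residues' CA atoms, or of the
    named ligand's heavy atoms.  Returns (distance_A, proximal_flag).
    """
    res = structure.residue(motif_chain, motif_resnum)
    if res is None:
        raise ValueError(f"motif residue {motif_chain}/{motif_resnum} not in structure")
    motif_xyz = None
    for name in ("OG", "OG1", "CA"):
        motif_xyz = res.coord(name)
        if motif_xyz is not None:
            break
    if motif_xyz is None:
        raise ValueError(f"motif residue {motif_chain}/{motif_resnum} has no OG/OG1/CA atom")

    points: list[np.ndarray] = []
    if ligand_name is not None:
        for _cid, lig in structure.ligands:
            if lig.name == ligand_name:
                points.extend(
                    a.xyz for a in lig.atoms.values() if not a.name.startswith("H")
                )
        if not points:
            raise ValueError(f"ligand {ligand_name!r} not found in structure")
    elif pocket_residues:
        missing = []
        for cid, num in pocket_residues:
            pres = structure.residue(cid, num)
            xyz = pres.coord("CA") if pres is not None else None
            if xyz is None:
                missing.append(f"{cid}/{num}")
            else:
                points.append(xyz)
        if missing:
            raise ValueError(f"pocket residues missing: {', '.join(missing)}")
    else:
        raise ValueError("either pocket_residues or ligand_name is required")
    centroid = np.mean(np.stack(points), axis=0)
    dist = float(np.linalg.norm(motif_xyz - centroid))
    return dist, dist <= proximal_cutoff
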