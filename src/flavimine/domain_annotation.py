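"""Domain-family annotation: hmmsearch tblout ingestion and a PSSM scanner.

Two routes assign protein families.  The fidelity route ingests HMMER3
``hmmsearch --tblout`` tables produced externally.  The self-contained
route scores ungapped windows against a position-specific scoring matrix
(log-odds bits over the 20 amino acids) and attaches an empirical
p-value obtained by re-scanning seeded shuffles of the query sequence.
Either way, each protein is annotated by its single best match below an
E-value (or empirical p-value) cutoff, following common practice in
large-scale Pfam annotation (cutoff 0.001 by default).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_EVALUE_CUTOFF = 1e-3
DEFAULT_N_SHUFFLES = 200

# hmmsearch --tblout: 18 fixed whitespace-separated fields, then free-text
# description.  Field indices used below follow the HMMER3 user guide.
_TBLOUT_MIN_FIELDS = 18


class TbloutError(ValueError):
    """Raised for rows that do not follow the tblout field layout."""


@dataclass
class DomainProfile:
    """An ungapped scoring profile over the 20 amino acids.

    ``columns`` is a (length, 20) array of per-position log-odds scores in
    bits relative to ``background`` frequencies.
    """

    accession: str
    name: str
    columns: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("profile columns must be an (L, 20) array")
        if self.columns.shape[0] < 1:
            raise ValueError("profile needs at least one column")
        if not np.all(np.isfinite(self.columns)):
            raise ValueError("profile scores must be finite")
        if self.background is None:
            self.background = np.full(20, 1 / 20)

    def __len__(self) -> int:
        return self.columns.shape[0]


@dataclass(frozen=True)
class DomainHit:
    """A (protein, family) assignment with its score and significance.

    ``evalue`` holds the full-sequence E-value for tblout hits or the
    shuffle-based empirical p-value for scanner hits.  Alignment
    coordinates are 1-based inclusive; they are ``None`` for tblout hits
    because the per-sequence table does not carry them.
    """

    protein_id: str
    accession: str
    bit_score: float
    evalue: float
    ali_start: int | None = None
    ali_end: int | None = None
    is_best: bool = False


def read_tblout(path: str | Path) -> list[DomainHit]:
    """Parse an ``hmmsearch --tblout`` file into DomainHits.

    One hit per non-comment row; the family accession is taken from the
    query accession field, falling back to the query name when hmmsearch
    printed '-'.  Full-sequence E-value and bit score are used.
    """
    hits: list[DomainHit] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _TBLOUT_MIN_FIELDS:
            raise TbloutError(
                f"{path}:{lineno}: expected >= {_TBLOUT_MIN_FIELDS} fields, "
                f"got {len(fields)}"
            )
        accession = fields[3] if fields[3] != "-" else fields[2]
        try:
            evalue = float(fields[4])
            score = float(fields[5])
        except ValueError as exc:
            raise TbloutError(f"{path}:{lineno}: non-numeric E-value/score") from exc
        if evalue < 0:
            raise TbloutError(f"{path}:{lineno}: negative E-value")
        hits.append(
            DomainHit(
                protein_id=fields[0], accession=accession,
                bit_score=score, evalue=evalue,
            )
        )
    return hits


def encode_sequence(seq: str) -> np.ndarray:
    """Map a protein sequence to alphabet indices; unknown letters -> -1."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in seq.upper()], dtype=np.int64)


def _window_scores(idx: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Scores of every ungapped window; ambiguous letters score the
    background-expected 0 bits (neutral)."""
    length = columns.shape[0]
    n_win = idx.size - length + 1
    scores = np.zeros(n_win)
    for k in range(length):
        sub = idx[k : k + n_win]
        col = columns[k]
        contrib = np.where(sub >= 0, col[np.clip(sub, 0, 19)], 0.0)
        scores += contrib
    return scores


def pssm_scan(
    seq: str,
    profile: DomainProfile,
    protein_id: str = "",
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> DomainHit | None:
    """Best ungapped window of ``profile`` along ``seq`` with empirical p-value.

    Returns the maximum-scoring window (leftmost on ties) or None when the
    sequence is shorter than the profile.  Significance is the fraction of
    ``n_shuffles`` seeded residue shuffles of the sequence whose own best
    window scores at least as high as the observed best.
    """
    idx = encode_sequence(seq)
    length = len(profile)
    if idx.size < length:
        return None
    scores = _window_scores(idx, profile.columns)
    best = int(np.argmax(scores))  # argmax returns the leftmost maximum
    best_score = float(scores[best])

    rng = np.random.default_rng(seed)
    if n_shuffles > 0:
        shuffled = rng.permuted(
            np.broadcast_to(idx, (n_shuffles, idx.size)).copy(), axis=1
        )
        n_win = idx.size - length + 1
        acc = np.zeros((n_shuffles, n_win))
        for k in range(length):
            sub = shuffled[:, k : k + n_win]
            acc += np.where(sub >= 0, profile.columns[k][np.clip(sub, 0, 19)], 0.0)
        exceed = int(np.sum(acc.max(axis=1) >= best_score))
        pvalue = exceed / n_shuffles
    else:
        pvalue = 0.0
    return DomainHit(
        protein_id=protein_id,
        accession=profile.accession,
        bit_score=best_score,
        evalue=pvalue,
        ali_start=best + 1,
        ali_end=best + length,
    )


def assign_best(
    hits: list[DomainHit], evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, DomainHit]:
    """Pick at most one best-match hit per protein.

    Among hits at or below the cutoff, the lowest E-value wins; ties are
    broken by higher bit score, then lexicographically smaller accession,
    so the result does not depend on input order.  Proteins with no
    passing hit are absent from the result (unannotated).
    """
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        cur = best.get(hit.protein_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.protein_id] = hit
    return {pid: replace(h, is_best=True) for pid, h in best.items()}


def _hit_rank(hit: DomainHit) -> tuple[float, float, str]:
    return (hit.evalue, -hit.bit_score, hit.accession)


def annotate_with_profiles(
    proteome: dict[str, str],
    profiles: list[DomainProfile],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
) -> dict[str, DomainHit]:
    """Scan every protein with every profile and keep best matches.

    The shuffle seed is derived deterministically from the master seed and
    the (protein, profile) identity so results are order-independent.
    """
    hits: list[DomainHit] = []
    for pid, seq in proteome.items():
        for profile in profiles:
            sub = np.random.SeedSequence(
                [seed, zlib.crc32(pid.encode()), zlib.crc32(profile.accession.encode())]
            )
            hit = pssm_scan(
                seq, profile, protein_id=pid, n_shuffles=n_shuffles,
                seed=int(sub.generate_state(1)[0] & 0x7FFFFFFF),
            )
            if hit is not None:
                hits.append(hit)
    return assign_best(hits, evalue_cutoff=evalue_cutoff)


def write_profile_tsv(profile: DomainProfile, path: str | Path) -> None:
    """Serialize a profile as TSV: header row, then one row per column
    with 20 score fields ordered by the canonical alphabet."""
    lines = [f"# accession={profile.accession}\tname={profile.name}"]
    lines.append("\t".join(AMINO_ACIDS))
    for row in profile.columns:
        lines.append("\t".join(f"{x:.6g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_tsv(path: str | Path) -> DomainProfile:
    lines = Path(path).read_text().splitlines()
    meta = {"accession": Path(path).stem, "name": Path(path).stem}
    rows: list[list[float]] = []
    for line in lines:
        if line.startswith("#"):
            for item in line[1:].split("\t"):
                key, _, value = item.strip().partition("=")
                if key in meta:
                    meta[key] = value
            continue
        if not line.strip() or line.replace("\t", "") .isalpha():
            continue
        rows.append([float(x) for x in line.split("\t")])
    return DomainProfile(meta["accession"], meta["name"], np.array(rows))
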