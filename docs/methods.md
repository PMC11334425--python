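# Methods

flavimine implements a comparative-genomics + structural-signature
pipeline for discovering candidate substrates and machinery of
ApbE-mediated protein flavinylation — the covalent attachment of FMN to
a serine/threonine inside an [S/T]GA[S/T]-like motif, a modification
characteristic of extracytosolic electron transfer systems in bacteria
and archaea.  This note records the models, parameter choices and
numerical conventions the package uses, and what its synthetic fixtures
do and do not demonstrate.

## Gene-neighborhood mining

A genome is a set of contigs, each an ordered list of genes.  After
reading (GFF3 CDS features or a plain TSV), genes are sorted by start
coordinate and assigned dense 0-based ordinals per contig, so all
neighborhood arithmetic is in *genes*, never base pairs: the window
around an anchor at ordinal *a* is ordinals `[max(0, a-k), min(n-1,
a+k)]` with `k = 5` by default.  Strand is recorded but plays no role in
windowing, windows are clipped at contig ends, and overlapping windows
around distinct anchors are kept separate — there is no merge rule and
no operon model.  Pseudogene/non-coding rows present in the input count
toward the window like any other row.  Co-localization frequency of a
target family is the fraction of anchor windows containing at least one
protein best-matched to that family, reported overall and per phylum.
The pipeline reports frequencies and leaves any "frequently
co-localized" cutoff to configuration.

## Domain annotation

Each protein receives at most one best-match family.  Two routes:

* **tblout ingestion** — rows of `hmmsearch --tblout` tables
  (whitespace-delimited, 18 fixed fields + description) are read with
  their full-sequence E-value and bit score.  Alignment coordinates are
  not present in this table format and are left unset.
* **built-in PSSM scanner** — an ungapped position-specific scoring
  matrix (log-odds bits over the 20 amino acids) is slid along the
  sequence; the best-scoring window wins, leftmost on ties.
  Significance is an empirical p-value: the fraction of `N` seeded
  residue shuffles of the query whose own best window scores at least
  as high (default `N = 200`).  The p-value is the plain count/N
  without a +1 pseudocount, so a hit that no shuffle matches gets
  p = 0 and can pass arbitrarily strict cutoffs; the granularity of the
  estimate is 1/N, and on null sequences the false-positive rate at
  cutoff α is ≈ max(α, 1/N).  The scanner is a self-contained stand-in
  for profile-HMM search, not a reimplementation of it; ungapped
  scoring cannot model indels, and the tblout route is the fidelity
  path for real data.

Best-match selection: among hits with E-value (or empirical p) ≤ cutoff
(default 0.001), the lowest E-value wins; ties break by higher bit
score, then lexicographically smaller accession, making the result
independent of hit order.  Whether per-domain or full-sequence E-values
define "best" is a genuine ambiguity in common practice; full-sequence
E-values are used here.

## Motif scanning and candidate calling

The default motif is exactly `[ST] G A [ST]` with the final S/T as the
flavinylated residue.  Degenerate variants ("[S/T]GA[S/T]-like") are
expressible through `MotifPattern` but off by default, since no
principled enumeration of tolerated deviations exists.  All matches are
reported at step 1 with overlaps allowed; `X` never matches.  A protein
becomes a **candidate flavinylation substrate** iff (a) its best-match
family is one of the configured target families (defaults: Flavodoxin_4
PF12682, FMN_red PF03358, DUF4405 PF14358), (b) it lies inside an
anchor (ApbE, PF02424) window, and (c) it carries ≥ 1 motif site.
Proteins with ≥ 3 sites are flagged multi-flavinylated, following the
convention that "multi" means more than two flavinylated domains.  No
signal-peptide or localization filter is applied.  `mutate_site`
implements the in-silico analogue of the alanine point mutation that
ablates a predicted site.

## Conservation

Per-column information content is `log2(20) − H(p)` in bits, with `p`
the residue frequencies among non-gap characters; gaps are excluded
rather than treated as a 21st symbol, matching standard logo practice.
Columns with occupancy < 0.5 are flagged low-occupancy (not dropped);
all-gap columns have undefined IC.  No small-sample correction is
applied by default — the intended use is alignments of hundreds of
rows, where the uniform-column bias `(19)/(2 N ln 2)` is ≈ 0.0014 bits
at N = 10,000 and ≈ 0.07 bits at N = 200, well below the 3-bit
threshold used to call strongly conserved columns.  Consensus ties
break alphabetically.  `map_column_to_structure` converts a column to
the ungapped residue number of a reference row, for cross-referencing
conserved histidines/threonines against coordinate models.

## Structure-level signatures

**PDB input** — first MODEL only; among altloc copies of an atom the
highest occupancy wins; HETATM ligands (FMN, HEM, ...) are kept apart
from polymer chains; waters are dropped.

**Transmembrane segments** — sequence-based Kyte-Doolittle sliding
windows (window 19, threshold 1.6, both configurable).  Every window
whose mean hydropathy clears the threshold marks its residues; the
union of overlapping qualifying windows forms one maximal segment, so
segments are always ≥ 19 residues.  A segment's reported hydropathy is
the *peak* window mean inside it, which is the quantity the threshold
acts on; the edge residues of a segment can individually be polar.
Membrane-plane fitting in 3D is deliberately out of scope — the six-TM
topology of DUF4405-like cytochromes is a sequence-level call here.

**Bis-His heme sites** — all histidine pairs whose NE2 atoms (ND1 when
NE2 is absent) lie within 6.0 Å are candidates; axial His-Fe-His
coordination across a heme iron puts the two N atoms ≈ 4.2 Å apart, and
6.0 Å leaves room for model error while excluding non-coordinating
pairs.  Same-chain pairs must be ≥ 10 residues apart in sequence
(adjacent histidines cannot flank a heme plane); cross-chain pairs have
no separation constraint, which is what lets a homodimer interface
(FezC-like) form a site from one His per protomer.  Both numbers are
configurable; they are geometric conventions, not fitted values.

**Superposition** — Kabsch's closed-form least-squares rigid
superposition via SVD of the cross-covariance matrix, with the
determinant correction enforcing a proper rotation (det +1).  The
correspondence is an input; sequence-independent structure alignment is
out of scope.  Degenerate inputs (< 3 pairs, collinear points) are
rejected.  Tests cross-check against an independent brute-force
rotation search (coarse random-rotation scan refined by Nelder-Mead).

**Motif-to-pocket distance** — Euclidean distance from the motif
Ser/Thr hydroxyl oxygen (OG/OG1, CA fallback) to the centroid of a
flavin pocket, defined either by named residues' CA atoms or by a bound
ligand's heavy atoms; a boolean "proximal" flag is attached at a
configurable cutoff (default 15 Å, roughly the span a flavinylated
segment must bridge for the covalent flavin to reach a non-covalent
binding site).  Only the static distance is computed; tether-reach or
conformational sampling is not modelled.

## Taxonomy

Distribution tables count *genomes*, not proteins: a genome with four
candidates contributes once to its taxon's numerator.  Protein-level
counts are emitted alongside.  Lineages are GTDB-style seven-rank
strings (`d__;p__;...`); per-phylum tables use rank 2.  No
normalization beyond the per-taxon fraction is applied.

## Synthetic data: what it emulates and what it does not

The generator emits the exact formats the pipeline reads (gene TSV,
FASTA, lineage strings, tblout, profile TSV, PDB) plus a JSON
ground-truth manifest.  Design choices:

* **Genomes** — one contig of `genes_per_contig` genes; every genome
  carries one anchor gene; with probability `p_cluster` a target-family
  gene is planted at a uniform nonzero offset within ±k.  Background
  proteins are rejection-sampled to contain neither motif matches nor
  family signatures, so planted counts are exact ground truth — a
  deliberate bias relative to nature, where [S/T]GA[S/T] occurs by
  chance (expected ≈ 0.0075 matches per 300-residue protein).  Planted
  domains are realized as fixed 12-residue signature peptides that the
  matching PSSM profiles score at +24 bits, and equivalently as rows of
  a generated tblout table (E = 1e-20).  The end-to-end runs use the
  tblout route: an empirical-p scanner has, by construction, a ≈ 1/N
  false-positive rate on null sequences, which at thousands of
  background proteins would plant occasional spurious anchors; the
  noise-free recovery contract (precision = recall = 1) is about the
  mining logic, not about scanner calibration, which is tested
  separately.  Phylum labels are drawn 60/25/10/5% from Firmicutes /
  Proteobacteria / Bacteroidota / Actinobacteriota, echoing the
  Firmicutes-dominant distributions typical of flavinylation clusters.
* **MSAs** — planted columns draw their designated residue with
  probability `planted_conservation` (default 0.95, the regime of
  "most highly conserved residue in the family"); all other cells are
  uniform over 20 residues.  Real alignments have phylogenetic
  correlation and gaps; these do not, so recovering planted columns
  shows detector correctness, not robustness to alignment error.
* **Structures** — CA traces on ideal helix geometry (rise 1.5 Å,
  100°/residue) with NE2 pseudo-atoms at exact configured coordinates;
  no side chains, no packing.  Sufficient for the geometric detectors;
  nothing about these models tests behaviour on real (e.g. predicted)
  coordinates beyond format handling.

All randomness flows from a single seed through named independent
streams; identical configs give byte-identical files.

## Determinism and output conventions

Tables are TSV (header row, UTF-8, '.' decimal, `%.6g` floats); each
run writes a JSON manifest with parameters, seed and SHA-256 input
checksums, and contains no timestamps, so re-running an identical
config reproduces every output byte for byte.  Outputs are computed
fully in memory and written through temp-file + atomic rename; a
failing run leaves no partial tables.  Table columns are documented in
`docs/output_schemas.md`.

## Problem sizes

The reference synthetic study set is 200 genomes × 40 genes with
`p_cluster = 0.5` (~8,000 proteins), which the full mining run
processes in a few seconds; scanner and geometry oracles use 200–1,000
random cases.  These sizes give binomial standard errors of ~3–4% on
recovered frequencies while keeping the whole suite fast.

## Known limitations

* The PSSM scanner is ungapped; real domains with indels need the
  hmmsearch route.
* "Best match" uses full-sequence E-values; per-domain selection may
  differ for multi-domain proteins.
* TM calling is hydropathy-only; re-entrant helices and amphipathic
  helices are out of reach.
* The heme detector proposes geometric candidates; it does not verify
  heme presence, iron coordination chemistry, or conservation — those
  are separate evidence streams the analysis combines downstream.
* Candidate calling is evidence of association, not proof of
  flavinylation; experimental validation is outside the package's
  scope.
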