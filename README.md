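# flavimine

Mining prokaryotic genomes and structure models for flavinylation-based
extracytosolic electron transfer systems.

Many bacteria move electrons across and beyond their membrane using
proteins that carry a *covalently* attached FMN.  The FMN transferase
ApbE installs this modification on the final serine/threonine of an
`[S/T]GA[S/T]`-like motif, and the genes encoding flavinylated proteins
cluster on the chromosome with *apbE* and with the membrane machinery
(transmembrane cytochromes, Nqr/Rnf-like complexes) that feeds them
electrons.  flavimine turns that observation into a tested discovery
pipeline for comparative genomicists and structural bioinformaticians:

* **gene-neighborhood mining** — find genes of chosen Pfam families in
  the ±k-gene window around *apbE* anchors (k = 5 by default), using
  best-match domain annotation (hmmsearch `--tblout` input or a
  built-in PSSM scanner) with an E-value cutoff of 0.001;
* **motif scanning** — locate `[S/T]GA[S/T]` flavinylation sites,
  promote co-localized motif-bearing proteins of target families
  (Flavodoxin_4, FMN_red, DUF4405) to candidate substrates, and flag
  multi-flavinylated proteins (≥ 3 sites);
* **conservation** — per-column information content
  `IC = log2 20 − H(p)` from an MSA, recovery of near-invariant
  residues (heme-coordinating His, flavinylated Thr) and mapping onto a
  reference structure;
* **structure signatures** — Kyte-Doolittle transmembrane segments
  (window 19, threshold 1.6), bis-His heme-site candidates
  (NE2-NE2 ≤ 6 Å, within or across chains), Kabsch least-squares
  superposition with RMSD, and motif-to-flavin-pocket distances in PDB
  models;
* **taxonomy** — per-phylum distributions of candidate-bearing genomes
  from GTDB-style lineage strings;
* **synthetic data** — a seeded generator that plants anchor+target
  clusters, motif sites, conserved columns and His pairs with exact
  ground-truth manifests, so every detector is testable end to end.

## Worked example

Generate a synthetic study set (200 genomes × 40 genes; every genome
has an *apbE*-like anchor, half also carry a planted target within ±5
genes), then mine it:

```bash
python analysis/01_simulate.py
python analysis/02_mine.py
```

which prints:

```
simulated 200 genomes (40 genes each) -> results/data
planted anchor genes: 200
planted (anchor, target) pairs: 93 (p_cluster=0.5)
phylum composition: {'Firmicutes': 129, 'Proteobacteria': 46, 'Bacteroidota': 14, 'Actinobacteriota': 11}
anchor windows: 200
candidate calls: 93  (planted pairs: 93)
precision: 1.000   recall: 1.000
co-localization frequency by target family (overall):
target_family   scope  n_windows  n_with_target  fraction
      PF12682 overall        200             29     0.145
      PF03358 overall        200             31     0.155
      PF14358 overall        200             33     0.165
```

Reading: every one of the 200 anchor windows was extracted; all 93
planted (anchor, target) pairs — and nothing else — were called as
candidate flavinylation substrates (a candidate must be in an anchor
window, best-matched to a target family, and carry ≥ 1 motif site).
The per-family co-localization fractions sum to ≈ 0.465, the realized
planting rate of `p_cluster = 0.5` split across the three target
families.  `analysis/03_conservation.py` and
`analysis/04_structure_features.py` run the conservation and structure
detectors the same way (planted His columns recovered exactly; a
six-helix protein yields exactly 6 TM segments; a planted His pair at
4.2 Å is the only heme-site candidate).

The same steps are available as a CLI for real inputs:

```bash
flavimine simulate --seed 1 --n-genomes 20 --out-dir demo
flavimine mine --genomes-dir demo/genomes --lineages demo/lineages.tsv \
               --tblout demo/annotations.tblout --out-dir demo_out
flavimine structure --structures-dir models/ --out-dir struct_out
flavimine conservation family_alignment.fasta --out-dir cons_out
```

Output tables are documented in `docs/output_schemas.md`; the models
and parameter choices in `docs/methods.md`.

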