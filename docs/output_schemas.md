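# Output table schemas

All tables are tab-delimited with a header row, UTF-8, '.' decimal
separator, floats formatted `%.6g`.  Booleans are `True`/`False`.

## mine run (`flavimine mine` / `run_mine`)

### clusters.tsv — one row per (anchor window, member gene)
| column | meaning |
|---|---|
| cluster_idx | 0-based index of the anchor window within the run |
| genome_id | genome of the window |
| contig_id | contig of the window |
| anchor_gene | gene_id of the anchor-family gene |
| member_gene | gene_id of this window member |
| member_ordinal | 0-based position of the member along its contig |
| member_protein | protein_id of the member, `.` if non-coding |
| member_family | best-match family accession of the member, `.` if unannotated or not anchor/target |
| strand | `+` or `-` |

### cluster_summary.tsv — one row per anchor window
| column | meaning |
|---|---|
| cluster_idx | as above |
| genome_id / contig_id / anchor_gene / anchor_protein | anchor identity |
| n_members | window size after clipping at contig ends (≤ 2k+1) |
| has_&lt;accession&gt; | one boolean column per target family: family present in window |

### motif_sites.tsv — one row per motif match
| column | meaning |
|---|---|
| protein_id | protein scanned |
| start | 1-based start of the match |
| matched | matched residues |
| flavinylated_pos | 1-based position of the modified S/T |

### candidates.tsv — one row per (window, candidate protein)
| column | meaning |
|---|---|
| protein_id | candidate protein |
| family | its best-match target-family accession |
| n_sites | number of motif sites in the protein |
| multi_flavinylated | n_sites ≥ 3 |
| cluster_idx | window the call comes from |
| genome_id | genome of the candidate |
| anchor_gene | anchor gene of that window |

### colocalization.tsv — target-family frequency in anchor windows
| column | meaning |
|---|---|
| target_family | family accession |
| scope | `overall` or `p__<phylum>` |
| n_windows | anchor windows in scope |
| n_with_target | windows containing the family |
| fraction | n_with_target / n_windows |

### taxonomy.tsv — per-taxon candidate distribution
| column | meaning |
|---|---|
| rank | taxonomic rank tabulated (default phylum) |
| taxon | taxon name (empty = unassigned) |
| n_genomes_with_feature | genomes with ≥ 1 candidate (counted once) |
| n_genomes_total | genomes in the taxon |
| fraction | n_with / n_total |
| n_feature_proteins | candidate calls summed over genomes (protein-level) |

### manifest.json
Provenance: tool/version, command, seed, full parameter set, SHA-256
checksums per input, and run-level counts.  No timestamps (outputs are
byte-reproducible).

## structure run (`flavimine structure` / `run_structure`)

### tm_segments.tsv
| column | meaning |
|---|---|
| structure | PDB file stem |
| chain | chain id |
| start / end | 1-based residue range of the segment in the chain sequence |
| peak_hydropathy | maximal 19-residue window mean Kyte-Doolittle value inside the segment |

### heme_pairs.tsv
| column | meaning |
|---|---|
| structure | PDB file stem |
| chain_a / res_a / chain_b / res_b | the two histidines |
| atom | coordinating atom name (NE2, ND1, or mixed `NE2/ND1`) |
| distance | inter-atom distance, Å |
| same_chain | both His on one chain |
| seq_separation | residue separation for same-chain pairs, `-1` cross-chain |

## conservation run (`flavimine conservation` / `run_conservation`)

### conservation_&lt;msa&gt;.tsv — one row per alignment column
| column | meaning |
|---|---|
| column | 1-based alignment column |
| occupancy | fraction of non-gap rows |
| ic_bits | log2(20) − H(p) over non-gap residues; NaN if all-gap |
| consensus | most frequent residue (alphabetical tie-break), `.` if all-gap |
| low_occupancy | occupancy < 0.5 |

### conserved_columns.tsv
| column | meaning |
|---|---|
| msa | alignment name |
| residue | residue class searched (His, Thr) |
| column | conserved column index (IC ≥ min_ic, occupancy ≥ min) |

## synthetic fixtures (`flavimine simulate` / `write_genome_set`)

`genomes/<id>.genes.tsv` (gene_id, contig_id, start, end, strand,
protein_id), `genomes/<id>.faa`, `lineages.tsv` (genome_id, GTDB-style
lineage), `annotations.tblout` (hmmsearch tblout dialect),
`profiles/<accession>.tsv` (one row per profile column, 20 log-odds
scores in canonical amino-acid order), `ground_truth.json` (planted
anchors, pairs with offsets, motif positions per protein, planted MSA
columns, planted His sites).
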