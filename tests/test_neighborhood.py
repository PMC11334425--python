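import pytest

from flavimine.domain_annotation import DomainHit
from flavimine.genome_io import GeneRecord, GenomeRecord, _index_contigs
from flavimine.neighborhood import (
    colocalization_frequency,
    extract_window,
    find_colocalized,
)
from flavimine.synthetic import ANCHOR_FAMILY, planted_annotations


def _contig(n):
    genes = [
        GeneRecord(f"g{i}", "c1", i * 100 + 1, i * 100 + 90, "+", f"p{i}")
        for i in range(n)
    ]
    return _index_contigs(genes)["c1"]


def _genome(families: dict[int, str], n=20, genome_id="G", phylum="Firmicutes"):
    """A toy genome with given ordinal -> family annotations."""
    contig = _contig(n)
    genes = {g.gene_id: g for g in contig}
    genome = GenomeRecord(
        genome_id=genome_id,
        contigs={"c1": contig},
        proteome={g.protein_id: "M" for g in contig},
        lineage=["Bacteria", phylum, "", "", "", "", ""],
    )
    annotations = {
        f"p{ordinal}": DomainHit(f"p{ordinal}", fam, 50.0, 1e-10, is_best=True)
        for ordinal, fam in families.items()
    }
    return genome, annotations, genes


class TestExtractWindow:
    def test_interior_window_has_2k_plus_1_genes(self):
        window = extract_window(_contig(20), 10, k=5)
        assert [g.ordinal for g in window] == list(range(5, 16))

    def test_clipped_at_contig_start(self):
        window = extract_window(_contig(20), 0, k=5)
        assert [g.ordinal for g in window] == list(range(0, 6))

    def test_single_gene_contig(self):
        window = extract_window(_contig(1), 0, k=5)
        assert [g.ordinal for g in window] == [0]

    def test_invalid_anchor_rejected(self):
        with pytest.raises(ValueError):
            extract_window(_contig(5), 7, k=5)

    def test_window_edge_law_exhaustive(self):
        """|window| = min(a,5) + min(n-1-a,5) + 1 for every anchor on n=20."""
        contig = _contig(20)
        for a in range(20):
            assert len(extract_window(contig, a, k=5)) == min(a, 5) + min(19 - a, 5) + 1

    def test_symmetric_under_genome_reversal(self):
        contig = _contig(15)
        reversed_genes = [
            GeneRecord(g.gene_id, "c1", 10_000 - g.end, 10_000 - g.start, g.strand,
                       g.protein_id)
            for g in contig
        ]
        rev = _index_contigs(reversed_genes)["c1"]
        for a in range(15):
            fwd_ids = {g.gene_id for g in extract_window(contig, a, k=4)}
            rev_ids = {g.gene_id for g in extract_window(rev, 14 - a, k=4)}
            assert fwd_ids == rev_ids


class TestFindColocalized:
    def test_target_inside_window_flagged(self):
        genome, annotations, _ = _genome({7: "PF02424", 9: "PF12682"})
        clusters = find_colocalized([genome], annotations, "PF02424", {"PF12682"})
        assert len(clusters) == 1
        assert clusters[0].contains_family("PF12682")
        assert clusters[0].family_content["PF12682"] == ["p9"]

    def test_target_beyond_k_not_flagged(self):
        genome, annotations, _ = _genome({0: "PF02424", 6: "PF12682"})
        clusters = find_colocalized([genome], annotations, "PF02424", {"PF12682"})
        assert not clusters[0].contains_family("PF12682")

    def test_two_anchors_two_overlapping_clusters(self):
        genome, annotations, _ = _genome({8: "PF02424", 11: "PF02424"})
        clusters = find_colocalized([genome], annotations, "PF02424", set())
        assert len(clusters) == 2
        shared = set(clusters[0].member_ids()) & set(clusters[1].member_ids())
        assert shared

    def test_unknown_anchor_family_rejected(self):
        genome, annotations, _ = _genome({3: "PF02424"})
        with pytest.raises(ValueError, match="anchor family"):
            find_colocalized([genome], annotations, "PF99999", set())

    def test_perfect_recovery_on_noise_free_planting(self, small_sim):
        cfg, genomes, truth = small_sim
        annotations = {
            pid: DomainHit(pid, fam, 150.0, 1e-20, is_best=True)
            for pid, fam in planted_annotations(genomes, truth).items()
        }
        targets = {p["family"] for p in truth.pairs}
        clusters = find_colocalized(
            genomes, annotations, ANCHOR_FAMILY, targets, k=cfg.window_k
        )
        found = {
            (c.genome_id, c.anchor.gene_id, pid)
            for c in clusters
            for fam, pids in c.family_content.items()
            if fam != ANCHOR_FAMILY
            for pid in pids
        }
        planted = {
            (p["genome_id"], p["anchor_gene"], p["target_protein"])
            for p in truth.pairs
        }
        assert found == planted  # precision = recall = 1.0


class TestColocalizationFrequency:
    def test_simple_fraction(self):
        rows = []
        for i, has_target in enumerate([True, True, True, False]):
            families = {5: "PF02424"}
            if has_target:
                families[7] = "PF12682"
            genome, annotations, _ = _genome(families, genome_id=f"G{i}")
            rows.append(
                find_colocalized([genome], annotations, "PF02424", {"PF12682"})[0]
            )
        overall, _table = colocalization_frequency(rows, "PF12682")
        assert overall == 0.75

    def test_zero_when_never_present(self):
        genome, annotations, _ = _genome({5: "PF02424"})
        clusters = find_colocalized([genome], annotations, "PF02424", {"PF12682"})
        overall, _ = colocalization_frequency(clusters, "PF12682")
        assert overall == 0.0

    def test_empty_cluster_list_undefined(self):
        with pytest.raises(ValueError):
            colocalization_frequency([], "PF12682")

    def test_per_phylum_table_uses_lineage(self):
        clusters, genomes = [], []
        for i, phylum in enumerate(["Firmicutes", "Proteobacteria"]):
            genome, annotations, _ = _genome(
                {5: "PF02424", 7: "PF12682"} if i == 0 else {5: "PF02424"},
                genome_id=f"G{i}", phylum=phylum,
            )
            genomes.append(genome)
            clusters.extend(
                find_colocalized([genome], annotations, "PF02424", {"PF12682"})
            )
        _overall, table = colocalization_frequency(clusters, "PF12682", genomes)
        by_phylum = dict(zip(table.phylum, table.fraction))
        assert by_phylum == {"Firmicutes": 1.0, "Proteobacteria": 0.0}

    def test_binomial_recovery_of_planting_probability(self):
        """Frequency over planted genomes estimates p_cluster to 3 SE."""
        import numpy as np

        from flavimine.synthetic import SimConfig, simulate_genomes

        p = 0.6
        cfg = SimConfig(seed=3, n_genomes=500, genes_per_contig=12, p_cluster=p,
                        protein_len_range=(60, 120))
        genomes, truth = simulate_genomes(cfg)
        annotations = {
            pid: DomainHit(pid, fam, 150.0, 1e-20, is_best=True)
            for pid, fam in planted_annotations(genomes, truth).items()
        }
        clusters = find_colocalized(
            genomes, annotations, ANCHOR_FAMILY,
            set(p_["family"] for p_ in truth.pairs), k=cfg.window_k,
        )
        hit = sum(
            any(f != ANCHOR_FAMILY for f in c.family_content) for c in clusters
        )
        frac = hit / len(clusters)
        se = np.sqrt(p * (1 - p) / len(clusters))
        assert abs(frac - p) <= 3 * se
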