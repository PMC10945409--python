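"""GFF parsing, tandem-cluster detection, TRG arrays, microsynteny."""

import itertools

import pytest

from ampatlas.genome import (
    GeneModel,
    GenomeError,
    assign_families,
    cluster_summary,
    detect_clusters,
    read_gff,
    scan_trg_clusters,
    synteny_presence,
)
from ampatlas.peptides import Peptide

TOY_GFF = """##gff-version 3
chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\tCDS\t1000\t1300\t.\t+\t0\tID=g1.c1;Parent=g1.t1
chr1\tsrc\tCDS\t1500\t2000\t.\t+\t0\tID=g1.c2;Parent=g1.t1
chr2\tsrc\tgene\t500\t800\t.\t-\t.\tID=g2
chr1\tsrc\tgene\t9000\t9500\t.\t+\t.\tID=g3
"""


def gm(gene_id, scaffold, start, end, family="f", species="sp", cds=300):
    return GeneModel(gene_id, scaffold, start, end, "+", species, family, cds)


class TestReadGff:
    def test_toy_file(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(TOY_GFF)
        genes = read_gff(path, species="hv")
        assert [g.gene_id for g in genes] == ["g1", "g3", "g2"]
        g1 = genes[0]
        assert (g1.scaffold, g1.start, g1.end, g1.strand) == ("chr1", 1000, 2000, "+")
        assert g1.cds_len == 301 + 501  # summed over both CDS segments
        assert genes[2].strand == "-"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.gff3"
        path.write_text("##gff-version 3\n")
        assert read_gff(path) == []

    def test_assign_families(self):
        genes = [gm("a", "c", 1, 10, None), gm("b", "c", 20, 30, None)]
        out = assign_families(genes, {"a": "famX"})
        assert out[0].family_id == "famX" and out[1].family_id is None


def brute_force_clusters(genes, max_gap):
    """Independent interval-run oracle: check every contiguous start-sorted
    slice for the maximal-run property."""
    result = []
    by_scaffold = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        n = len(ordered)
        for i in range(n):
            for j in range(i + 1, n + 1):
                run = ordered[i:j]
                ok = all(
                    run[k + 1].start - run[k].end <= max_gap
                    for k in range(len(run) - 1)
                )
                left_break = i == 0 or ordered[i].start - ordered[i - 1].end > max_gap
                right_break = j == n or ordered[j].start - ordered[j - 1].end > max_gap
                if ok and left_break and right_break and len(run) >= 2:
                    result.append(tuple(g.gene_id for g in run))
    return sorted(result)


class TestDetectClusters:
    def test_pair_plus_singleton(self):
        genes = [
            gm("a", "c", 1_000, 2_000),
            gm("b", "c", 5_000, 6_000),
            gm("z", "c", 500_000, 501_000),
        ]
        clusters, unclustered = detect_clusters(genes, 100_000)
        assert [c.members for c in clusters] == [("a", "b")]
        assert [g.gene_id for g in unclustered] == ["z"]

    def test_all_gaps_large_no_clusters(self):
        genes = [gm(f"g{i}", "c", i * 500_000, i * 500_000 + 100) for i in range(1, 5)]
        clusters, unclustered = detect_clusters(genes, 100_000)
        assert clusters == [] and len(unclustered) == 4

    def test_mixed_family_rejected(self):
        with pytest.raises(GenomeError):
            detect_clusters([gm("a", "c", 1, 2, "f1"), gm("b", "c", 5, 6, "f2")], 10)

    def test_matches_brute_force_oracle(self, rng):
        """Random arrangements agree with the exhaustive run oracle."""
        for rep in range(60):
            n = int(rng.integers(2, 12))
            genes = []
            for i in range(n):
                start = int(rng.integers(1, 400_000))
                genes.append(
                    gm(f"g{i:02d}", f"c{int(rng.integers(1, 3))}", start, start + 500)
                )
            max_gap = int(rng.integers(10_000, 150_000))
            clusters, unclustered = detect_clusters(genes, max_gap)
            assert sorted(c.members for c in clusters) == brute_force_clusters(
                genes, max_gap
            )
            # partition property
            got = sorted(
                itertools.chain(
                    (m for c in clusters for m in c.members),
                    (g.gene_id for g in unclustered),
                )
            )
            assert got == sorted(g.gene_id for g in genes)

    def test_order_and_translation_invariance(self, rng):
        genes = [gm(f"g{i}", "c", 10_000 * i + 1, 10_000 * i + 600) for i in range(6)]
        shuffled = list(genes)
        rng.shuffle(shuffled)
        c1, _ = detect_clusters(genes, 20_000)
        c2, _ = detect_clusters(shuffled, 20_000)
        assert [c.members for c in c1] == [c.members for c in c2]
        moved = [
            GeneModel(g.gene_id, g.scaffold, g.start + 7_777, g.end + 7_777,
                      g.strand, g.species, g.family_id, g.cds_len)
            for g in genes
        ]
        c3, _ = detect_clusters(moved, 20_000)
        assert [c.members for c in c3] == [c.members for c in c1]

    def test_larger_gap_never_shrinks_largest_cluster(self, rng):
        starts = [int(rng.integers(1, 300_000)) for _ in range(10)]
        genes = [gm(f"g{i}", "c", s, s + 400) for i, s in enumerate(starts)]
        prev = 0
        for gap in [5_000, 20_000, 80_000, 320_000]:
            clusters, _ = detect_clusters(genes, gap)
            largest = max((len(c) for c in clusters), default=1)
            assert largest >= prev
            prev = largest


class TestClusterSummary:
    def test_per_scaffold_counts(self):
        genes = [
            gm("a", "c1", 1_000, 2_000),
            gm("b", "c1", 5_000, 6_000),
            gm("c", "c2", 1_000, 2_000),
        ]
        clusters, _ = detect_clusters(genes, 100_000)
        tab = cluster_summary("f", clusters, genes).set_index("scaffold")
        assert tab.loc["c1", "n_members"] == 2
        assert tab.loc["c1", "largest_cluster"] == 2
        assert tab.loc["c2", "n_members"] == 1
        assert tab.loc["c2", "n_clusters"] == 0
        assert tab["n_members"].sum() == 3

    def test_empty_family(self):
        assert cluster_summary("f", [], []).empty


def trg_genes_and_peptides(seq="MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"):
    genes, peps = [], []
    for i in range(12):
        gid = f"t{i:02d}"
        start = 1_000 + i * 2_000
        genes.append(GeneModel(gid, "c", start, start + 3 * len(seq), "+", "sp", None, 3 * len(seq)))
        peps.append(Peptide(gid, "sp", seq, source_gene=gid))
    return genes, peps


class TestTrgScan:
    def test_planted_run_detected(self):
        genes, peps = trg_genes_and_peptides()
        out = scan_trg_clusters(genes, peps, min_run=10, max_cds=1500, id_min=0.3)
        assert len(out) == 1 and len(out[0]) == 12
        assert out[0].mean_identity == pytest.approx(1.0)

    def test_no_short_genes_empty(self):
        genes, peps = trg_genes_and_peptides()
        long_genes = [
            GeneModel(g.gene_id, g.scaffold, g.start, g.end, g.strand,
                      g.species, None, 5_000)
            for g in genes
        ]
        assert scan_trg_clusters(long_genes, peps) == []

    def test_long_gene_splits_run(self):
        genes, peps = trg_genes_and_peptides()
        # make the middle gene too long: each half has < min_run genes
        g = genes[6]
        genes[6] = GeneModel(g.gene_id, g.scaffold, g.start, g.end, g.strand,
                             g.species, None, 9_999)
        assert scan_trg_clusters(genes, peps, min_run=10) == []
        # with a lower min_run both halves qualify
        halves = scan_trg_clusters(genes, peps, min_run=5)
        assert [len(c) for c in halves] == [6, 5]

    def test_dissimilar_run_filtered_by_identity(self, rng):
        from ampatlas.simulate import make_peptide

        genes, _ = trg_genes_and_peptides()
        peps = [
            Peptide(g.gene_id, "sp", make_peptide("decoy", rng, g.gene_id).sequence,
                    source_gene=g.gene_id)
            for g in genes
        ]
        assert scan_trg_clusters(genes, peps, min_run=10, id_min=0.5) == []


def synteny_fixture(with_target_member=True, drop_anchors=0):
    genes = []
    # query: 3 left anchors, 2 family genes, 3 right anchors on qc1
    pos = 1_000
    orthologs = {}
    for i in range(3):
        genes.append(GeneModel(f"qL{i}", "qc1", pos, pos + 500, "+", "Q", None, 500))
        orthologs[f"qL{i}"] = f"tL{i}"
        pos += 10_000
    for i in range(2):
        genes.append(GeneModel(f"qf{i}", "qc1", pos, pos + 500, "+", "Q", "fam", 500))
        pos += 5_000
    for i in range(3):
        genes.append(GeneModel(f"qR{i}", "qc1", pos, pos + 500, "+", "Q", None, 500))
        orthologs[f"qR{i}"] = f"tR{i}"
        pos += 10_000
    # target: anchors around (optionally) a family member
    pos = 2_000
    for i in range(3 - drop_anchors):
        genes.append(GeneModel(f"tL{i}", "tc1", pos, pos + 500, "+", "T", None, 500))
        pos += 10_000
    if with_target_member:
        genes.append(GeneModel("tf0", "tc1", pos, pos + 500, "+", "T", "fam", 500))
        pos += 5_000
    for i in range(3 - drop_anchors):
        genes.append(GeneModel(f"tR{i}", "tc1", pos, pos + 500, "+", "T", None, 500))
        pos += 10_000
    return genes, orthologs


class TestSynteny:
    def test_retained(self):
        genes, orth = synteny_fixture(with_target_member=True)
        v = synteny_presence("fam", "Q", "T", orth, genes, k=3, m_min=3)
        assert v.status == "retained" and v.anchor_count == 6

    def test_lost(self):
        genes, orth = synteny_fixture(with_target_member=False)
        v = synteny_presence("fam", "Q", "T", orth, genes, k=3, m_min=3)
        assert v.status == "lost"

    def test_unclassified_with_too_few_anchors(self):
        genes, orth = synteny_fixture(with_target_member=False, drop_anchors=2)
        v = synteny_presence("fam", "Q", "T", orth, genes, k=3, m_min=3)
        assert v.status == "unclassified"

    def test_family_absent_in_query_is_error(self):
        genes, orth = synteny_fixture()
        with pytest.raises(GenomeError):
            synteny_presence("nope", "Q", "T", orth, genes)

    def test_planted_loss_in_simulation(self, default_sim):
        """The generator's planted family loss is called lost, and the
        retained family retained."""
        v = synteny_presence(
            "hydramacin_like", "speciesA", "speciesB",
            default_sim.orthologs, default_sim.genes,
        )
        assert v.status == "lost"
        r = synteny_presence(
            "periculin_like", "speciesA", "speciesB",
            default_sim.orthologs, default_sim.genes,
        )
        assert r.status == "retained"
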