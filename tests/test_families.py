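"""Alignment, family partitioning, neighbor joining, and clade statistics."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from ampatlas.families import (
    Family,
    FamilyError,
    all_pairs_align,
    build_families,
    build_tree,
    clade_stats,
    neighbor_joining,
    pairwise_align,
)
from ampatlas.peptides import Peptide
from ampatlas.simulate import (
    FamilySpec,
    SimulationConfig,
    make_peptide,
    simulate_family_history,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def pep(seq, pid="p", species="t"):
    return Peptide(id=pid, species=species, sequence=seq)


def gotoh_score(a: str, b: str, open_=10.0, ext=1.0) -> float:
    """Independent affine-gap global DP (first gap residue costs ``open_``)."""
    n, m = len(a), len(b)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(open_ + (i - 1) * ext)
    for j in range(1, m + 1):
        Y[0][j] = -(open_ + (j - 1) * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - open_, X[i - 1][j] - ext, Y[i - 1][j] - open_)
            Y[i][j] = max(M[i][j - 1] - open_, Y[i][j - 1] - ext, X[i][j - 1] - open_)
    return max(M[n][m], X[n][m], Y[n][m])


class TestPairwiseAlign:
    def test_identical_sequences(self):
        r = pairwise_align(pep("MKTAYIAK", "a"), pep("MKTAYIAK", "b"))
        assert r.identity == 1.0 and r.coverage == 1.0

    def test_completely_different(self):
        r = pairwise_align(pep("AAAA", "a"), pep("WWWW", "b"))
        assert r.identity == 0.0

    def test_score_matches_dp_oracle_classic_pair(self):
        r = pairwise_align(pep("HEAGAWGHEE", "a"), pep("PAWHEAE", "b"))
        assert r.score == pytest.approx(gotoh_score("HEAGAWGHEE", "PAWHEAE"))

    def test_score_matches_dp_oracle_random_pairs(self, rng):
        """Exhaustive-DP equality for all random pairs <= 30 aa combined."""
        for _ in range(40):
            la = int(rng.integers(3, 16))
            lb = int(rng.integers(3, min(28 - la, 16) + 1))
            a = "".join(rng.choice(list(AA20), size=la))
            b = "".join(rng.choice(list(AA20), size=lb))
            r = pairwise_align(pep(a, "a"), pep(b, "b"))
            assert r.score == pytest.approx(gotoh_score(a, b)), (a, b)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list(AA20), size=20))
        b = "".join(rng.choice(list(AA20), size=25))
        r1 = pairwise_align(pep(a, "a"), pep(b, "b"))
        r2 = pairwise_align(pep(b, "b"), pep(a, "a"))
        assert r1.score == r2.score
        assert r1.identity == pytest.approx(r2.identity)


class TestBuildFamilies:
    def test_identical_triplet_one_family(self):
        peps = [pep("MKTAYIAKQRDD", f"p{i}") for i in range(3)]
        fams = build_families(peps)
        assert len(fams) == 1 and len(fams[0]) == 3

    def test_unrelated_pair_two_singletons(self):
        peps = [pep("MKTAYIAKQRDD", "a"), pep("GGSPLNHWFCVV", "b")]
        assert len(build_families(peps)) == 2

    def test_partition_property(self, rng):
        peps = [make_peptide("decoy", rng, f"d{i}") for i in range(12)]
        peps += [make_peptide("amp_bipartite", rng, f"a{i}") for i in range(6)]
        fams = build_families(peps)
        members = sorted(m for f in fams for m in f.members)
        assert members == sorted(p.id for p in peps)

    def test_raising_id_min_refines(self, rng):
        peps = [make_peptide("amp_bipartite", rng, f"a{i}") for i in range(8)]
        aln = all_pairs_align(peps)
        for lo, hi in [(0.3, 0.5), (0.5, 0.7), (0.7, 0.9)]:
            coarse = build_families(peps, lo, 0.6, aln)
            fine = build_families(peps, hi, 0.6, aln)
            coarse_of = {m: f.family_id for f in coarse for m in f.members}
            # every fine family must sit inside one coarse family
            for f in fine:
                assert len({coarse_of[m] for m in f.members}) == 1

    def test_invalid_threshold(self):
        with pytest.raises(FamilyError):
            build_families([pep("AAAA")], id_min=1.5)

    def test_planted_family_recovered(self, rng):
        """A simulated 28-member duplication family comes back as one
        component at default thresholds."""
        spec = FamilySpec(
            "fam", "amp_bipartite", {"speciesA": 28},
            {"speciesA": [("chr1", [28])]},
        )
        cfg = SimulationConfig(seed=5, species=("speciesA",), families=(spec,))
        hist = simulate_family_history(spec, cfg, rng)
        peps = [
            Peptide(f"m{i:02d}", "speciesA", s)
            for i, s in enumerate(hist.copies["speciesA"])
        ]
        decoys = [make_peptide("decoy", rng, f"d{i}") for i in range(10)]
        fams = build_families(peps + decoys)
        sizes = sorted(len(f) for f in fams)
        assert max(sizes) == 28


def random_additive_tree(rng, n_taxa):
    """Random binary tree with uniform branch lengths and its exact
    leaf-to-leaf path distances (the additive matrix oracle)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = {t: None for t in taxa}
    edges = {}  # child -> (parent, length)
    pool = list(taxa)
    next_id = 0
    while len(pool) > 1:
        i = int(rng.integers(len(pool)))
        a = pool.pop(i)
        j = int(rng.integers(len(pool)))
        b = pool.pop(j)
        parent = f"n{next_id}"
        next_id += 1
        edges[a] = (parent, float(rng.uniform(0.05, 1.0)))
        edges[b] = (parent, float(rng.uniform(0.05, 1.0)))
        pool.append(parent)
    root = pool[0]

    def path_to_root(x):
        out = {}
        d = 0.0
        while x in edges:
            parent, ln = edges[x]
            d += ln
            out[parent] = d
            x = parent
        return out

    dist = {}
    for a, b in itertools.combinations(taxa, 2):
        pa, pb = path_to_root(a), path_to_root(b)
        shared = [n for n in pa if n in pb]
        d_lca = min(pa[n] + pb[n] for n in shared)
        dist[(a, b)] = d_lca
    return taxa, dist


def patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(sorted(tree.taxon_namespace, key=lambda t: t.label), 2):
        out[(t1.label, t2.label)] = pdm.patristic_distance(t1, t2)
    return out


class TestNeighborJoining:
    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 7, 8])
    def test_exact_on_additive_matrices(self, n_taxa):
        """NJ reproduces every pairwise path distance of the generating
        tree to 1e-9 (hence topology and branch lengths)."""
        rng = np.random.default_rng(100 + n_taxa)
        for rep in range(10):
            taxa, dist = random_additive_tree(rng, n_taxa)
            newick = neighbor_joining(dist, taxa)
            got = patristic(newick)
            for (a, b), d in dist.items():
                key = (a, b) if (a, b) in got else (b, a)
                assert got[key] == pytest.approx(d, abs=1e-9)

    def test_three_taxa_closed_form(self):
        dist = {("a", "b"): 0.4, ("a", "c"): 0.6, ("b", "c"): 0.8}
        newick = neighbor_joining(dist, ["a", "b", "c"])
        got = patristic(newick)
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        assert got[("a", "b")] == pytest.approx(0.4)
        assert got[("a", "c")] == pytest.approx(0.6)
        assert got[("b", "c")] == pytest.approx(0.8)

    def test_star_tree_for_tiny_family(self):
        fam = Family("a", ("a", "b"), {"t": 2})
        tree = build_tree(fam, [pep("AAAA", "a"), pep("AAAA", "b")])
        assert tree.is_star

    def test_negative_lengths_clamped(self, rng):
        for rep in range(20):
            taxa = [f"t{i}" for i in range(5)]
            dist = {
                (a, b): float(rng.uniform(0.01, 1.0))
                for a, b in itertools.combinations(taxa, 2)
            }
            newick = neighbor_joining(dist, taxa)
            tree = dendropy.Tree.get(data=newick, schema="newick")
            for e in tree.edges():
                if e.length is not None:
                    assert e.length >= 0


def graph_bipartition_oracle(newick, species_of, f_min=3):
    """Independent route: cut every edge of the tree graph with networkx and
    enumerate the leaf sets of the two components."""
    import networkx as nx

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    g = nx.Graph()
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node))
    leaf_of = {id(lf): lf.taxon.label for lf in tree.leaf_node_iter()}
    all_leaves = frozenset(leaf_of.values())
    sides = {all_leaves}
    for u, v in list(g.edges()):
        g.remove_edge(u, v)
        for comp in nx.connected_components(g):
            leaves = frozenset(leaf_of[x] for x in comp if x in leaf_of)
            if leaves:
                sides.add(leaves)
        g.add_edge(u, v)
    largest = {sp: 1 for sp in set(species_of.values())}
    covered = set()
    for side in sides:
        sp = {species_of[x] for x in side}
        if len(sp) == 1:
            (s,) = sp
            largest[s] = max(largest[s], len(side))
            if len(side) >= f_min:
                covered |= side
    founders = tuple(sorted(all_leaves - covered))
    present = {species_of[lf] for lf in all_leaves}
    return {s: largest[s] for s in present}, founders


class TestCladeStats:
    def test_balanced_two_species(self):
        from ampatlas.families import FamilyTree

        tree = FamilyTree("f", "((a1:1,a2:1):1,(b1:1,b2:1):1);")
        st = clade_stats(tree, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}, f_min=2)
        assert st.largest_clade == {"A": 2, "B": 2}
        assert st.founder_ids == ()

    def test_star_tree_single_species(self):
        from ampatlas.families import FamilyTree

        tree = FamilyTree("f", "(a1:1,a2:1,a3:1,a4:1);")
        st = clade_stats(tree, {f"a{i}": "A" for i in range(1, 5)})
        assert st.largest_clade == {"A": 4}

    def test_unknown_species_rejected(self):
        from ampatlas.families import FamilyTree

        tree = FamilyTree("f", "(a:1,b:1,c:1);")
        with pytest.raises(FamilyError):
            clade_stats(tree, {"a": "A", "b": "B"})

    def test_matches_bipartition_oracle_on_random_trees(self):
        """Exhaustive-enumeration equality on random 8-leaf trees."""
        from ampatlas.families import FamilyTree

        rng = np.random.default_rng(77)
        for rep in range(15):
            taxa, dist = random_additive_tree(rng, 8)
            newick = neighbor_joining(dist, taxa)
            species_of = {t: ("A" if rng.random() < 0.5 else "B") for t in taxa}
            st = clade_stats(FamilyTree("f", newick), species_of)
            want_largest, want_founders = graph_bipartition_oracle(
                newick, species_of
            )
            assert st.largest_clade == want_largest
            assert st.founder_ids == want_founders


class TestSpeciesClades:
    def test_two_species_history_forms_species_clades(self, rng):
        """Paralogues born after the species split group by species."""
        spec = FamilySpec(
            "fam", "amp_bipartite", {"speciesA": 6, "speciesB": 6},
            {"speciesA": [("c", [6])], "speciesB": [("c", [6])]},
        )
        cfg = SimulationConfig(
            seed=9, families=(spec,), p_species=0.08, p_dup=0.03
        )
        hist = simulate_family_history(spec, cfg, rng)
        peps = [
            Peptide(f"{sp}_{i}", sp, s)
            for sp in cfg.species
            for i, s in enumerate(hist.copies[sp])
        ]
        fams = build_families(peps)
        assert len(fams) == 1
        tree = build_tree(fams[0], peps)
        st = clade_stats(tree, {p.id: p.species for p in peps})
        assert st.largest_clade["speciesA"] == 6
        assert st.largest_clade["speciesB"] == 6
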