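"""Paralogue families and their species-clade structure.

AMP families in Hydra are dominated by recent within-species tandem
duplications, so paralogues from one species are typically near-identical
while orthologues across species have diverged.  This module groups
peptides into families by single-linkage over pairwise global alignment
identity, builds a neighbor-joining (NJ) tree per family on p-distance, and
summarizes each tree by species-clade statistics: the largest
single-species clade per species, and "founder" leaves that sit outside
every large species-specific clade — the likely pre-expansion ancestral
lineages.

NJ is implemented here (saitou-nei Q criterion, canonical lowest-id
tie-break, negative branch lengths clamped to zero) so that tree inference
is deterministic and exact on additive distance matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .peptides import Peptide


class FamilyError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentResult:
    id_a: str
    id_b: str
    identity: float  # matches / aligned non-gap columns
    coverage: float  # aligned non-gap columns / length of shorter sequence
    score: float


@dataclass(frozen=True)
class Family:
    family_id: str
    members: tuple[str, ...]
    species_counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class FamilyTree:
    family_id: str
    newick: str
    is_star: bool = False


@dataclass(frozen=True)
class CladeStats:
    family_id: str
    largest_clade: dict[str, int]  # species -> largest pure-species clade size
    founder_ids: tuple[str, ...]

    @property
    def n_founder_lineages(self) -> int:
        return len(self.founder_ids)


# ---------------------------------------------------------------------------
# Pairwise alignment

def make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 1.0
) -> Align.PairwiseAligner:
    """Global affine aligner; a gap of length k costs open + (k-1)*extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def pairwise_align(
    a: Peptide, b: Peptide, aligner: Align.PairwiseAligner | None = None
) -> AlignmentResult:
    """Global alignment of two peptides with identity and coverage."""
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    matches = 0
    aligned_cols = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        aligned_cols += ea - sa
        for i, j in zip(range(sa, ea), range(sb, eb)):
            if a.sequence[i] == b.sequence[j]:
                matches += 1
    shorter = min(len(a), len(b))
    return AlignmentResult(
        id_a=a.id,
        id_b=b.id,
        identity=matches / aligned_cols if aligned_cols else 0.0,
        coverage=aligned_cols / shorter,
        score=float(aln.score),
    )


def all_pairs_align(
    peptides: Sequence[Peptide], aligner: Align.PairwiseAligner | None = None
) -> dict[tuple[str, str], AlignmentResult]:
    """Alignment results for all unordered pairs, keyed by sorted id pair."""
    if aligner is None:
        aligner = make_aligner()
    out = {}
    for a, b in itertools.combinations(peptides, 2):
        key = tuple(sorted((a.id, b.id)))
        out[key] = pairwise_align(a, b, aligner)
    return out


# ---------------------------------------------------------------------------
# Family construction (single linkage over the identity graph)

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_families(
    peptides: Sequence[Peptide],
    id_min: float = 0.5,
    cov_min: float = 0.6,
    alignments: Mapping[tuple[str, str], AlignmentResult] | None = None,
) -> list[Family]:
    """Partition peptides into families (connected components of the graph
    with an edge wherever identity >= id_min and coverage >= cov_min).

    Each family is named after its lexicographically smallest member.
    """
    if not (0 <= id_min <= 1 and 0 <= cov_min <= 1):
        raise FamilyError("thresholds must lie in [0, 1]")
    if alignments is None:
        alignments = all_pairs_align(peptides)
    species_of = {p.id: p.species for p in peptides}
    uf = _UnionFind([p.id for p in peptides])
    for (ia, ib), res in alignments.items():
        if res.identity >= id_min and res.coverage >= cov_min:
            uf.union(ia, ib)
    groups: dict[str, list[str]] = {}
    for p in peptides:
        groups.setdefault(uf.find(p.id), []).append(p.id)
    families = []
    for members in groups.values():
        members = tuple(sorted(members))
        counts: dict[str, int] = {}
        for m in members:
            counts[species_of[m]] = counts.get(species_of[m], 0) + 1
        families.append(Family(family_id=members[0], members=members, species_counts=counts))
    return sorted(families, key=lambda f: f.family_id)


def families_table(families: Sequence[Family], species_of: Mapping[str, str]) -> pd.DataFrame:
    rows = [
        {"family_id": f.family_id, "member": m, "species": species_of[m]}
        for f in families
        for m in f.members
    ]
    return pd.DataFrame(rows, columns=["family_id", "member", "species"])


# ---------------------------------------------------------------------------
# Neighbor joining

def p_distance_matrix(
    members: Sequence[str],
    alignments: Mapping[tuple[str, str], AlignmentResult],
) -> dict[tuple[str, str], float]:
    """p-distance (1 - identity) for every unordered member pair."""
    dist = {}
    for a, b in itertools.combinations(sorted(members), 2):
        res = alignments[(a, b)]
        dist[(a, b)] = 1.0 - res.identity
    return dist


class _Node:
    __slots__ = ("label", "children", "rep")

    def __init__(self, label: str | None, children=None, rep: str = ""):
        self.label = label
        self.children = children or []  # list of (child, branch_length)
        self.rep = rep  # smallest leaf id below; canonical tie-break key

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(dist: Mapping[tuple[str, str], float], labels: Sequence[str]) -> str:
    """Canonical NJ tree in newick form (unrooted, trifurcating root).

    Ties in the Q criterion are broken toward the pair with the smallest
    sorted representative-leaf ids; negative branch lengths are clamped to 0.
    Exact on additive matrices.
    """
    labels = sorted(labels)
    if len(labels) < 2:
        raise FamilyError("neighbor joining needs >= 2 taxa")
    nodes = {lab: _Node(lab, rep=lab) for lab in labels}
    D = {}
    for (a, b), d in dist.items():
        key = (min(a, b), max(a, b))
        D[key] = float(d)

    def d(u: str, v: str) -> float:
        return D[(min(u, v), max(u, v))]

    active = list(labels)
    while len(active) > 3:
        n = len(active)
        r = {u: sum(d(u, v) for v in active if v != u) for u in active}
        best = None
        for u, v in itertools.combinations(sorted(active), 2):
            q = (n - 2) * d(u, v) - r[u] - r[v]
            if best is None or q < best[0] - 1e-12:
                best = (q, u, v)
        _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        rep = min(nodes[a].rep, nodes[b].rep)
        new = _Node(None, [(nodes[a], la), (nodes[b], lb)], rep=rep)
        key = f"@{rep}"
        nodes[key] = new
        for u in active:
            if u not in (a, b):
                D[(min(key, u), max(key, u))] = 0.5 * (d(a, u) + d(b, u) - d(a, b))
        active = [u for u in active if u not in (a, b)] + [key]
        active.sort()
    if len(active) == 3:
        a, b, c = sorted(active)
        la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
        lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
        lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
        root = _Node(
            None,
            [
                (nodes[a], max(la, 0.0)),
                (nodes[b], max(lb, 0.0)),
                (nodes[c], max(lc, 0.0)),
            ],
            rep=min(nodes[x].rep for x in (a, b, c)),
        )
    else:
        a, b = sorted(active)
        root = _Node(None, [(nodes[a], d(a, b)), (nodes[b], 0.0)], rep=nodes[a].rep)
    return root.newick() + ";"


def build_tree(
    family: Family,
    peptides: Sequence[Peptide],
    alignments: Mapping[tuple[str, str], AlignmentResult] | None = None,
) -> FamilyTree:
    """NJ tree on p-distances for one family; star tree for size < 3."""
    members = list(family.members)
    if len(members) < 3:
        inner = ",".join(f"{m}:0" for m in members)
        return FamilyTree(family.family_id, f"({inner});", is_star=True)
    if alignments is None:
        pool = [p for p in peptides if p.id in set(members)]
        alignments = all_pairs_align(pool)
    dist = p_distance_matrix(members, alignments)
    return FamilyTree(family.family_id, neighbor_joining(dist, members))


# ---------------------------------------------------------------------------
# Species-clade statistics

def _edge_sides(newick: str) -> tuple[list[frozenset[str]], frozenset[str]]:
    """All bipartition sides of an unrooted tree (both orientations per edge)."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    sides: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 0 < len(below) < len(all_leaves):
            sides.add(below)
            sides.add(all_leaves - below)
    # the whole tree counts as a clade (a family entirely from one species
    # is that species' largest clade)
    sides.add(all_leaves)
    if len(all_leaves) == 2:
        for leaf in all_leaves:
            sides.add(frozenset([leaf]))
    return sorted(sides, key=lambda s: (len(s), sorted(s))), all_leaves


def clade_stats(
    tree: FamilyTree,
    species_of: Mapping[str, str],
    f_min: int = 3,
) -> CladeStats:
    """Largest pure-species clade per species, and founder leaves.

    A clade of an unrooted tree is one side of an edge bipartition.  A leaf
    is a founder when it belongs to no single-species clade of size >=
    ``f_min`` — it diverged before its species' duplication burst.
    """
    sides, leaves = _edge_sides(tree.newick)
    missing = [lf for lf in leaves if lf not in species_of]
    if missing:
        raise FamilyError(f"leaves without species assignment: {sorted(missing)}")
    largest: dict[str, int] = {species_of[lf]: 1 for lf in leaves}
    in_big_clade: set[str] = set()
    for side in sides:
        sp = {species_of[lf] for lf in side}
        if len(sp) == 1:
            (species,) = sp
            largest[species] = max(largest[species], len(side))
            if len(side) >= f_min:
                in_big_clade |= side
    founders = tuple(sorted(lf for lf in leaves if lf not in in_big_clade))
    return CladeStats(tree.family_id, largest, founders)


def clade_stats_table(
    stats: Sequence[CladeStats],
    families: Sequence[Family],
    species_of: Mapping[str, str],
) -> pd.DataFrame:
    by_id = {f.family_id: f for f in families}
    rows = []
    for st in stats:
        fam = by_id[st.family_id]
        for species, largest in sorted(st.largest_clade.items()):
            rows.append(
                {
                    "family_id": st.family_id,
                    "species": species,
                    "largest_clade": largest,
                    "n_members": fam.species_counts.get(species, 0),
                    "n_founders": sum(
                        1 for f in st.founder_ids if species_of[f] == species
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["family_id", "species", "largest_clade", "n_members", "n_founders"],
    )
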