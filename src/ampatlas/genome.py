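"""Genomic organization of AMP families: tandem clusters, taxonomically
restricted gene (TRG) arrays, and microsynteny-based loss calls.

Hydra AMP paralogues are born by repeated local duplication, so most family
members sit in dense same-chromosome runs.  ``detect_clusters`` finds the
maximal runs of family genes whose inter-gene gaps stay below a bp
threshold; two presets reflect two granularities of the same locus (a 50 kb
gap splits a dense array into sub-clusters that a 200 kb gap merges).
``scan_trg_clusters`` searches the whole annotation for arrays of short,
mutually similar genes — candidate uncharacterized AMP families.
``synteny_presence`` tests whether a family that is missing from a target
species was genuinely lost: flanking-gene anchors are mapped through an
orthologue table, and if they frame a contiguous target window containing
no family member, the family is called lost at that locus.

Coordinates are 1-based inclusive (GFF3 convention) throughout; BED input
is converted at the boundary by the omics module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pandas as pd

from .families import make_aligner, pairwise_align
from .peptides import Peptide


class GenomeError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    species: str = "unknown"
    family_id: str | None = None
    cds_len: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise GenomeError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class GenomicCluster:
    cluster_id: str
    scaffold: str
    members: tuple[str, ...]  # gene ids ordered by start
    span: int  # bp from first start to last end
    family_id: str | None = None
    mean_identity: float | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class SyntenyVerdict:
    family_id: str
    query_species: str
    target_species: str
    status: str  # retained | lost | unclassified
    anchor_count: int
    target_window: tuple[str, int, int] | None = None


# ---------------------------------------------------------------------------
# GFF3 input

def read_gff(path: str | Path, species: str = "unknown") -> list[GeneModel]:
    """GeneModels from the ``gene`` features of a GFF3 file.

    CDS children (via mRNA or direct) contribute summed ``cds_len``.
    Input order is irrelevant; genes come back sorted by (scaffold, start).
    """
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            id_spec={"gene": "ID", "mRNA": "ID"},
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes = []
    for feat in db.features_of_type("gene"):
        if "ID" not in feat.attributes:
            raise GenomeError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        cds_len = 0
        for cds in db.children(feat, featuretype="CDS"):
            cds_len += cds.end - cds.start + 1
        genes.append(
            GeneModel(
                gene_id=feat.attributes["ID"][0],
                scaffold=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                species=species,
                cds_len=cds_len,
            )
        )
    return sorted(genes, key=lambda g: (g.scaffold, g.start, g.gene_id))


def assign_families(
    genes: Sequence[GeneModel], family_of: Mapping[str, str]
) -> list[GeneModel]:
    """Return copies of ``genes`` carrying their family assignment."""
    return [
        GeneModel(
            g.gene_id, g.scaffold, g.start, g.end, g.strand, g.species,
            family_of.get(g.gene_id), g.cds_len,
        )
        for g in genes
    ]


# ---------------------------------------------------------------------------
# Tandem clusters

def detect_clusters(
    genes: Sequence[GeneModel], max_gap: int = 100_000
) -> tuple[list[GenomicCluster], list[GeneModel]]:
    """Maximal same-scaffold runs of one family's genes with inter-gene
    gaps (next.start - prev.end) <= ``max_gap``.

    Runs of length >= 2 become clusters; the rest are returned unclustered.
    Intervening unrelated genes never break a run — only the bp gap does.
    """
    fams = {g.family_id for g in genes}
    if len(fams) > 1:
        raise GenomeError(f"detect_clusters expects one family, got {sorted(map(str, fams))}")
    clusters: list[GenomicCluster] = []
    unclustered: list[GeneModel] = []
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for scaffold in sorted(by_scaffold):
        run: list[GeneModel] = []
        ordered = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        for g in ordered:
            if run and g.start - run[-1].end > max_gap:
                _flush_run(run, clusters, unclustered)
                run = []
            run.append(g)
        _flush_run(run, clusters, unclustered)
    return clusters, unclustered


def _flush_run(run, clusters, unclustered) -> None:
    if len(run) >= 2:
        clusters.append(
            GenomicCluster(
                cluster_id=f"{run[0].scaffold}:{run[0].start}",
                scaffold=run[0].scaffold,
                members=tuple(g.gene_id for g in run),
                span=run[-1].end - run[0].start + 1,
                family_id=run[0].family_id,
            )
        )
    elif run:
        unclustered.append(run[0])


def cluster_summary(
    family_id: str,
    clusters: Sequence[GenomicCluster],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per-scaffold member/cluster counts for one family.

    Columns: scaffold, n_members, n_clusters, largest_cluster.  Totals over
    scaffolds equal the family size.
    """
    fam_genes = [g for g in genes if g.family_id == family_id]
    rows = []
    scaffolds = sorted({g.scaffold for g in fam_genes})
    for scaffold in scaffolds:
        members = [g for g in fam_genes if g.scaffold == scaffold]
        cl = [c for c in clusters if c.scaffold == scaffold and c.family_id == family_id]
        rows.append(
            {
                "scaffold": scaffold,
                "n_members": len(members),
                "n_clusters": len(cl),
                "largest_cluster": max((len(c) for c in cl), default=0),
            }
        )
    return pd.DataFrame(
        rows, columns=["scaffold", "n_members", "n_clusters", "largest_cluster"]
    )


def clusters_table(
    clusters: Sequence[GenomicCluster], unclustered: Sequence[GeneModel] = ()
) -> pd.DataFrame:
    rows = [
        {
            "cluster_id": c.cluster_id,
            "family_id": c.family_id,
            "scaffold": c.scaffold,
            "n_members": len(c),
            "members": ",".join(c.members),
            "span": c.span,
        }
        for c in clusters
    ]
    for g in unclustered:
        rows.append(
            {
                "cluster_id": "unclustered",
                "family_id": g.family_id,
                "scaffold": g.scaffold,
                "n_members": 1,
                "members": g.gene_id,
                "span": g.end - g.start + 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "family_id", "scaffold", "n_members", "members", "span"],
    )


# ---------------------------------------------------------------------------
# TRG-array scan

def scan_trg_clusters(
    genes: Sequence[GeneModel],
    peptides: Sequence[Peptide],
    min_run: int = 10,
    max_cds: int = 1500,
    id_min: float = 0.3,
) -> list[GenomicCluster]:
    """Arrays of consecutive short, mutually similar genes.

    A qualifying run is >= ``min_run`` consecutive genes on one scaffold
    (in start order, nothing in between) whose CDS lengths are all <=
    ``max_cds`` and whose mean pairwise peptide identity is >= ``id_min``.
    Maximal short-gene runs are found first, then filtered by identity.
    """
    pep_of = {p.source_gene or p.id: p for p in peptides}
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    aligner = make_aligner()
    out = []
    for scaffold in sorted(by_scaffold):
        ordered = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        run: list[GeneModel] = []
        for g in ordered + [None]:
            if g is not None and g.cds_len <= max_cds:
                run.append(g)
                continue
            if len(run) >= min_run:
                ids = [r.gene_id for r in run]
                pool = [pep_of[i] for i in ids if i in pep_of]
                mean_id = _mean_identity(pool, aligner)
                if mean_id is not None and mean_id >= id_min:
                    out.append(
                        GenomicCluster(
                            cluster_id=f"TRG:{scaffold}:{run[0].start}",
                            scaffold=scaffold,
                            members=tuple(ids),
                            span=run[-1].end - run[0].start + 1,
                            family_id="TRG",
                            mean_identity=mean_id,
                        )
                    )
            run = []
    return out


def _mean_identity(pool: Sequence[Peptide], aligner) -> float | None:
    if len(pool) < 2:
        return None
    vals = [
        pairwise_align(a, b, aligner).identity
        for a, b in itertools.combinations(pool, 2)
    ]
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# Microsynteny loss calls

def synteny_presence(
    family_id: str,
    query_species: str,
    target_species: str,
    orthologs: Mapping[str, str],
    genes: Sequence[GeneModel],
    k: int = 5,
    m_min: int = 3,
    margin: int = 50_000,
) -> SyntenyVerdict:
    """Presence/loss of a family at its syntenic locus in a target species.

    The ``k`` non-family genes flanking the query family locus on each side
    are mapped through the orthologue table; if >= ``m_min`` anchors land on
    one target scaffold, the anchored interval (+- ``margin``) is searched
    for any target-species family member.  ``retained`` if one is found,
    ``lost`` if none, ``unclassified`` when anchors are too few or
    discordant.
    """
    query_genes = [
        g for g in genes if g.species == query_species and g.family_id == family_id
    ]
    if not query_genes:
        raise GenomeError(
            f"family {family_id!r} has no genes in query species {query_species!r}"
        )
    # locus = scaffold holding most family members
    counts: dict[str, int] = {}
    for g in query_genes:
        counts[g.scaffold] = counts.get(g.scaffold, 0) + 1
    locus_scaffold = max(sorted(counts), key=lambda s: counts[s])
    locus = sorted(
        (g for g in query_genes if g.scaffold == locus_scaffold),
        key=lambda g: g.start,
    )
    lo, hi = locus[0].start, locus[-1].end
    neighbours = sorted(
        (
            g
            for g in genes
            if g.species == query_species
            and g.scaffold == locus_scaffold
            and g.family_id != family_id
        ),
        key=lambda g: g.start,
    )
    left = [g for g in neighbours if g.end < lo][-k:]
    right = [g for g in neighbours if g.start > hi][:k]
    anchors = [orthologs[g.gene_id] for g in left + right if g.gene_id in orthologs]
    target_genes = {g.gene_id: g for g in genes if g.species == target_species}
    mapped = [target_genes[a] for a in anchors if a in target_genes]
    if not mapped:
        return SyntenyVerdict(family_id, query_species, target_species, "unclassified", 0)
    scaffold_counts: dict[str, int] = {}
    for g in mapped:
        scaffold_counts[g.scaffold] = scaffold_counts.get(g.scaffold, 0) + 1
    best_scaffold = max(sorted(scaffold_counts), key=lambda s: scaffold_counts[s])
    concordant = [g for g in mapped if g.scaffold == best_scaffold]
    if len(concordant) < m_min:
        return SyntenyVerdict(
            family_id, query_species, target_species, "unclassified", len(concordant)
        )
    wlo = max(1, min(g.start for g in concordant) - margin)
    whi = max(g.end for g in concordant) + margin
    window = (best_scaffold, wlo, whi)
    present = any(
        g.family_id == family_id
        and g.scaffold == best_scaffold
        and g.start <= whi
        and g.end >= wlo
        for g in genes
        if g.species == target_species
    )
    status = "retained" if present else "lost"
    return SyntenyVerdict(
        family_id, query_species, target_species, status, len(concordant), window
    )


def synteny_table(verdicts: Sequence[SyntenyVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family_id": v.family_id,
                "query_species": v.query_species,
                "target_species": v.target_species,
                "status": v.status,
                "anchors": v.anchor_count,
                "target_window": (
                    f"{v.target_window[0]}:{v.target_window[1]}-{v.target_window[2]}"
                    if v.target_window
                    else ""
                ),
            }
            for v in verdicts
        ],
        columns=[
            "family_id", "query_species", "target_species",
            "status", "anchors", "target_window",
        ],
    )
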