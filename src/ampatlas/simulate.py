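"""Ground-truthed synthetic data with the statistical structure of Hydra
AMP repertoires.

The generator emulates the processes the analysis stages assume:

* peptide templates with planted structural labels — bipartite-charge AMP
  precursors with a signal peptide and a cysteine scaffold, six-Cys
  Trp-rich (CWR-style) peptides with non-defensin spacing, canonical
  beta-defensin-spaced peptides, and composition-matched decoys;
* gene families born from a single founder by repeated within-species
  tandem duplication, with charge-class-preserving substitutions so that
  every copy keeps its planted structural label;
* genomes in which duplicated copies sit in dense same-chromosome runs
  (a 14 + 9 two-cluster layout plus 5 scattered copies by default,
  mirroring the largest known Hydra AMP family), flanked by anchor genes
  with one-to-one cross-species orthologues for microsynteny tests, and a
  planted family loss in the second species that removes the gene but
  keeps its flanks;
* a cell-annotated count matrix in which most family paralogues are
  transcriptionally silent (all-zero), and an ATAC peak set that places an
  open-chromatin peak inside the 2.5 kb upstream window of every family
  gene — the silent-but-primed configuration.

A single integer seed drives every random draw; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel
from .peptides import Peptide, write_fasta

AA = "ACDEFGHIKLMNPQRSTVWY"

# background residue frequencies for decoys (uniprot-like, slightly de-enriched
# in Cys and Trp so stray cysteine scaffolds are vanishingly rare)
BACKGROUND = {
    "A": 0.09, "C": 0.01, "D": 0.06, "E": 0.065, "F": 0.04, "G": 0.07,
    "H": 0.02, "I": 0.055, "K": 0.045, "L": 0.095, "M": 0.02, "N": 0.04,
    "P": 0.05, "Q": 0.04, "R": 0.04, "S": 0.075, "T": 0.055, "V": 0.07,
    "W": 0.01, "Y": 0.03,
}

BASIC = "KR"
ACIDIC = "DE"
# neutral replacement pool excludes Cys (scaffold) and Trp (Trp-fraction label)
NEUTRAL_POOL = "AGSTNQLIVPFYHM"


@dataclass(frozen=True)
class FamilySpec:
    """One simulated gene family.

    ``layout`` maps species to ``(scaffold, [run sizes])`` groups; run sizes
    of 1 are scattered singletons.  The sizes must sum to ``copies`` for
    that species.
    """

    name: str
    template: str  # amp_bipartite | hycwr | defensin | decoy
    copies: dict[str, int]
    layout: dict[str, list[tuple[str, list[int]]]]
    anchored: bool = False  # emit flanking anchor genes with 1:1 orthologues
    mature_len: int = 36


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    species: tuple[str, ...] = ("speciesA", "speciesB")
    families: tuple[FamilySpec, ...] = ()
    p_species: float = 0.08   # per-site substitution prob on each species branch
    p_dup: float = 0.02       # per-site substitution prob per copy per duplication
    cluster_gap_bp: tuple[int, int] = (2_000, 20_000)
    intercluster_gap: int = 120_000  # splits at a 50 kb preset, merges at 200 kb
    scattered_gap: int = 300_000
    fraction_silent: float = 24 / 28
    decoy_gene_count: int = 40
    planted_losses: tuple[tuple[str, str], ...] = ()
    n_anchors: int = 5
    n_cells_per_type: int = 40
    nb_dispersion: float = 0.5
    expr_mean: float = 5.0
    trg_array_size: int = 30

    def __post_init__(self) -> None:
        for p in (self.p_species, self.p_dup, self.fraction_silent):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")


CELL_TYPES = (
    "ecto_epithelial", "endo_epithelial", "gland", "neuron_ec1",
    "neuron_ec2", "neuron_n5", "interstitial", "germline",
)
BODY_REGIONS = ("head", "body", "foot", "tentacles")
#: neuronal population confined to the tentacles (hosts the planted
#: region-restricted gene)
TENTACLE_TYPE = "neuron_ec2"


def default_config(seed: int = 0) -> SimulationConfig:
    """The reference two-species scenario.

    Species A carries a 28-copy bipartite-AMP family laid out as two
    chromosome-10 clusters of 14 and 9 plus 5 scattered copies, a
    single-copy six-Cys family that species B has lost (flanks retained),
    a 30-gene array of short near-identical taxon-restricted genes, and
    background decoys.  24 of the 28 family paralogues are silent; every
    family gene carries an upstream ATAC peak.
    """
    periculin = FamilySpec(
        name="periculin_like",
        template="amp_bipartite",
        copies={"speciesA": 28, "speciesB": 8},
        layout={
            "speciesA": [
                ("chr10", [14, 9]),
                ("chr2", [1, 1]),
                ("chr3", [1, 1]),
                ("chr7", [1]),
            ],
            "speciesB": [("chrB10", [8])],
        },
        anchored=True,
    )
    hydramacin = FamilySpec(
        name="hydramacin_like",
        template="defensin",
        copies={"speciesA": 1, "speciesB": 1},
        layout={"speciesA": [("chr12", [1])], "speciesB": [("chrB12", [1])]},
        anchored=True,
    )
    hycwr = FamilySpec(
        name="hycwr_like_fam",
        template="hycwr",
        copies={"speciesA": 5, "speciesB": 1},
        layout={"speciesA": [("chr8", [5])], "speciesB": [("chrB8", [1])]},
    )
    return SimulationConfig(
        seed=seed,
        families=(periculin, hydramacin, hycwr),
        planted_losses=(("hydramacin_like", "speciesB"),),
    )


# ---------------------------------------------------------------------------
# Peptide templates

def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(rng.choice(list(pool), size=n))


def _signal_prefix(rng: np.random.Generator) -> str:
    """15-residue signal peptide satisfying the detection heuristic:
    non-negative N-region charge, a hydrophobic core, and an A-x-A
    signal-peptidase site at position 15."""
    return "MKT" + _draw(rng, "LIVF", 9) + "ASA"


def _amphipathic_cationic(rng: np.random.Generator, n: int) -> str:
    """Idealized cationic amphipathic helix: hydrophobics on the face at
    helical angle cos > 0, basics on the opposite face."""
    out = []
    for j in range(n):
        angle = np.radians(100.0 * j)
        if np.cos(angle) > 0:
            out.append(rng.choice(list("LIVFA")))
        else:
            out.append(rng.choice(list("KKKRG")))
    return "".join(out)


def make_peptide(
    template: str,
    rng: np.random.Generator,
    name: str = "pep",
    species: str = "synthetic",
    mature_len: int = 36,
) -> Peptide:
    """One peptide with a planted structural label.

    ``amp_bipartite``: signal peptide + short anionic block + long cationic
    amphipathic block with an 8-Cys scaffold and a dibasic processing site.
    ``hycwr``: six Cys with non-defensin spacing, >= 8% Trp, cationic
    C-terminus, no dibasic motifs.  ``defensin``: six Cys with canonical
    beta-defensin gap spacing.  ``decoy``: background composition.
    """
    if template == "amp_bipartite":
        anionic = _draw(rng, "DDEESN", 6)
        cationic = _amphipathic_cationic(rng, max(mature_len - 8, 24))
        # plant an 8-Cys scaffold across the mature region and a dibasic site;
        # cysteines displace only non-basic residues so the cationic C-block
        # keeps its charge
        mature = list(anionic + "KR" + cationic)
        slots = [i for i in range(2, len(mature) - 1) if mature[i] not in "KR"]
        for slot_idx in np.linspace(0, len(slots) - 1, 8).astype(int):
            mature[slots[slot_idx]] = "C"
        seq = _signal_prefix(rng) + "".join(mature)
    elif template == "hycwr":
        # gaps (7, 7, 5, 2, 3) fail both defensin grammars
        gaps = (7, 7, 5, 2, 3)
        lead = _no_dibasic(rng, 6)
        parts = ["C"]
        for g in gaps:
            filler = list(_no_dibasic(rng, g))
            # guarantee the Trp budget inside the scaffold
            if g >= 2:
                filler[g // 2] = "W"
            parts.append("".join(filler) + "C")
        tail = "".join(
            rng.choice(["KW", "KG", "KS", "WG"]) for _ in range(5)
        )
        seq = lead + "".join(parts) + tail
        seq = seq.replace("KK", "KG").replace("KR", "KG").replace("RR", "RG").replace("RK", "RG")
    elif template == "defensin":
        gaps = (5, 3, 10, 5, 0)
        parts = [_draw(rng, "GSTANQILV", 8), "C"]
        for g in gaps:
            parts.append(_draw(rng, "GSTANQILVKE", g) + "C")
        parts.append(_draw(rng, "GSTANQ", 4))
        seq = "".join(parts)
    elif template == "decoy":
        n = int(rng.integers(60, 140))
        letters = list(BACKGROUND)
        probs = np.array(list(BACKGROUND.values()))
        probs = probs / probs.sum()
        seq = "".join(rng.choice(letters, size=n, p=probs))
    else:
        raise ValueError(f"unknown template {template!r}")
    return Peptide(id=name, species=species, sequence=seq)


def _no_dibasic(rng: np.random.Generator, n: int) -> str:
    """Random stretch free of K/R so no dibasic motif can form."""
    return _draw(rng, "AGSTNQLIVPFYHM", n)


def protected_positions(template: str, sequence: str) -> frozenset[int]:
    """0-based positions that substitutions must not touch, so the planted
    structural label survives arbitrary divergence."""
    protected = {i for i, aa in enumerate(sequence) if aa in "CW"}
    if template == "amp_bipartite":
        protected |= set(range(15))  # the signal peptide
        protected |= {i for i in range(len(sequence) - 1)
                      if sequence[i : i + 2] in ("KR", "RR", "KK", "RK")}
    return frozenset(protected)


def mutate(
    sequence: str,
    p: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """i.i.d. per-site substitutions preserving the residue's charge class.

    Basic residues swap within {K, R}, acidic within {D, E}; neutral
    residues draw from a Cys/Trp-free neutral pool.  No indels.
    """
    seq = list(sequence)
    hits = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hits:
        if i in protected:
            continue
        aa = seq[i]
        if aa in BASIC:
            pool = BASIC.replace(aa, "")
        elif aa in ACIDIC:
            pool = ACIDIC.replace(aa, "")
        elif aa in ("C", "W"):
            continue
        else:
            pool = NEUTRAL_POOL.replace(aa, "")
        seq[i] = str(rng.choice(list(pool)))
    return "".join(seq)


# ---------------------------------------------------------------------------
# Family history

@dataclass
class FamilyHistory:
    family: str
    template: str
    copies: dict[str, list[str]]  # species -> sequences in tandem order
    events: list[dict]


def simulate_family_history(
    spec: FamilySpec,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> FamilyHistory:
    """Evolve one founder along a star species tree, then duplicate in place.

    Each species inherits the founder with ``p_species`` substitutions;
    each within-species tandem duplication copies a random existing gene
    next to itself and lets both copies accrue ``p_dup`` substitutions.
    """
    root = make_peptide(spec.template, rng, mature_len=spec.mature_len)
    protected = protected_positions(spec.template, root.sequence)
    events: list[dict] = []
    copies: dict[str, list[str]] = {}
    for species in cfg.species:
        n = spec.copies.get(species, 0)
        if n == 0:
            copies[species] = []
            continue
        base = mutate(root.sequence, cfg.p_species, rng, protected)
        seqs = [base]
        for _ in range(n - 1):
            i = int(rng.integers(len(seqs)))
            child = mutate(seqs[i], cfg.p_dup, rng, protected)
            seqs[i] = mutate(seqs[i], cfg.p_dup, rng, protected)
            seqs.insert(i + 1, child)
            events.append({"type": "duplication", "species": species,
                           "family": spec.name, "source_index": i})
        copies[species] = seqs
    for fam, species in cfg.planted_losses:
        if fam == spec.name:
            events.append({"type": "loss", "species": species, "family": fam})
    return FamilyHistory(spec.name, spec.template, copies, events)


# ---------------------------------------------------------------------------
# Genome assembly

@dataclass
class Simulation:
    config: SimulationConfig
    peptides: list[Peptide]
    genes: list[GeneModel]  # family_id carries the true family
    orthologs: dict[str, str]
    histories: list[FamilyHistory]
    counts: np.ndarray  # cells x genes, raw
    matrix_genes: list[str]
    cell_meta: pd.DataFrame  # cell_id, cell_type, body_region
    peaks: list[tuple[str, int, int]]  # 0-based half-open
    truth: dict


def _place_gene(
    genes: list[GeneModel],
    peptides: list[Peptide],
    gene_id: str,
    scaffold: str,
    start: int,
    sequence: str,
    species: str,
    family: str | None,
    strand: str,
) -> int:
    """Append a gene + its peptide; return the gene end coordinate."""
    cds = 3 * (len(sequence) + 1)
    end = start + cds - 1
    genes.append(
        GeneModel(gene_id, scaffold, start, end, strand, species, family, cds)
    )
    peptides.append(
        Peptide(id=gene_id, species=species, sequence=sequence, source_gene=gene_id)
    )
    return end


def simulate(cfg: SimulationConfig | None = None) -> Simulation:
    """Run the full generator: families, genomes, omics, truth table."""
    if cfg is None:
        cfg = default_config()
    rng = np.random.default_rng(cfg.seed)
    lost = set(cfg.planted_losses)
    genes: list[GeneModel] = []
    peptides: list[Peptide] = []
    orthologs: dict[str, str] = {}
    truth_genes: dict[str, dict] = {}
    histories = []

    cursors: dict[tuple[str, str], int] = {}  # (species, scaffold) -> next start

    def cursor(species: str, scaffold: str) -> int:
        return cursors.get((species, scaffold), 50_001)

    def advance(species: str, scaffold: str, pos: int) -> None:
        cursors[(species, scaffold)] = pos

    for spec in cfg.families:
        hist = simulate_family_history(spec, cfg, rng)
        histories.append(hist)
        for species in cfg.species:
            seqs = hist.copies.get(species, [])
            if not seqs:
                continue
            groups = spec.layout[species]
            if sum(n for _, sizes in groups for n in sizes) != len(seqs):
                raise ValueError(
                    f"{spec.name}/{species}: layout does not sum to copy number"
                )
            is_lost = (spec.name, species) in lost
            # anchors flank the main locus (the scaffold of the first group)
            main_scaffold = groups[0][0]
            if spec.anchored:
                pos = cursor(species, main_scaffold)
                for i in range(cfg.n_anchors):
                    aid = f"{species}_{spec.name}_ancL{i}"
                    anchor_pep = make_peptide("decoy", rng, aid, species)
                    end = _place_gene(genes, peptides, aid, main_scaffold, pos,
                                      anchor_pep.sequence, species, None,
                                      "+" if rng.random() < 0.5 else "-")
                    pos = end + 10_000
                    truth_genes[aid] = {"family": None, "species": species,
                                        "scaffold": main_scaffold, "role": "anchor"}
                advance(species, main_scaffold, pos + 20_000)
            idx = 0
            last_run_size: dict[str, int] = {}
            for scaffold, sizes in groups:
                for size in sizes:
                    pos = cursor(species, scaffold)
                    if scaffold in last_run_size:
                        # runs split at the 50 kb preset but merge at 200 kb;
                        # scattered singletons never merge
                        pos += (
                            cfg.intercluster_gap
                            if last_run_size[scaffold] >= 2 and size >= 2
                            else cfg.scattered_gap
                        )
                    for _ in range(size):
                        gid = f"{species}_{spec.name}_{idx:03d}"
                        seq = seqs[idx]
                        if not is_lost:
                            strand = "+" if rng.random() < 0.5 else "-"
                            end = _place_gene(genes, peptides, gid, scaffold, pos,
                                              seq, species, spec.name, strand)
                            truth_genes[gid] = {
                                "family": spec.name, "species": species,
                                "scaffold": scaffold, "role": "member",
                            }
                            pos = end + int(rng.integers(*cfg.cluster_gap_bp))
                        else:
                            pos += 3 * (len(seq) + 1) + int(rng.integers(*cfg.cluster_gap_bp))
                        idx += 1
                    advance(species, scaffold, pos)
                    last_run_size[scaffold] = size
            if spec.anchored:
                pos = cursor(species, main_scaffold) + 30_000
                for i in range(cfg.n_anchors):
                    aid = f"{species}_{spec.name}_ancR{i}"
                    anchor_pep = make_peptide("decoy", rng, aid, species)
                    end = _place_gene(genes, peptides, aid, main_scaffold, pos,
                                      anchor_pep.sequence, species, None,
                                      "+" if rng.random() < 0.5 else "-")
                    pos = end + 10_000
                    truth_genes[aid] = {"family": None, "species": species,
                                        "scaffold": main_scaffold, "role": "anchor"}
                advance(species, main_scaffold, pos)
        # cross-species anchor orthologues
        if spec.anchored:
            sp0 = cfg.species[0]
            for other in cfg.species[1:]:
                for side in ("L", "R"):
                    for i in range(cfg.n_anchors):
                        a = f"{sp0}_{spec.name}_anc{side}{i}"
                        b = f"{other}_{spec.name}_anc{side}{i}"
                        orthologs[a] = b

    # taxon-restricted-gene array: short near-identical collinear genes
    sp0 = cfg.species[0]
    if cfg.trg_array_size:
        trg_root = make_peptide("decoy", rng, mature_len=0)
        trg_seq = trg_root.sequence[:80]
        pos = 50_001
        for i in range(cfg.trg_array_size):
            gid = f"{sp0}_trg_{i:03d}"
            seq = mutate(trg_seq, 0.05, rng)
            end = _place_gene(genes, peptides, gid, "chr5", pos, seq, sp0,
                              None, "+" if rng.random() < 0.5 else "-")
            pos = end + int(rng.integers(1_000, 4_000))
            truth_genes[gid] = {"family": "trg_array", "species": sp0,
                                "scaffold": "chr5", "role": "trg"}

    # background decoys on their own scaffolds, widely spaced
    for i in range(cfg.decoy_gene_count):
        gid = f"{sp0}_decoy_{i:03d}"
        pep = make_peptide("decoy", rng, gid, sp0)
        scaffold = "chr1" if i % 2 == 0 else "chr6"
        pos = cursor(sp0, scaffold)
        end = _place_gene(genes, peptides, gid, scaffold, pos, pep.sequence,
                          sp0, None, "+" if rng.random() < 0.5 else "-")
        advance(sp0, scaffold, end + 40_000)
        truth_genes[gid] = {"family": None, "species": sp0,
                            "scaffold": scaffold, "role": "decoy"}

    counts, matrix_genes, cell_meta, peaks, omics_truth = _emit_omics_arrays(
        cfg, genes, rng
    )
    for gid, info in omics_truth.items():
        truth_genes.setdefault(gid, {}).update(info)

    truth = {
        "seed": cfg.seed,
        "genes": truth_genes,
        "losses": [
            {"family": fam, "species": sp} for fam, sp in cfg.planted_losses
        ],
        "families": {
            spec.name: {sp: spec.copies.get(sp, 0) for sp in cfg.species}
            for spec in cfg.families
        },
    }
    return Simulation(
        config=cfg,
        peptides=peptides,
        genes=genes,
        orthologs=orthologs,
        histories=histories,
        counts=counts,
        matrix_genes=matrix_genes,
        cell_meta=cell_meta,
        peaks=peaks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Omics arrays

def _emit_omics_arrays(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator,
):
    """Counts, cell metadata, and ATAC peaks for the first species.

    The main family's paralogues are split into silent (all-zero counts)
    and expressed copies; one expressed copy goes to the tentacle-confined
    neuronal population (the planted region-restricted gene), the others to
    the germline.  Housekeeping genes keep every cell's total positive.
    Every family gene receives an ATAC peak centred inside its 2.5 kb
    upstream window; decoys and housekeeping genes stay peak-free.
    """
    sp0 = cfg.species[0]
    fam_genes = [g for g in genes if g.species == sp0 and g.family_id is not None]
    main_family = cfg.families[0].name if cfg.families else None
    main_genes = sorted(
        g.gene_id for g in fam_genes if g.family_id == main_family
    )
    other_fam_genes = sorted(
        g.gene_id for g in fam_genes if g.family_id != main_family
    )
    n_silent = int(round(cfg.fraction_silent * len(main_genes)))
    silent_ids = sorted(
        rng.choice(main_genes, size=n_silent, replace=False)
    ) if main_genes else []
    expressed_ids = [g for g in main_genes if g not in set(silent_ids)]

    housekeeping = [f"{sp0}_hk_{i:02d}" for i in range(12)]
    matrix_genes = main_genes + other_fam_genes + housekeeping

    n_types = len(CELL_TYPES)
    n_cells = n_types * cfg.n_cells_per_type
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    cell_type = np.repeat(CELL_TYPES, cfg.n_cells_per_type)
    region = np.empty(n_cells, dtype=object)
    for i in range(n_cells):
        if cell_type[i] == TENTACLE_TYPE:
            region[i] = "tentacles"
        else:
            region[i] = BODY_REGIONS[i % len(BODY_REGIONS)]
    cell_meta = pd.DataFrame(
        {"cell_id": cell_ids, "cell_type": cell_type, "body_region": region}
    )

    r = 1.0 / cfg.nb_dispersion
    counts = np.zeros((n_cells, len(matrix_genes)), dtype=int)
    gene_truth: dict[str, dict] = {}

    def nb(mean: float, size: int) -> np.ndarray:
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)

    for j, gid in enumerate(matrix_genes):
        if gid in set(silent_ids):
            gene_truth[gid] = {"silent": True, "expressed_type": None}
            continue
        if gid in housekeeping:
            counts[:, j] = nb(2.0, n_cells)
            gene_truth[gid] = {"silent": False, "expressed_type": "all"}
            continue
        if gid in expressed_ids:
            # first expressed paralogue is the planted tentacle-restricted one
            ctype = TENTACLE_TYPE if gid == expressed_ids[0] else "germline"
        else:
            ctype = "endo_epithelial"
        mask = cell_type == ctype
        draws = np.maximum(nb(cfg.expr_mean, int(mask.sum())), 1)
        counts[mask, j] = draws
        gene_truth[gid] = {"silent": False, "expressed_type": ctype}

    # ATAC peaks: every family gene primed, housekeeping primed, decoys not
    peaks: list[tuple[str, int, int]] = []
    primed_ids = {g.gene_id for g in fam_genes}
    for g in sorted(fam_genes, key=lambda g: (g.scaffold, g.start)):
        if g.strand == "+":
            tss0 = g.start - 1
            center = tss0 - 1_250
        else:
            tss0 = g.end - 1
            center = tss0 + 1 + 1_250
        start = max(0, center - 200)
        peaks.append((g.scaffold, start, start + 400))
    for gid in gene_truth:
        gene_truth[gid]["primed"] = gid in primed_ids
    return counts, matrix_genes, cell_meta, peaks, gene_truth


# ---------------------------------------------------------------------------
# File emission (all plain text)

def write_simulation(sim: Simulation, outdir: str | Path, genome_fasta: bool = False) -> dict[str, Path]:
    """Write FASTA/GFF3/TSV/MTX/BED/JSON files; byte-identical per seed."""
    import scipy.io as sio
    import scipy.sparse as sp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["proteins"] = outdir / "proteins.faa"
    write_fasta(sim.peptides, paths["proteins"])

    for species in sim.config.species:
        sp_genes = [g for g in sim.genes if g.species == species]
        if not sp_genes:
            continue
        path = outdir / f"genes_{species}.gff3"
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(sp_genes, key=lambda g: (g.scaffold, g.start)):
                attrs = f"ID={g.gene_id}"
                if g.family_id:
                    attrs += f";family={g.family_id}"
                fh.write(
                    f"{g.scaffold}\tampatlas_sim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                fh.write(
                    f"{g.scaffold}\tampatlas_sim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
                )
                fh.write(
                    f"{g.scaffold}\tampatlas_sim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
                )
        paths[f"gff_{species}"] = path

    paths["orthologs"] = outdir / "orthologs.tsv"
    with open(paths["orthologs"], "w") as fh:
        fh.write("query_gene\ttarget_gene\n")
        for a in sorted(sim.orthologs):
            fh.write(f"{a}\t{sim.orthologs[a]}\n")

    paths["matrix"] = outdir / "expression.mtx"
    sio.mmwrite(str(paths["matrix"]), sp.csr_matrix(sim.counts))
    paths["matrix_genes"] = outdir / "expression_genes.tsv"
    paths["matrix_cells"] = outdir / "expression_cells.tsv"
    pd.Series(sim.matrix_genes).to_csv(
        paths["matrix_genes"], sep="\t", index=False, header=False
    )
    sim.cell_meta["cell_id"].to_csv(
        paths["matrix_cells"], sep="\t", index=False, header=False
    )
    paths["metadata"] = outdir / "cell_metadata.tsv"
    sim.cell_meta.to_csv(paths["metadata"], sep="\t", index=False)

    paths["peaks"] = outdir / "peaks.bed"
    with open(paths["peaks"], "w") as fh:
        for scaffold, start, end in sorted(sim.peaks):
            fh.write(f"{scaffold}\t{start}\t{end}\n")

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(sim.truth, indent=1, sort_keys=True))

    if genome_fasta:
        paths["genome"] = outdir / "genome_stub.fa"
        with open(paths["genome"], "w") as fh:
            spans: dict[tuple[str, str], int] = {}
            for g in sim.genes:
                key = (g.species, g.scaffold)
                spans[key] = max(spans.get(key, 0), g.end + 1_000)
            for (species, scaffold), length in sorted(spans.items()):
                fh.write(f">{species}|{scaffold}\n")
                for i in range(0, length, 80):
                    fh.write("N" * min(80, length - i) + "\n")
    return paths


def counts_to_anndata(sim: Simulation):
    """In-memory AnnData (cells x genes) from the simulated counts."""
    import anndata as ad

    adata = ad.AnnData(
        X=sim.counts.astype(float),
        obs=sim.cell_meta.set_index("cell_id"),
        var=pd.DataFrame(index=pd.Index(sim.matrix_genes, name="gene_id")),
    )
    return adata
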