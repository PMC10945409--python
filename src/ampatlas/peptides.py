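"""Physicochemical hallmarks of antimicrobial-peptide (AMP) precursors.

Hydra AMP precursors share a recognizable anatomy: a small secreted protein
with an N-terminal signal peptide, a bipartite charge distribution (an
anionic block followed by a strongly cationic block, or vice versa), dibasic
proteolytic processing sites, and a characteristic cysteine scaffold.  This
module computes those hallmarks from the amino-acid sequence alone and
applies a transparent decision list to label each peptide as an AMP
candidate, a defensin-like peptide, a cysteine/tryptophan-rich (CWR-family)
peptide, or none of these.

All heuristics are rule-based and fully deterministic; no external
predictors are invoked.  Thresholds are exposed through
:class:`FeatureConfig` so they can be tightened or relaxed per dataset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Side-chain charge at neutral pH: Lys/Arg +1, Asp/Glu -1, His 0, termini ignored.
CHARGE: dict[str, float] = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

#: Kyte-Doolittle hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

#: Small residues allowed at the -3 and -1 positions of a signal-peptidase site.
SMALL_RESIDUES = frozenset("AGSCTV")

#: Dibasic proteolytic processing motifs (prohormone-convertase style).
DIBASIC_MOTIFS = ("KR", "RR", "KK", "RK")

# Six-cysteine spacing grammars (allowed ranges for the five inter-Cys gaps).
# A "big" defensin is the beta grammar preceded by a >=25-residue Cys-free
# N-terminal extension.
DEFENSIN_TEMPLATES: dict[str, tuple[tuple[int, int], ...]] = {
    "defensin_alpha": ((1, 1), (3, 4), (9, 9), (6, 9), (0, 0)),
    "defensin_beta": ((4, 6), (3, 4), (9, 13), (4, 7), (0, 0)),
}
BIG_DEFENSIN_MIN_PREFIX = 25


class PeptideError(ValueError):
    """Invalid peptide sequence or out-of-range request."""


@dataclass(frozen=True)
class Peptide:
    """A precursor peptide with its species of origin.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    species : str
        Species tag (free text, e.g. ``"H_vulgaris_AEP"``).
    sequence : str
        Amino-acid sequence in the 20-letter alphabet (``X`` permitted).
    source_gene : str, optional
        Gene model the precursor was predicted from.
    """

    id: str
    species: str
    sequence: str
    source_gene: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise PeptideError(
                f"peptide {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignalPeptideCall:
    present: bool
    cleavage_pos: int  # 1-based residue after which cleavage occurs; 0 if absent
    n_region_charge: float
    h_region_score: float
    too_short: bool = False


@dataclass(frozen=True)
class CysPattern:
    n_cys: int
    spacing: tuple[int, ...]  # residues between consecutive cysteines
    template_match: str  # defensin_alpha | defensin_beta | big_defensin | hycwr_like | other | none


@dataclass(frozen=True)
class AmpFeatureVector:
    peptide_id: str
    species: str
    length: int
    net_charge: float
    polarity_score: float
    polarity_split: int
    trp_fraction: float
    cys_pattern: CysPattern
    signal: SignalPeptideCall
    cleavage_sites: tuple[int, ...]


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable thresholds of the hallmark classifier."""

    h_min: float = 1.5          # min mean KD hydropathy of the signal h-region window
    trp_min: float = 0.08       # min Trp fraction for the CWR-family call
    len_max: int = 120          # max mature-peptide length for an AMP candidate
    pol_min: float = 0.5        # min bipartite-charge contrast for an AMP candidate
    q_min: float = 3.0          # min mature net charge for an AMP candidate
    charge: dict[str, float] = field(default_factory=lambda: dict(CHARGE))
    templates: dict[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFENSIN_TEMPLATES)
    )


DEFAULT_CONFIG = FeatureConfig()


def net_charge(
    p: Peptide,
    region: tuple[int, int] | None = None,
    charge: dict[str, float] | None = None,
) -> float:
    """Net side-chain charge of ``p`` over a 1-based closed ``region``.

    Additive over disjoint regions by construction.
    """
    table = CHARGE if charge is None else charge
    if region is None:
        region = (1, len(p))
    lo, hi = region
    if not (1 <= lo <= hi <= len(p)):
        raise PeptideError(
            f"region {region} out of bounds for length-{len(p)} peptide {p.id!r}"
        )
    return float(sum(table.get(aa, 0.0) for aa in p.sequence[lo - 1 : hi]))


def polarity_score(
    p: Peptide, charge: dict[str, float] | None = None
) -> tuple[float, int]:
    """Maximal C-minus-N mean-charge contrast over central split points.

    Splits ``s`` range over ``[ceil(L/4), floor(3L/4)]``; the score is
    ``mean(charge[s+1..L]) - mean(charge[1..s])`` maximized over ``s``, with
    the smallest attaining split returned on ties.  A charge-uniform
    sequence scores 0.
    """
    table = CHARGE if charge is None else charge
    L = len(p)
    if L < 4:
        raise PeptideError(f"polarity_score needs length >= 4, got {L}")
    charges = [table.get(aa, 0.0) for aa in p.sequence]
    lo = -(-L // 4)  # ceil(L/4)
    hi = (3 * L) // 4
    best_score, best_split = None, None
    prefix = 0.0
    cum = []
    for c in charges:
        prefix += c
        cum.append(prefix)
    total = cum[-1]
    for s in range(lo, hi + 1):
        left = cum[s - 1] / s
        right = (total - cum[s - 1]) / (L - s)
        score = right - left
        if best_score is None or score > best_score + 1e-12:
            best_score, best_split = score, s
    return float(best_score), int(best_split)


def trp_fraction(p: Peptide) -> float:
    return p.sequence.count("W") / len(p)


def _gaps_match(spacing: Sequence[int], template: Sequence[tuple[int, int]]) -> bool:
    if len(spacing) != len(template):
        return False
    return all(lo <= g <= hi for g, (lo, hi) in zip(spacing, template))


def cys_pattern(p: Peptide, config: FeatureConfig = DEFAULT_CONFIG) -> CysPattern:
    """Cysteine count, inter-Cys spacing, and scaffold-grammar match.

    Six-Cys peptides are checked against the alpha/beta defensin gap
    grammars (a beta match behind a >=25-residue Cys-free leader counts as a
    big defensin).  Six-Cys peptides failing every defensin grammar but rich
    in tryptophan are called ``hycwr_like``.
    """
    positions = [i + 1 for i, aa in enumerate(p.sequence) if aa == "C"]
    n = len(positions)
    spacing = tuple(
        positions[i + 1] - positions[i] - 1 for i in range(n - 1)
    )
    if n == 0:
        return CysPattern(0, (), "none")
    match = "other"
    if n == 6:
        if _gaps_match(spacing, config.templates["defensin_alpha"]):
            match = "defensin_alpha"
        elif _gaps_match(spacing, config.templates["defensin_beta"]):
            if positions[0] - 1 >= BIG_DEFENSIN_MIN_PREFIX:
                match = "big_defensin"
            else:
                match = "defensin_beta"
        elif trp_fraction(p) >= config.trp_min:
            match = "hycwr_like"
    return CysPattern(n, spacing, match)


def find_cleavage_sites(p: Peptide) -> list[int]:
    """1-based positions of the *second* residue of each dibasic motif.

    Overlapping motifs are all reported (``KKK`` yields positions 2 and 3).
    """
    seq = p.sequence
    sites = [
        i + 2
        for i in range(len(seq) - 1)
        if seq[i : i + 2] in DIBASIC_MOTIFS
    ]
    return sites


def detect_signal_peptide(
    p: Peptide, config: FeatureConfig = DEFAULT_CONFIG
) -> SignalPeptideCall:
    """Heuristic signal-peptide call from the classic tripartite anatomy.

    A signal peptide is called present when all three hold:

    1. the N-region (residues 1-5) carries a non-negative net charge;
    2. some 7-residue window within residues 6-30 reaches mean
       Kyte-Doolittle hydropathy >= ``h_min`` (the hydrophobic core);
    3. a signal-peptidase site obeying the (-3,-1) small-residue rule lies
       in residues 15-45; the earliest qualifying position is reported.

    Sequences shorter than 25 residues are returned as absent with the
    ``too_short`` flag raised.
    """
    seq = p.sequence
    if len(seq) < 25:
        return SignalPeptideCall(False, 0, 0.0, 0.0, too_short=True)
    n_charge = net_charge(p, (1, 5), config.charge)
    h_best = float("-inf")
    for start in range(6, min(30, len(seq)) - 6 + 1):  # 1-based window starts
        window = seq[start - 1 : start + 6]
        h = sum(KYTE_DOOLITTLE[aa] for aa in window) / 7.0
        h_best = max(h_best, h)
    cleavage = 0
    for pos in range(15, min(45, len(seq)) + 1):
        if seq[pos - 1] in SMALL_RESIDUES and seq[pos - 3] in SMALL_RESIDUES:
            cleavage = pos
            break
    present = n_charge >= 0 and h_best >= config.h_min and cleavage > 0
    return SignalPeptideCall(present, cleavage if present else 0, n_charge, h_best)


def compute_features(
    p: Peptide, config: FeatureConfig = DEFAULT_CONFIG
) -> AmpFeatureVector:
    """Full hallmark vector for one peptide."""
    if len(p) >= 4:
        pol, split = polarity_score(p, config.charge)
    else:
        pol, split = 0.0, 1
    return AmpFeatureVector(
        peptide_id=p.id,
        species=p.species,
        length=len(p),
        net_charge=net_charge(p, None, config.charge),
        polarity_score=pol,
        polarity_split=split,
        trp_fraction=trp_fraction(p),
        cys_pattern=cys_pattern(p, config),
        signal=detect_signal_peptide(p, config),
        cleavage_sites=tuple(find_cleavage_sites(p)),
    )


def classify_peptide(
    fv: AmpFeatureVector,
    p: Peptide | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> str:
    """Decision-list label: defensin grammar first, then the CWR grammar,
    then the secreted-cationic AMP-candidate test, else ``none``.

    The AMP-candidate test requires a called signal peptide, a mature region
    of at most ``len_max`` residues, and either a bipartite-charge contrast
    >= ``pol_min`` or a mature net charge >= ``q_min``.
    """
    match = fv.cys_pattern.template_match
    if match in ("defensin_alpha", "defensin_beta", "big_defensin"):
        return "defensin_like"
    if match == "hycwr_like":
        return "hycwr_like"
    if fv.signal.present:
        mature_len = fv.length - fv.signal.cleavage_pos
        if p is not None:
            mature_charge = net_charge(
                p, (fv.signal.cleavage_pos + 1, fv.length), config.charge
            )
        else:
            # without the sequence, approximate the mature charge by the whole-
            # precursor charge (signal peptides are near-neutral under this scheme)
            mature_charge = fv.net_charge
        if mature_len <= config.len_max and (
            fv.polarity_score >= config.pol_min or mature_charge >= config.q_min
        ):
            return "amp_candidate"
    return "none"


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing

_HEADER_KV = re.compile(r"\[(\w+)=([^\]]*)\]")


def read_fasta(path: str | Path, default_species: str = "unknown") -> list[Peptide]:
    """Read peptides from protein FASTA; ``[species=...]`` header keys parsed."""
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(_HEADER_KV.findall(rec.description))
        peptides.append(
            Peptide(
                id=rec.id,
                species=kv.get("species", default_species),
                sequence=str(rec.seq).upper(),
                source_gene=kv.get("gene"),
            )
        )
    ids = [p.id for p in peptides]
    if len(set(ids)) != len(ids):
        raise PeptideError(f"duplicate peptide ids in {path}")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    records = [
        SeqRecord(
            Seq(p.sequence),
            id=p.id,
            description=f"[species={p.species}]"
            + (f" [gene={p.source_gene}]" if p.source_gene else ""),
        )
        for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def features_table(
    peptides: Sequence[Peptide], config: FeatureConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-peptide hallmark table with the final label."""
    rows = []
    for p in peptides:
        fv = compute_features(p, config)
        rows.append(
            {
                "id": p.id,
                "species": p.species,
                "length": fv.length,
                "net_charge": fv.net_charge,
                "polarity_score": round(fv.polarity_score, 6),
                "polarity_split": fv.polarity_split,
                "n_cys": fv.cys_pattern.n_cys,
                "spacing": "-".join(map(str, fv.cys_pattern.spacing)),
                "trp_fraction": round(fv.trp_fraction, 6),
                "signal_present": fv.signal.present,
                "cleavage_pos": fv.signal.cleavage_pos,
                "label": classify_peptide(fv, p, config),
            }
        )
    return pd.DataFrame(rows)
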