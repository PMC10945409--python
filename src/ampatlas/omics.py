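"""Single-cell expression and chromatin-accessibility evidence for AMP genes.

A striking feature of Hydra AMP families is that most paralogues are
transcriptionally silent under homeostatic conditions, yet their promoter
regions carry open-chromatin (ATAC) peaks — they are silent but primed for
induction.  This module calls expressed/silent status per gene from a
cell-annotated count matrix, quantifies cell-type specificity with the tau
statistic, tests spatial restriction along the body axis, and intersects
gene-upstream windows with ATAC peaks to call promoter priming.

Counts live in an :class:`anndata.AnnData` (cells x genes) with ``obs``
columns ``cell_type`` and optionally ``body_region``; normalization follows
the standard single-cell recipe (scale each cell to 10,000 total counts,
then log1p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from intervaltree import IntervalTree

from .genome import GeneModel


class OmicsError(ValueError):
    pass


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    status: str  # expressed | silent
    expressing_cell_types: tuple[str, ...]
    specificity_tau: float  # NaN for silent genes
    region_restricted: bool | None = None


@dataclass(frozen=True)
class PrimingCall:
    gene_id: str
    primed: bool
    nearest_peak_distance: float  # bp from TSS, negative = upstream; NaN if no peak


# ---------------------------------------------------------------------------
# Matrix I/O and normalization

def load_matrix(
    matrix_path: str | Path,
    metadata_path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ad.AnnData:
    """Load a cells x genes count matrix with cell metadata.

    ``matrix_path`` may be MatrixMarket (``.mtx``, with genes/cells sidecar
    files) or a dense TSV (genes in columns, cell ids in the first column).
    Metadata TSV needs columns ``cell_id`` and ``cell_type``
    (``body_region`` optional).
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        import scipy.io as sio

        counts = sio.mmread(str(matrix_path)).tocsr()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
        adata = ad.AnnData(
            X=counts,
            obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
        )
    else:
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        adata = ad.AnnData(X=df.to_numpy(dtype=float), obs=pd.DataFrame(index=df.index),
                           var=pd.DataFrame(index=df.columns))
    meta = pd.read_csv(metadata_path, sep="\t").set_index("cell_id")
    missing = adata.obs_names.difference(meta.index)
    if len(missing):
        raise OmicsError(f"cells without metadata: {list(missing)[:5]}")
    adata.obs["cell_type"] = meta.loc[adata.obs_names, "cell_type"].astype(str).values
    if "body_region" in meta.columns:
        adata.obs["body_region"] = (
            meta.loc[adata.obs_names, "body_region"].astype(str).values
        )
    return adata


def normalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Per-cell depth normalization to ``target_sum`` followed by log1p.

    Cells with zero total count are dropped with a warning; raw counts are
    kept in ``layers['counts']``.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals == 0).all():
        raise OmicsError("all cells have zero total count")
    if (totals == 0).any():
        n0 = int((totals == 0).sum())
        warnings.warn(f"dropping {n0} zero-count cells")
        adata = adata[totals > 0].copy()
    else:
        adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    sc.pp.normalize_total(adata, target_sum=target_sum)
    sc.pp.log1p(adata)
    return adata


# ---------------------------------------------------------------------------
# Expression calls

def specificity_tau(profile: np.ndarray) -> float:
    """Tau specificity over a per-cell-type mean-expression profile.

    0 for a uniform profile, 1 when a single cell type carries all
    expression; undefined (NaN) for an all-zero profile.
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2 or x.max() <= 0:
        return float("nan")
    xhat = x / x.max()
    return float(np.sum(1.0 - xhat) / (x.size - 1))


def call_expression(
    adata: ad.AnnData,
    detect_frac: float = 0.01,
    min_cells: int = 3,
) -> list[ExpressionCall]:
    """Expressed/silent status and cell-type specificity per gene.

    A gene is expressed in cell type ``t`` when its raw count is positive
    in at least ``max(min_cells, detect_frac * n_cells(t))`` cells of
    ``t``; a gene is globally expressed when some cell type qualifies.
    Tau is computed on per-type mean normalized expression.
    """
    if "cell_type" not in adata.obs:
        raise OmicsError("adata.obs lacks a cell_type column")
    counts = adata.layers.get("counts", adata.X)
    counts = np.asarray(counts.todense() if hasattr(counts, "todense") else counts)
    norm = np.asarray(
        adata.X.todense() if hasattr(adata.X, "todense") else adata.X
    )
    types = adata.obs["cell_type"].astype(str)
    out = []
    type_masks = {t: (types == t).to_numpy() for t in sorted(types.unique())}
    for j, gene in enumerate(adata.var_names):
        expressing = []
        for t, mask in type_masks.items():
            n_pos = int((counts[mask, j] > 0).sum())
            need = max(min_cells, int(np.ceil(detect_frac * mask.sum())))
            if n_pos >= need:
                expressing.append(t)
        if expressing:
            profile = np.array([norm[mask, j].mean() for mask in type_masks.values()])
            tau = specificity_tau(profile)
            out.append(ExpressionCall(gene, "expressed", tuple(expressing), tau))
        else:
            out.append(ExpressionCall(gene, "silent", (), float("nan")))
    return out


def region_restriction(
    call: ExpressionCall,
    adata: ad.AnnData,
    region_frac: float = 0.8,
) -> bool | None:
    """True when >= ``region_frac`` of a gene's positive cells share one
    body region; None when region labels are unavailable."""
    if "body_region" not in adata.obs:
        return None
    if call.status == "silent":
        return False
    counts = adata.layers.get("counts", adata.X)
    counts = np.asarray(counts.todense() if hasattr(counts, "todense") else counts)
    j = adata.var_names.get_loc(call.gene_id)
    pos = counts[:, j] > 0
    if not pos.any():
        return False
    regions = adata.obs["body_region"].astype(str)[pos]
    top = regions.value_counts(sort=True).iloc[0]
    return bool(top / pos.sum() >= region_frac)


# ---------------------------------------------------------------------------
# ATAC priming

@dataclass(frozen=True)
class AtacPeakSet:
    """ATAC peaks as 0-based half-open intervals per scaffold."""

    trees: dict[str, IntervalTree]

    @classmethod
    def from_bed(cls, path: str | Path) -> "AtacPeakSet":
        trees: dict[str, IntervalTree] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                scaffold, start, end = fields[0], int(fields[1]), int(fields[2])
                if start >= end:
                    raise OmicsError(f"invalid BED interval {scaffold}:{start}-{end}")
                trees.setdefault(scaffold, IntervalTree()).addi(start, end)
        return cls(trees)

    @classmethod
    def from_intervals(
        cls, intervals: Sequence[tuple[str, int, int]]
    ) -> "AtacPeakSet":
        trees: dict[str, IntervalTree] = {}
        for scaffold, start, end in intervals:
            if start >= end:
                raise OmicsError(f"invalid interval {scaffold}:{start}-{end}")
            trees.setdefault(scaffold, IntervalTree()).addi(start, end)
        return cls(trees)


def call_priming(
    genes: Sequence[GeneModel],
    peaks: AtacPeakSet,
    upstream_bp: int = 2500,
) -> list[PrimingCall]:
    """Promoter priming from ATAC peaks in the strand-aware upstream window.

    The TSS is the gene-model 5' end (start for + strand, end for -); the
    window is the ``upstream_bp`` bases immediately 5' of the TSS,
    excluding the TSS itself.  A gene is primed when any peak overlaps the
    window.  The nearest-peak distance is signed with upstream negative
    (0 when a peak covers the TSS); NaN when the scaffold has no peaks.
    """
    out = []
    for g in genes:
        tree = peaks.trees.get(g.scaffold)
        if tree is None or not tree:
            out.append(PrimingCall(g.gene_id, False, float("nan")))
            continue
        if g.strand == "+":
            tss0 = g.start - 1  # 0-based TSS position
            win = (max(0, tss0 - upstream_bp), tss0)
        else:
            tss0 = g.end - 1
            win = (tss0 + 1, tss0 + 1 + upstream_bp)
        primed = bool(tree.overlap(*win)) if win[0] < win[1] else False
        out.append(
            PrimingCall(g.gene_id, primed, _nearest_distance(tree, tss0, g.strand))
        )
    return out


def _nearest_distance(tree: IntervalTree, tss0: int, strand: str) -> float:
    """Signed bp offset of the closest peak base from the TSS (upstream < 0)."""
    best = None
    for iv in tree:
        if iv.begin <= tss0 < iv.end:
            return 0.0
        # closest base of this peak, 0-based
        base = iv.end - 1 if iv.end - 1 < tss0 else iv.begin
        offset = base - tss0 if strand == "+" else tss0 - base
        if best is None or abs(offset) < abs(best):
            best = offset
    return float(best) if best is not None else float("nan")


def silent_but_primed(
    calls: Sequence[ExpressionCall], primings: Sequence[PrimingCall]
) -> list[str]:
    """Genes silent in the atlas whose promoters carry an ATAC peak."""
    silent = {c.gene_id for c in calls if c.status == "silent"}
    primed = {p.gene_id for p in primings if p.primed}
    return sorted(silent & primed)


def expression_table(
    calls: Sequence[ExpressionCall], restricted: Mapping[str, bool | None] | None = None
) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "gene": c.gene_id,
                "status": c.status,
                "tau": round(c.specificity_tau, 6) if np.isfinite(c.specificity_tau) else "",
                "expressing_types": ",".join(c.expressing_cell_types),
                "region_restricted": (
                    "" if restricted is None or restricted.get(c.gene_id) is None
                    else bool(restricted[c.gene_id])
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "status", "tau", "expressing_types", "region_restricted"]
    )


def priming_table(primings: Sequence[PrimingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": p.gene_id,
                "primed": p.primed,
                "distance": p.nearest_peak_distance,
            }
            for p in primings
        ],
        columns=["gene", "primed", "distance"],
    )
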