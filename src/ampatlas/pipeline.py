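"""End-to-end orchestration: features -> scan -> families -> genome context
-> omics integration, with a consolidated JSON report.

The reference entry point is :func:`run_scenario`, which runs the whole
analysis chain over the synthetic two-species scenario and checks the
closed loop against the generator's truth table: family sizes, the
two-granularity cluster structure of the main family locus, the
silent-but-primed paralogue set, and the planted syntenic family loss.
All randomness flows from one integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from . import families as fam_mod
from . import genome as gen_mod
from . import omics as omics_mod
from . import scan as scan_mod
from . import simulate as sim_mod
from .peptides import features_table

CLUSTER_PRESETS = {"preset_50k": 50_000, "preset_200k": 200_000}


@dataclass(frozen=True)
class ScenarioConfig:
    """Thresholds of the end-to-end run; YAML-loadable, flags override.

    Every field has the library default; a config file only needs the keys
    it wants to change.
    """

    seed: int = 0
    id_min: float = 0.5        # family-edge identity threshold
    cov_min: float = 0.6       # family-edge coverage threshold
    f_min: int = 3             # minimum species-clade size for founder calls
    detect_frac: float = 0.01  # per-cell-type detection fraction
    min_cells: int = 3         # per-cell-type detection floor
    upstream_bp: int = 2500    # ATAC priming window
    sigma_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def train_scenario_model(
    seed: int, n_each: int = 60, window_len: int = 19
) -> scan_mod.SigmaModel:
    """Sigma model trained on freshly drawn synthetic AMP/decoy peptides."""
    rng = np.random.default_rng(seed + 10_007)
    pos = [
        sim_mod.make_peptide("amp_bipartite", rng, f"amp{i:03d}", mature_len=40)
        for i in range(n_each)
    ]
    neg = [sim_mod.make_peptide("decoy", rng, f"dec{i:03d}") for i in range(n_each)]
    return scan_mod.train_sigma_model(pos, neg, window_len=window_len, seed=seed)


def run_scenario(
    seed: int = 0,
    outdir: str | Path | None = None,
    config: ScenarioConfig | None = None,
) -> dict:
    """Full pipeline over the default synthetic scenario; returns the report.

    When ``outdir`` is given, per-stage TSVs and the JSON report are
    written there (byte-identical across reruns with the same seed).
    """
    sc = config or ScenarioConfig(seed=seed)
    cfg = sim_mod.default_config(seed)
    sim = sim_mod.simulate(cfg)
    if not sim.peptides:
        raise ValueError("no peptides generated; invalid configuration")
    truth_family = {
        gid: info.get("family") for gid, info in sim.truth["genes"].items()
    }

    # --- stage 1: peptide hallmark features -------------------------------
    feats = features_table(sim.peptides)

    # --- stage 2: membrane-activity scan ----------------------------------
    model = train_scenario_model(seed)
    roles = {gid: info.get("role") for gid, info in sim.truth["genes"].items()}
    fam_peps = [p for p in sim.peptides if truth_family.get(p.id)]
    decoy_peps = [p for p in sim.peptides if roles.get(p.id) == "decoy"]
    profiles = [scan_mod.scan(p, model) for p in fam_peps + decoy_peps]
    scan_tab = scan_mod.scan_table(profiles)

    # --- stage 3: paralogue families and trees ----------------------------
    alignments = fam_mod.all_pairs_align(sim.peptides)
    inferred = fam_mod.build_families(
        sim.peptides, sc.id_min, sc.cov_min, alignments=alignments
    )
    species_of = {p.id: p.species for p in sim.peptides}
    # name inferred families by the majority true family of their members
    fam_name: dict[str, str] = {}
    for f in inferred:
        votes: dict[str, int] = {}
        for m in f.members:
            t = truth_family.get(m)
            if t:
                votes[t] = votes.get(t, 0) + 1
        fam_name[f.family_id] = (
            max(sorted(votes), key=lambda k: votes[k]) if votes else f.family_id
        )
    big = [f for f in inferred if len(f) >= 3]
    clade_reports = {}
    for f in big:
        tree = fam_mod.build_tree(f, sim.peptides, alignments)
        st = fam_mod.clade_stats(tree, species_of, f_min=sc.f_min)
        clade_reports[fam_name[f.family_id]] = {
            "largest_clade": dict(sorted(st.largest_clade.items())),
            "n_founders": st.n_founder_lineages,
        }

    # --- stage 4: genomic context -----------------------------------------
    big_names = {fam_name[f.family_id] for f in big}
    member_family = {
        m: fam_name[f.family_id]
        for f in inferred
        for m in f.members
        if fam_name[f.family_id] in big_names
    }
    genes = gen_mod.assign_families(sim.genes, member_family)
    cluster_report: dict[str, dict] = {}
    named_fams = sorted({g.family_id for g in genes if g.family_id})
    for name in named_fams:
        fam_genes = [g for g in genes if g.family_id == name]
        cluster_report[name] = {}
        for preset, gap in CLUSTER_PRESETS.items():
            per_scaffold: dict[str, list[int]] = {}
            clusters, unclustered = gen_mod.detect_clusters(fam_genes, gap)
            for c in clusters:
                per_scaffold.setdefault(c.scaffold, []).append(len(c))
            for g in unclustered:
                per_scaffold.setdefault(g.scaffold, [])
            cluster_report[name][preset] = {
                "clusters": {
                    s: sorted(v, reverse=True) for s, v in sorted(per_scaffold.items())
                },
                "n_unclustered": len(unclustered),
            }
    trg = gen_mod.scan_trg_clusters(genes, sim.peptides)
    synteny = []
    seen_pairs = set()
    for fam, target in [(f, s) for f, s in cfg.planted_losses] + [
        (cfg.families[0].name, cfg.species[1])
    ]:
        if (fam, target) in seen_pairs:
            continue
        seen_pairs.add((fam, target))
        try:
            v = gen_mod.synteny_presence(
                fam, cfg.species[0], target, sim.orthologs, sim.genes
            )
        except gen_mod.GenomeError:
            continue
        synteny.append(
            {"family": fam, "query": cfg.species[0], "target": target,
             "status": v.status, "anchors": v.anchor_count}
        )

    # --- stage 5: omics integration ---------------------------------------
    adata = sim_mod.counts_to_anndata(sim)
    adata = omics_mod.normalize(adata)
    calls = omics_mod.call_expression(adata, sc.detect_frac, sc.min_cells)
    restricted = {
        c.gene_id: omics_mod.region_restriction(c, adata) for c in calls
    }
    main_name = cfg.families[0].name
    main_genes = [g for g in sim.genes if truth_family.get(g.gene_id) == main_name
                  and g.species == cfg.species[0]]
    peaks = omics_mod.AtacPeakSet.from_intervals(sim.peaks)
    primings = omics_mod.call_priming(main_genes, peaks, sc.upstream_bp)
    main_ids = {g.gene_id for g in main_genes}
    main_calls = [c for c in calls if c.gene_id in main_ids]
    sbp = omics_mod.silent_but_primed(main_calls, primings)

    # --- consolidated report ----------------------------------------------
    by_truth_label = {}
    for label, ids in (
        ("amp_bipartite",
         [p.id for p in fam_peps if _template_of(sim, p.id) == "amp_bipartite"]),
        ("decoy", [p.id for p in decoy_peps]),
    ):
        sel = scan_tab[scan_tab["id"].isin(ids)]["mean_sigma"]
        if len(sel):
            by_truth_label[label] = float(sel.mean())
    report = {
        "seed": seed,
        "n_peptides": len(sim.peptides),
        "families": {
            fam_name[f.family_id]: {
                "total": len(f),
                "by_species": dict(sorted(f.species_counts.items())),
            }
            for f in big
        },
        "clusters": cluster_report,
        "clade_stats": clade_reports,
        "trg_clusters": [
            {"scaffold": c.scaffold, "n": len(c),
             "mean_identity": round(c.mean_identity, 4)}
            for c in trg
        ],
        "synteny": sorted(synteny, key=lambda v: (v["family"], v["target"])),
        "expression": {
            "n_genes": len(main_calls),
            "n_silent": sum(1 for c in main_calls if c.status == "silent"),
            "n_expressed": sum(1 for c in main_calls if c.status == "expressed"),
            "n_primed": sum(1 for p in primings if p.primed),
            "n_silent_but_primed": len(sbp),
            "n_region_restricted": sum(
                1 for c in main_calls if restricted.get(c.gene_id)
            ),
        },
        "scan_mean_sigma": by_truth_label,
        "label_counts": feats["label"].value_counts().to_dict(),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        feats.to_csv(outdir / "features.tsv", sep="\t", index=False)
        scan_tab.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        fam_mod.families_table(inferred, species_of).to_csv(
            outdir / "families.tsv", sep="\t", index=False
        )
        omics_mod.expression_table(calls, restricted).to_csv(
            outdir / "expression.tsv", sep="\t", index=False
        )
        omics_mod.priming_table(primings).to_csv(
            outdir / "priming.tsv", sep="\t", index=False
        )
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
    return report


def _template_of(sim: sim_mod.Simulation, pep_id: str) -> str | None:
    fam = sim.truth["genes"].get(pep_id, {}).get("family")
    for spec in sim.config.families:
        if spec.name == fam:
            return spec.template
    return None
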