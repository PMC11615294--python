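"""End-to-end pipelines tying the modules together, with run manifests.

``run_crosschath`` executes: embedding -> KNN graph -> Markov-stability scan
-> scale selection -> marker assignment -> specific pairs (-> interactions).
``run_crosschatt`` executes: binarize -> (optional spatial restriction) ->
relation graph -> maximal cliques -> forests -> frequency ranking.
Both are deterministic given (config, seed) and write plain-text outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ccc import hierarchy_groups, hierarchy_interactions
from .graph import embed, knn_graph
from .io import (
    ExpressionMatrix,
    LRDatabase,
    RAW_COUNTS,
    SpatialCoords,
    drop_empty_cells,
    lognormalize,
)
from .markov import HierarchicalClustering, build_operator, run_scan, select_scales
from .spatial import augment_embedding, build_neighborhood, restrict_supports
from .specificity import assign_markers, specific_pairs
from .trees import TreeSet, binarize, trees_from_supports

logger = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    mode: str = "all"            # all | ligands | receptors
    k: int = 15
    n_components: int = 50
    n_hvg: int = 2000
    grid_min: float = -1.0
    grid_max: float = 4.0
    grid_points: int = 100
    louvain_runs: int = 100
    basin_theta: float = 0.1
    basin_width: int = 3
    spatial_weight: float = 1.0
    p_threshold: float = 1e-3
    seed: int = 0


@dataclass
class TreesConfig:
    kind: str = "ligand"         # ligand | receptor | lr_union
    tau: float = 0.0
    eps: float = 0.0
    min_cells: int = 10
    min_nodes: int = 2
    radius: float | None = None  # spatial restriction when coords given
    seed: int = 0


@dataclass
class CrossChatHResult:
    hierarchy: HierarchicalClustering
    scan: "object"
    pairs: list
    assignments_ligand: dict
    assignments_receptor: dict
    interactions: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _prepare(em: ExpressionMatrix) -> ExpressionMatrix:
    if em.layer_tag == RAW_COUNTS:
        em = drop_empty_cells(em)
        em = lognormalize(em)
    return em


def run_crosschath(
    em: ExpressionMatrix,
    db: LRDatabase | None,
    cfg: ClusterConfig | None = None,
    coords: SpatialCoords | None = None,
    outdir: str | Path | None = None,
    score_interactions: bool = False,
) -> CrossChatHResult:
    cfg = cfg or ClusterConfig()
    if cfg.mode in ("ligands", "receptors") and db is None:
        raise ValueError(f"mode={cfg.mode!r} requires a ligand-receptor database")
    lognorm = _prepare(em)
    if cfg.mode == "all":
        emb = embed(lognorm, "all", cfg.n_components, n_hvg=cfg.n_hvg, seed=cfg.seed)
    else:
        units = db.ligand_units if cfg.mode == "ligands" else db.receptor_units
        genes = sorted({s for u in units for s in u.split("_")})
        emb = embed(
            lognorm, genes, cfg.n_components, n_hvg=None, seed=cfg.seed,
            provenance=f"pca_{cfg.mode}",
        )
    if coords is not None:
        emb = augment_embedding(emb, coords, cfg.spatial_weight)
    g = knn_graph(emb, cfg.k)
    op = build_operator(g)
    scan = run_scan(
        op, cfg.grid_min, cfg.grid_max, cfg.grid_points, cfg.louvain_runs, cfg.seed
    )
    hier = select_scales(scan, cfg.basin_theta, cfg.basin_width)
    pairs = []
    lig_assign: dict = {}
    rec_assign: dict = {}
    interactions = []
    if db is not None:
        lig_assign = assign_markers(lognorm, hier, db.ligand_units)
        rec_assign = assign_markers(lognorm, hier, db.receptor_units)
        pairs = specific_pairs(lig_assign, rec_assign, db, cfg.p_threshold)
        if score_interactions:
            groups = hierarchy_groups(hier)
            interactions = hierarchy_interactions(
                lognorm, groups, db, pairs_subset=[p.name for p in pairs]
            )
    manifest = {
        "tool": "crosschat",
        "version": __version__,
        "stage": "crosschath",
        "config": asdict(cfg),
        "n_cells": lognorm.n_cells,
        "n_genes": lognorm.n_genes,
        "selected_scales": hier.n_communities(),
    }
    result = CrossChatHResult(hier, scan, pairs, lig_assign, rec_assign, interactions, manifest)
    if outdir is not None:
        write_crosschath_outputs(result, lognorm, Path(outdir))
    return result


def write_crosschath_outputs(
    res: CrossChatHResult, em: ExpressionMatrix, outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.hierarchy.to_frame(em.cell_ids).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    scan = res.scan
    pd.DataFrame(
        {
            "log10_t": scan.log_times,
            "markov_time": scan.times,
            "n_communities": scan.n_communities,
            "markov_stability": scan.ms_values,
            "vi_g": scan.vi_g,
        }
    ).to_csv(outdir / "scan.tsv", sep="\t", index=False)
    pd.DataFrame(scan.vi_p).to_csv(outdir / "vi_p.csv", index=False)
    rows = [
        {
            "ligand": p.ligand.unit,
            "receptor": p.receptor.unit,
            "pathway": p.pathway,
            "ligand_scale": p.ligand.scale,
            "ligand_cluster": p.ligand.cluster,
            "p_ligand": p.ligand.p_value,
            "receptor_scale": p.receptor.scale,
            "receptor_cluster": p.receptor.cluster,
            "p_receptor": p.receptor.p_value,
            "score": p.score,
        }
        for p in res.pairs
    ]
    pd.DataFrame(
        rows,
        columns=[
            "ligand", "receptor", "pathway", "ligand_scale", "ligand_cluster",
            "p_ligand", "receptor_scale", "receptor_cluster", "p_receptor", "score",
        ],
    ).to_csv(outdir / "specific_pairs.tsv", sep="\t", index=False)
    if res.interactions:
        pd.DataFrame(
            [
                {
                    "sender": i.sender,
                    "receiver": i.receiver,
                    "ligand": i.interaction.ligand,
                    "receptor": i.interaction.receptor,
                    "pathway": i.interaction.pathway,
                    "strength": i.strength,
                    "proportion": i.proportion,
                }
                for i in res.interactions
            ]
        ).to_csv(outdir / "interactions.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))


@dataclass
class CrossChatTResult:
    trees: TreeSet
    frequencies: list
    manifest: dict = field(default_factory=dict)


def run_crosschatt(
    em: ExpressionMatrix,
    db: LRDatabase,
    cfg: TreesConfig | None = None,
    coords: SpatialCoords | None = None,
    outdir: str | Path | None = None,
) -> CrossChatTResult:
    from .trees import frequency_ranking, _union_supports

    cfg = cfg or TreesConfig()
    if cfg.kind == "lr_union":
        sm = _union_supports(em, db, cfg.tau, cfg.min_cells)
    else:
        units = db.ligand_units if cfg.kind == "ligand" else db.receptor_units
        sm = binarize(em, units, cfg.tau, cfg.min_cells)
    if coords is not None and cfg.kind in ("ligand", "receptor"):
        idx = build_neighborhood(coords, cfg.radius)
        partner_units = db.receptor_units if cfg.kind == "ligand" else db.ligand_units
        partner_sm = binarize(em, partner_units, cfg.tau, min_cells=0)
        sm = restrict_supports(sm, partner_sm, db, idx, side=cfg.kind)
        sm.supports = [s for s in sm.supports]
        keep = [i for i, s in enumerate(sm.supports) if len(s) >= cfg.min_cells]
        sm.entity_ids = [sm.entity_ids[i] for i in keep]
        sm.supports = [sm.supports[i] for i in keep]
    ts = trees_from_supports(sm, kind=cfg.kind, eps=cfg.eps, min_nodes=cfg.min_nodes)
    ts.tau, ts.min_cells = cfg.tau, cfg.min_cells
    freqs = frequency_ranking(ts)
    manifest = {
        "tool": "crosschat",
        "version": __version__,
        "stage": "crosschatt",
        "config": asdict(cfg),
        "n_trees": len(ts),
    }
    res = CrossChatTResult(ts, freqs, manifest)
    if outdir is not None:
        write_crosschatt_outputs(res, Path(outdir))
    return res


def write_crosschatt_outputs(res: CrossChatTResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "kind": res.trees.kind,
        "tau": res.trees.tau,
        "eps": res.trees.eps,
        "trees": [t.to_dict() for t in res.trees.trees],
    }
    (outdir / "trees.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "trees.nwk").write_text(
        "\n".join(t.to_newick() for t in res.trees.trees) + ("\n" if res.trees.trees else "")
    )
    pd.DataFrame(res.frequencies, columns=["entity", "n_trees"]).to_csv(
        outdir / "frequency.tsv", sep="\t", index=False
    )
    (outdir / "manifest.json").write_text(json.dumps(res.manifest, indent=2, sort_keys=True))
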