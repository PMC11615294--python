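"""Synthetic validation data: hierarchical negative-binomial markers and
planted support trees, plus the evaluation metrics used against them.

Two generators are provided.  ``simulate_hierarchy`` emulates a scRNA-seq
count matrix with a perfect three-level cluster hierarchy (2/4/8 balanced
clusters over 1000 cells) in which 1000 of 10,000 genes are markers: 200
per cluster at the coarsest scale, 100 at the middle, 25 at the finest
(400/400/200 markers per scale).  Counts are negative binomial with
variance mu + 0.1 mu^2.  ``simulate_trees`` plants five laminar trees over
15 structured genes among 85 background genes, each background gene
expressed in 500 uniformly drawn cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import ExpressionMatrix, LRDatabase, LRInteraction, RAW_COUNTS
from .markov import HierarchicalClustering
from .specificity import MarkerAssignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reference parameters (base means + fold changes)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceParams:
    """Per-gene base means and per-scale marker fold changes.

    ``marker_mean_pool`` is the top-20% expression stratum from which marker
    base means are drawn; ``background_mean_pool`` is the lower-80% stratum
    for non-marker genes.
    """

    marker_mean_pool: np.ndarray
    background_mean_pool: np.ndarray
    fold_changes: tuple[float, float, float] = (3.0, 4.0, 5.0)


def reference_params(
    source: str = "builtin",
    path: str | Path | None = None,
    seed: int = 0,
    n_pool: int = 13714,
) -> ReferenceParams:
    """Build the generator's parameter profile.

    ``builtin``: a documented emulation — a pool of ``n_pool`` gene means
    drawn log-normal(mu=1, sigma=1), split at its 80th percentile into the
    marker stratum (top 20%) and background stratum (lower 80%), with fixed
    per-scale fold changes (3, 4, 5).  ``pbmc3k``: derive both strata and
    the fold changes from a local copy of the 10x PBMC-3k filtered matrix
    (2700 cells, 13,714 genes); requires ``path`` pointing at the extracted
    triplet directory.
    """
    if source == "builtin":
        rng = np.random.default_rng(seed)
        means = rng.lognormal(mean=1.0, sigma=1.0, size=n_pool)
        cut = np.quantile(means, 0.8)
        return ReferenceParams(
            marker_mean_pool=means[means >= cut],
            background_mean_pool=means[means < cut],
        )
    if source == "pbmc3k":
        if path is None or not Path(path).exists():
            raise FileNotFoundError(
                "pbmc3k mode needs the extracted 10x PBMC-3k filtered matrix "
                "(download pbmc3k_filtered_gene_bc_matrices.tar.gz from the 10x "
                "Genomics sample page and pass the directory containing "
                "matrix.mtx/genes.tsv/barcodes.tsv)"
            )
        return _pbmc3k_params(Path(path), seed)
    raise ValueError(f"unknown source {source!r}")


def _pbmc3k_params(path: Path, seed: int) -> ReferenceParams:
    """Steps: median-normalize totals, rank genes by mean expression, split
    at the 80th percentile; estimate per-scale fold changes as the median
    one-vs-rest fold change of the top 400/400/200 DE genes over a k-means
    clustering of the cells."""
    from .io import read_expression
    from .graph import embed, select_hvg
    from .io import lognormalize, drop_empty_cells
    from sklearn.cluster import KMeans

    em = read_expression(
        [path / "matrix.mtx", path / "genes.tsv", path / "barcodes.tsv"]
    )
    em = drop_empty_cells(em)
    totals = np.asarray(em.values.sum(axis=1)).ravel()
    factors = float(np.median(totals)) / totals
    import scipy.sparse as sp

    norm = sp.diags(factors) @ sp.csr_matrix(em.values, dtype=float)
    means = np.asarray(norm.mean(axis=0)).ravel()
    cut = np.quantile(means, 0.8)
    # fold changes from a one-vs-rest comparison over a coarse clustering
    ln = lognormalize(em)
    emb = embed(ln, "all", n_components=50, seed=seed)
    labels = KMeans(n_clusters=8, n_init=10, random_state=seed).fit_predict(emb.vectors)
    dense_means = []
    for c in range(8):
        m_in = np.asarray(norm[labels == c].mean(axis=0)).ravel()
        m_out = np.asarray(norm[labels != c].mean(axis=0)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(m_out > 0, m_in / np.maximum(m_out, 1e-9), 0.0)
        dense_means.append(fc)
    fc_best = np.max(np.vstack(dense_means), axis=0)
    order = np.argsort(-fc_best)
    f1 = float(np.median(fc_best[order[:400]]))
    f2 = float(np.median(fc_best[order[:400]]))
    f3 = float(np.median(fc_best[order[:200]]))
    return ReferenceParams(
        marker_mean_pool=means[means >= cut],
        background_mean_pool=means[(means < cut) & (means > 0)],
        fold_changes=(f1, f2, f3),
    )


# ---------------------------------------------------------------------------
# hierarchical NB simulation
# ---------------------------------------------------------------------------

@dataclass
class HierSimConfig:
    n_cells: int = 1000
    n_genes: int = 10000
    clusters_per_scale: tuple[int, ...] = (2, 4, 8)
    # per-scale totals 400/400/200 over 2/4/8 clusters (1000 markers overall)
    markers_per_cluster: tuple[int, ...] = (200, 100, 25)
    dispersion: float = 0.1
    seed: int = 0

    @property
    def n_marker_genes(self) -> int:
        return sum(
            k * m for k, m in zip(self.clusters_per_scale, self.markers_per_cluster)
        )


@dataclass
class GroundTruth:
    labels_by_scale: list[np.ndarray]
    marker_map: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_trees: list[dict[str, str | None]] = field(default_factory=list)


def _nested_labels(n_cells: int, clusters_per_scale: tuple[int, ...]) -> list[np.ndarray]:
    """Balanced, perfectly nested labelings (each cluster splits evenly)."""
    out = []
    for k in clusters_per_scale:
        edges = np.linspace(0, n_cells, k + 1).astype(int)
        lab = np.zeros(n_cells, dtype=int)
        for c in range(k):
            lab[edges[c] : edges[c + 1]] = c
        out.append(lab)
    return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_hierarchy(
    cfg: HierSimConfig, params: ReferenceParams | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    rng = np.random.default_rng(cfg.seed)
    params = params or reference_params("builtin", seed=cfg.seed)
    labels = _nested_labels(cfg.n_cells, cfg.clusters_per_scale)
    n_markers = cfg.n_marker_genes
    n_bg = cfg.n_genes - n_markers
    if n_bg < 0:
        raise ValueError("n_genes smaller than the number of marker genes")
    marker_base = rng.choice(params.marker_mean_pool, size=n_markers, replace=True)
    bg_means = rng.choice(params.background_mean_pool, size=n_bg, replace=True)
    if np.any(marker_base <= 0) or np.any(bg_means < 0):
        raise ValueError("non-positive mean expression in parameter pools")

    counts = np.zeros((cfg.n_cells, cfg.n_genes), dtype=np.int64)
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    marker_map: dict[str, tuple[int, int]] = {}
    gi = 0
    for si, (k, m_per) in enumerate(zip(cfg.clusters_per_scale, cfg.markers_per_cluster)):
        fc = params.fold_changes[min(si, len(params.fold_changes) - 1)]
        for c in range(k):
            in_mask = labels[si] == c
            f = in_mask.mean()
            for _ in range(m_per):
                base = marker_base[gi]
                mu_out = base / (f * fc + (1 - f))
                mu_in = fc * mu_out
                mu = np.where(in_mask, mu_in, mu_out)
                counts[:, gi] = _nb_draw(rng, mu, cfg.dispersion)
                marker_map[gene_ids[gi]] = (si, c)
                gi += 1
    for j in range(n_bg):
        counts[:, gi + j] = _nb_draw(
            rng, np.full(cfg.n_cells, bg_means[j]), cfg.dispersion
        )
    cell_ids = [f"cell{i:04d}" for i in range(cfg.n_cells)]
    em = ExpressionMatrix(counts.astype(float), gene_ids, cell_ids, RAW_COUNTS)
    return em, GroundTruth(labels, marker_map)


# ---------------------------------------------------------------------------
# planted-tree simulation
# ---------------------------------------------------------------------------

# topology: per tree, node -> parent (None = root); names avoid "_" which is
# reserved for multi-subunit units
_DEFAULT_TOPOLOGIES: list[dict[str, str | None]] = [
    {"T0root": None, "T0mid": "T0root", "T0leaf": "T0mid"},   # 3-chain
    {"T1root": None, "T1a": "T1root", "T1b": "T1root"},       # 2 disjoint kids
    {"T2root": None, "T2mid": "T2root", "T2leaf": "T2mid"},   # 3-chain
    {"T3root": None, "T3a": "T3root", "T3b": "T3root"},
    {"T4root": None, "T4a": "T4root", "T4b": "T4root"},
]


@dataclass
class TreeSimConfig:
    n_cells: int = 1000
    n_genes: int = 100
    background_support: int = 500
    topologies: list[dict[str, str | None]] = field(
        default_factory=lambda: [dict(t) for t in _DEFAULT_TOPOLOGIES]
    )
    root_size: int = 180
    seed: int = 0


def simulate_trees(cfg: TreeSimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Binary expression matrix with planted laminar trees.

    The structured genes' supports realize the configured topologies on
    mutually disjoint root cell blocks (cells assigned via a seeded
    permutation); each remaining gene is a background gene expressed in
    ``background_support`` uniformly chosen cells, re-drawn per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_struct = sum(len(t) for t in cfg.topologies)
    if n_struct * 0 + cfg.root_size * len(cfg.topologies) > cfg.n_cells:
        raise ValueError("root blocks exceed the cell count")
    n_bg = cfg.n_genes - n_struct
    if n_bg < 0:
        raise ValueError("n_genes smaller than the structured gene count")
    perm = rng.permutation(cfg.n_cells)
    counts = np.zeros((cfg.n_cells, cfg.n_genes), dtype=np.int64)
    gene_ids: list[str] = []
    planted: list[dict[str, str | None]] = []
    col = 0
    offset = 0
    for topo in cfg.topologies:
        block = perm[offset : offset + cfg.root_size]
        offset += cfg.root_size
        supports = _realize_topology(topo, block)
        for gene, parent in topo.items():
            counts[supports[gene], col] = 1
            gene_ids.append(gene)
            col += 1
        planted.append(dict(topo))
    for j in range(n_bg):
        cells = rng.choice(cfg.n_cells, size=cfg.background_support, replace=False)
        counts[cells, col] = 1
        gene_ids.append(f"bg{j:03d}")
        col += 1
    cell_ids = [f"cell{i:04d}" for i in range(cfg.n_cells)]
    em = ExpressionMatrix(counts.astype(float), gene_ids, cell_ids, RAW_COUNTS)
    return em, GroundTruth(labels_by_scale=[], planted_trees=planted)


def _realize_topology(
    topo: dict[str, str | None], block: np.ndarray
) -> dict[str, np.ndarray]:
    """Assign nested/disjoint sub-blocks of ``block`` to the tree's nodes.

    The root takes the whole block; each node's children split (part of)
    their parent's cells into disjoint halves, leaving a margin so parent
    supports are strict supersets.
    """
    children: dict[str, list[str]] = {}
    root = None
    for node, parent in topo.items():
        if parent is None:
            root = node
        else:
            children.setdefault(parent, []).append(node)
    assert root is not None, "topology must have exactly one root"
    supports: dict[str, np.ndarray] = {root: block}

    def rec(node: str) -> None:
        kids = children.get(node, [])
        if not kids:
            return
        cells = supports[node]
        usable = cells[: int(len(cells) * 0.8)]  # margin => strict inclusion
        parts = np.array_split(usable, len(kids))
        for kid, part in zip(kids, parts):
            supports[kid] = part
            rec(kid)

    rec(root)
    return supports


def database_for_genes(genes: list[str], pathway: str = "sim") -> LRDatabase:
    """A ligand-side database stub: each gene becomes a ligand with a dummy
    cognate receptor (absent from the matrix), for ligand-tree detection."""
    return LRDatabase(
        [LRInteraction(g, f"R{g}", pathway) for g in genes]
    )


def tree_recovered(ts, planted: dict[str, str | None]) -> bool:
    """True iff some detected tree's entities and parent relation match the
    planted topology exactly."""
    genes = frozenset(planted.keys())
    for t in ts.trees:
        if t.entity_names() != genes:
            continue
        pm = t.parent_map()
        ok = all(pm.get(g, "<missing>") == planted[g] for g in planted)
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two labelings (permutation model)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings cover different cell sets")
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(a, b))


def match_scales(
    hier: HierarchicalClustering, truth: GroundTruth
) -> list[tuple[int, float]]:
    """For each ground-truth scale, the selected scale with maximal ARI
    (and that ARI)."""
    out = []
    for t_lab in truth.labels_by_scale:
        aris = [
            adjusted_rand_index(t_lab, hier.partitions[si])
            for si in range(hier.n_scales)
        ]
        best = int(np.argmax(aris))
        out.append((best, float(aris[best])))
    return out


def _cluster_mapping(truth_labels: np.ndarray, det_labels: np.ndarray) -> dict[int, int]:
    """Optimal truth-cluster -> detected-cluster map by overlap (Hungarian)."""
    kt = int(truth_labels.max()) + 1
    kd = int(det_labels.max()) + 1
    cont = np.zeros((kt, kd))
    for tc, dc in zip(truth_labels, det_labels):
        cont[tc, dc] += 1
    rows, cols = linear_sum_assignment(-cont)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def marker_recovery_rate(
    assignments: dict[str, MarkerAssignment],
    hier: HierarchicalClustering,
    truth: GroundTruth,
    top_n: int = 1000,
) -> tuple[float, dict[int, float]]:
    """Success rate of marker detection among the top-N lowest-p genes.

    Overall rate = (planted markers within the top N that are assigned to
    the matching (scale, cluster)) / min(N, number of planted markers);
    per-scale rates divide each scale's correct count by that scale's
    planted marker total.  Detected scales/clusters are matched to ground
    truth by maximal ARI and Hungarian cluster overlap.
    """
    ranked = sorted(assignments.values(), key=lambda a: (a.p_value, a.unit))
    if top_n > len(ranked):
        logger.warning("top_n=%d exceeds %d ranked genes; clamped", top_n, len(ranked))
        top_n = len(ranked)
    top = ranked[:top_n]
    scale_match = match_scales(hier, truth)
    cluster_maps = {
        ts: _cluster_mapping(truth.labels_by_scale[ts], hier.partitions[si])
        for ts, (si, _) in enumerate(scale_match)
    }
    n_correct = 0
    per_scale_correct: dict[int, int] = {}
    per_scale_total: dict[int, int] = {}
    for _, (s, _c) in truth.marker_map.items():
        per_scale_total[s] = per_scale_total.get(s, 0) + 1
    for a in top:
        tm = truth.marker_map.get(a.unit)
        if tm is None:
            continue
        ts, tc = tm
        si_expected, _ = scale_match[ts]
        correct = a.scale == si_expected and a.cluster == cluster_maps[ts].get(tc, -1)
        if correct:
            n_correct += 1
            per_scale_correct[ts] = per_scale_correct.get(ts, 0) + 1
    denom = min(top_n, len(truth.marker_map))
    overall = n_correct / denom if denom else 0.0
    per_scale = {
        s: per_scale_correct.get(s, 0) / per_scale_total[s] for s in per_scale_total
    }
    return overall, per_scale
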