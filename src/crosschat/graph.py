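"""KNN cell-graph construction.

Cells are embedded by PCA (on all genes, on ligand genes only, or on
receptor genes only), a directed k-nearest-neighbor graph is built under
cosine similarity, and the graph is symmetrized by union.  The resulting
weighted adjacency feeds the random-walk machinery in
:mod:`crosschat.markov`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, LOGNORM, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    cell_ids: list[str]
    vectors: np.ndarray
    provenance: str = "pca_all_genes"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if not np.all(np.isfinite(self.vectors)):
            raise ValidationError("non-finite embedding entries")


@dataclass
class CellGraph:
    """Symmetric weighted adjacency with zero diagonal over cells."""

    cell_ids: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        a = self.adjacency
        if (abs(a - a.T)).max() > 1e-10:
            raise ValidationError("adjacency not symmetric")
        if a.diagonal().any():
            raise ValidationError("nonzero diagonal")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def to_edge_list(self) -> list[tuple[str, str, float]]:
        coo = sp.triu(self.adjacency).tocoo()
        return [
            (self.cell_ids[i], self.cell_ids[j], float(w))
            for i, j, w in zip(coo.row, coo.col, coo.data)
        ]


def select_hvg(em: ExpressionMatrix, n_top: int = 2000) -> list[str]:
    """Top genes by variance of the log-normalized expression."""
    x = em.values
    if sp.issparse(x):
        mean = np.asarray(x.mean(axis=0)).ravel()
        mean_sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
        var = mean_sq - mean**2
    else:
        var = np.var(np.asarray(x, dtype=float), axis=0)
    order = np.argsort(-var, kind="stable")[: min(n_top, em.n_genes)]
    return [em.gene_ids[i] for i in sorted(order)]


def embed(
    em: ExpressionMatrix,
    gene_subset: Sequence[str] | str = "all",
    n_components: int = 50,
    scale: bool = True,
    *,
    n_hvg: int | None = 2000,
    provenance: str | None = None,
    seed: int = 0,
) -> Embedding:
    """PCA embedding of cells on a gene subset.

    ``gene_subset="all"`` uses every gene (optionally restricted to the
    ``n_hvg`` most variable ones); otherwise a list of gene symbols
    (multi-subunit unit names are expanded by the caller).  Genes absent
    from the matrix are skipped with a log message.
    """
    if em.layer_tag != LOGNORM:
        raise ValidationError("embed expects log-normalized expression")
    if gene_subset == "all":
        genes = select_hvg(em, n_hvg) if n_hvg else list(em.gene_ids)
        prov = provenance or "pca_all_genes"
    else:
        gidx = em.gene_index()
        genes = [g for g in gene_subset if g in gidx]
        missing = len(gene_subset) - len(genes)
        if missing:
            logger.info("embed: %d subset genes absent from matrix", missing)
        if not genes:
            raise ValidationError("gene subset has no overlap with matrix")
        prov = provenance or "pca_subset"
    gidx = em.gene_index()
    cols = [gidx[g] for g in genes]
    x = em.values[:, cols]
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, dtype=float)
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    max_comp = min(x.shape) - 1
    if n_components >= min(x.shape):
        n_components = max_comp
    if n_components < 2:
        raise ValidationError("need at least 2 PCA components")
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=seed)
    vecs = pca.fit_transform(x)
    return Embedding(list(em.cell_ids), vecs, prov)


def _cosine_normalize(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValidationError(
            f"all-zero embedding rows at indices {np.where(norms == 0)[0][:5]}"
        )
    return vectors / norms[:, None]


def knn_graph(emb: Embedding, k: int = 15) -> CellGraph:
    """Directed cosine k-NN, symmetrized by union (max of directed weights).

    Negative cosine weights are clipped to zero; if clipping or pruning
    disconnects the graph, components are reconnected by their single
    highest-cosine bridging edge (logged).
    """
    n = emb.vectors.shape[0]
    if k < 1 or k >= n:
        raise ValidationError(f"need 1 <= k < n; got k={k}, n={n}")
    unit = _cosine_normalize(emb.vectors)
    nn = NearestNeighbors(n_neighbors=k + 1, metric="cosine").fit(unit)
    dist, idx = nn.kneighbors(unit)
    rows, cols, vals = [], [], []
    for i in range(n):
        taken = 0
        for d, j in zip(dist[i], idx[i]):
            if j == i:
                continue
            if taken == k:
                break
            rows.append(i)
            cols.append(j)
            vals.append(max(0.0, 1.0 - d))
            taken += 1
    directed = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    adj = directed.maximum(directed.T)
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj = _ensure_connected(adj, unit)
    return CellGraph(list(emb.cell_ids), adj.tocsr())


def _ensure_connected(adj: sp.csr_matrix, unit: np.ndarray) -> sp.csr_matrix:
    """Repair a disconnected union graph.

    For every component pair, the single highest-cosine bridging edge is a
    candidate; a maximum-spanning tree over components (by bridge cosine)
    selects which bridges to add, so strongly related components join
    directly while unrelated ones connect only through the spanning
    structure.  Bridge weights are floored at a tiny positive value to keep
    the random walk irreducible.
    """
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp == 1:
        return adj
    logger.warning("graph has %d components; bridging on a max-spanning structure", n_comp)
    members = [np.where(labels == c)[0] for c in range(n_comp)]
    best_w = np.full((n_comp, n_comp), -np.inf)
    best_edge: dict[tuple[int, int], tuple[int, int]] = {}
    for a in range(n_comp):
        for b in range(a + 1, n_comp):
            sim = unit[members[a]] @ unit[members[b]].T
            i, j = np.unravel_index(np.argmax(sim), sim.shape)
            best_w[a, b] = best_w[b, a] = sim[i, j]
            best_edge[(a, b)] = (int(members[a][i]), int(members[b][j]))
    # Prim's algorithm, maximizing cosine
    adj = sp.lil_matrix(adj)
    in_tree = {0}
    while len(in_tree) < n_comp:
        cand = [
            (best_w[a, b], a, b)
            for a in in_tree
            for b in range(n_comp)
            if b not in in_tree
        ]
        w, a, b = max(cand)
        i, j = best_edge[(min(a, b), max(a, b))]
        adj[i, j] = adj[j, i] = max(float(w), 1e-6)
        in_tree.add(b)
    return adj.tocsr()
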