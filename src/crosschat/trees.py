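"""Local hierarchy detection over ligand/receptor supports.

The support of a unit is the set of cells whose (binarized) expression
exceeds a threshold.  Units whose supports are pairwise disjoint or nested
form a laminar family, i.e. a forest under inclusion.  Connecting units
whose supports are disjoint-or-inclusive and enumerating maximal cliques
(Bron-Kerbosch) finds exactly the maximal laminar subfamilies; each clique
is then decomposed into its rooted inclusion trees.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionMatrix, LRDatabase
from .specificity import unit_expression

logger = logging.getLogger(__name__)

DISJOINT = "disjoint"
INCLUSIVE = "inclusive"
OVERLAP = "overlap"
EQUAL = "equal"


# ---------------------------------------------------------------------------
# supports
# ---------------------------------------------------------------------------

@dataclass
class SupportMatrix:
    """Entity ids with their supporting cell-index sets."""

    entity_ids: list[str]
    supports: list[frozenset[int]]
    n_cells: int
    tau: float = 0.0


def binarize(
    em: ExpressionMatrix,
    units: list[str],
    tau: float = 0.0,
    min_cells: int = 10,
) -> SupportMatrix:
    """Support of a unit = cells with unit expression > tau; entities
    supported by fewer than ``min_cells`` cells are dropped."""
    ids: list[str] = []
    sups: list[frozenset[int]] = []
    for u in units:
        try:
            v = unit_expression(em, u)
        except KeyError:
            continue
        s = frozenset(np.where(v > tau)[0].tolist())
        if len(s) >= min_cells:
            ids.append(u)
            sups.append(s)
    return SupportMatrix(ids, sups, em.n_cells, tau)


def merge_equal_supports(sm: SupportMatrix) -> SupportMatrix:
    """Entities with identical supports collapse into one node whose id
    joins the member names with '='."""
    by_support: dict[frozenset[int], list[str]] = {}
    order: list[frozenset[int]] = []
    for eid, s in zip(sm.entity_ids, sm.supports):
        if s not in by_support:
            by_support[s] = []
            order.append(s)
        by_support[s].append(eid)
    ids = ["=".join(by_support[s]) for s in order]
    return SupportMatrix(ids, order, sm.n_cells, sm.tau)


def relation(s1: frozenset[int], s2: frozenset[int], eps: float = 0.0) -> str:
    """Relation of two nonempty supports under slack ``eps``.

    With m = min(|s1|, |s2|): disjoint iff the overlap is at most eps*m;
    inclusive iff the overlap covers at least (1-eps)*m of the smaller set
    and the sizes differ; equal iff identical; otherwise overlap.
    """
    if s1 == s2:
        return EQUAL
    m = min(len(s1), len(s2))
    inter = len(s1 & s2)
    if inter <= eps * m:
        return DISJOINT
    if inter >= (1.0 - eps) * m and len(s1) != len(s2):
        return INCLUSIVE
    return OVERLAP


def build_relation_graph(sm: SupportMatrix, eps: float = 0.0) -> nx.Graph:
    """Nodes = entity indices; edge iff supports are disjoint or inclusive."""
    g = nx.Graph()
    g.add_nodes_from(range(len(sm.entity_ids)))
    for i in range(len(sm.entity_ids)):
        for j in range(i + 1, len(sm.entity_ids)):
            rel = relation(sm.supports[i], sm.supports[j], eps)
            if rel in (DISJOINT, INCLUSIVE):
                g.add_edge(i, j, relation=rel)
    return g


def maximal_cliques(rg: nx.Graph) -> list[list[int]]:
    """All maximal cliques (Bron-Kerbosch with pivoting), canonically sorted."""
    cliques = [sorted(c) for c in nx.find_cliques(rg)]
    cliques.sort(key=lambda c: (len(c), c))
    return cliques


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    entity: str
    support: frozenset[int]
    children: list["TreeNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()


@dataclass
class SignalTree:
    root: TreeNode
    kind: str = "ligand"

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes())

    def entity_names(self) -> frozenset[str]:
        names: set[str] = set()
        for node in self.nodes():
            names.update(node.entity.split("="))
        return frozenset(names)

    def parent_map(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {self.root.entity: None}

        def rec(node: TreeNode):
            for ch in node.children:
                out[ch.entity] = node.entity
                rec(ch)

        rec(self.root)
        return out

    def to_dict(self) -> dict:
        def rec(node: TreeNode) -> dict:
            return {
                "entity": node.entity,
                "support_size": len(node.support),
                "children": [rec(c) for c in sorted(node.children, key=lambda x: x.entity)],
            }

        return rec(self.root)

    def to_newick(self) -> str:
        def esc(name: str) -> str:
            return name.replace(" ", "_").replace("(", "").replace(")", "")

        def rec(node: TreeNode) -> str:
            if not node.children:
                return esc(node.entity)
            inner = ",".join(rec(c) for c in sorted(node.children, key=lambda x: x.entity))
            return f"({inner}){esc(node.entity)}"

        return rec(self.root) + ";"


@dataclass
class TreeSet:
    trees: list[SignalTree]
    kind: str = "ligand"
    tau: float = 0.0
    eps: float = 0.0
    min_cells: int = 10
    min_nodes: int = 2

    def __len__(self) -> int:
        return len(self.trees)


def forest_from_clique(
    entity_ids: list[str],
    supports: list[frozenset[int]],
    min_nodes: int = 2,
    eps: float = 0.0,
    kind: str = "ligand",
) -> list[SignalTree]:
    """Decompose a laminar family into rooted inclusion trees.

    Parent of a node = its smallest strict (eps-inclusive) superset within
    the family.  Connected components of the resulting forest are emitted as
    separate trees; components smaller than ``min_nodes`` are filtered.
    With eps > 0 laminarity may break transitively; offending siblings are
    detached into their own components with a warning.
    """
    k = len(entity_ids)
    order = sorted(range(k), key=lambda i: (-len(supports[i]), entity_ids[i]))
    parent = [-1] * k
    for i in range(k):
        best = -1
        for j in range(k):
            if j == i or len(supports[j]) <= len(supports[i]):
                continue
            if relation(supports[i], supports[j], eps) == INCLUSIVE:
                if best < 0 or len(supports[j]) < len(supports[best]) or (
                    len(supports[j]) == len(supports[best]) and j < best
                ):
                    best = j
        parent[i] = best
    nodes = [TreeNode(entity_ids[i], supports[i]) for i in range(k)]
    roots: list[int] = []
    for i in order:
        if parent[i] < 0:
            roots.append(i)
        else:
            nodes[parent[i]].children.append(nodes[i])
    # sibling sanity check (exact at eps=0; may fail for eps>0)
    for i in range(k):
        kids = [j for j in range(k) if parent[j] == i]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                j = kids[b]
                if parent[j] != i:
                    continue  # already detached
                rel = relation(supports[kids[a]], supports[j], eps)
                if rel != DISJOINT:
                    warnings.warn(
                        f"siblings {entity_ids[kids[a]]}, {entity_ids[j]} are "
                        f"{rel}; detaching the smaller one"
                    )
                    nodes[i].children.remove(nodes[j])
                    parent[j] = -1
                    roots.append(j)
    trees = [SignalTree(nodes[r], kind) for r in roots]
    return [t for t in trees if t.n_nodes >= min_nodes]


def detect_trees(
    em: ExpressionMatrix,
    db: LRDatabase,
    kind: str = "ligand",
    tau: float = 0.0,
    eps: float = 0.0,
    min_cells: int = 10,
    min_nodes: int = 2,
) -> TreeSet:
    """End-to-end tree detection for ligand units, receptor units, or
    per-DB-pair ligand/receptor support unions."""
    if kind not in ("ligand", "receptor", "lr_union"):
        raise ValueError(f"unknown kind {kind!r}")
    if kind == "lr_union":
        sm = _union_supports(em, db, tau, min_cells)
    else:
        units = db.ligand_units if kind == "ligand" else db.receptor_units
        sm = binarize(em, units, tau, min_cells)
    return trees_from_supports(sm, kind=kind, eps=eps, min_nodes=min_nodes)


def trees_from_supports(
    sm: SupportMatrix, kind: str = "ligand", eps: float = 0.0, min_nodes: int = 2
) -> TreeSet:
    sm = merge_equal_supports(sm)
    rg = build_relation_graph(sm, eps)
    trees: list[SignalTree] = []
    for clique in maximal_cliques(rg):
        if len(clique) < min_nodes:
            continue
        trees.extend(
            forest_from_clique(
                [sm.entity_ids[i] for i in clique],
                [sm.supports[i] for i in clique],
                min_nodes=min_nodes,
                eps=eps,
                kind=kind,
            )
        )
    # identical trees can arise from overlapping cliques; deduplicate
    seen: set[str] = set()
    unique: list[SignalTree] = []
    for t in trees:
        key = t.to_newick()
        if key not in seen:
            seen.add(key)
            unique.append(t)
    return TreeSet(unique, kind, sm.tau, eps, min_cells=0, min_nodes=min_nodes)


def _union_supports(
    em: ExpressionMatrix, db: LRDatabase, tau: float, min_cells: int
) -> SupportMatrix:
    lig_sm = binarize(em, db.ligand_units, tau, min_cells=0)
    rec_sm = binarize(em, db.receptor_units, tau, min_cells=0)
    lig = dict(zip(lig_sm.entity_ids, lig_sm.supports))
    rec = dict(zip(rec_sm.entity_ids, rec_sm.supports))
    ids, sups = [], []
    for it in db.interactions:
        if it.ligand not in lig or it.receptor not in rec:
            continue
        s = lig[it.ligand] | rec[it.receptor]
        if len(s) >= min_cells:
            ids.append(it.name)
            sups.append(s)
    return SupportMatrix(ids, sups, em.n_cells, tau)


# ---------------------------------------------------------------------------
# downstream views
# ---------------------------------------------------------------------------

def frequency_ranking(ts: TreeSet) -> list[tuple[str, int]]:
    """Number of trees containing each entity, descending (ties alphabetical)."""
    counts: dict[str, int] = {}
    for t in ts.trees:
        for name in t.entity_names():
            counts[name] = counts.get(name, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def pair_trees(
    ligand_ts: TreeSet, receptor_ts: TreeSet, db: LRDatabase
) -> list[tuple[int, int, list[str]]]:
    """(ligand-tree index, receptor-tree index, matched interactions) for all
    tree pairs sharing at least one database interaction."""
    out = []
    for i, lt in enumerate(ligand_ts.trees):
        lnames = lt.entity_names()
        for j, rt in enumerate(receptor_ts.trees):
            rnames = rt.entity_names()
            matched = [
                it.name
                for it in db.interactions
                if it.ligand in lnames and it.receptor in rnames
            ]
            if matched:
                out.append((i, j, matched))
    return out
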