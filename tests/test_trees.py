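import itertools

import numpy as np
import pytest

from crosschat.io import ExpressionMatrix, RAW_COUNTS
from crosschat.simulate import TreeSimConfig, database_for_genes, simulate_trees, tree_recovered
from crosschat.trees import (
    DISJOINT,
    EQUAL,
    INCLUSIVE,
    OVERLAP,
    SupportMatrix,
    binarize,
    build_relation_graph,
    detect_trees,
    forest_from_clique,
    frequency_ranking,
    maximal_cliques,
    merge_equal_supports,
    pair_trees,
    relation,
    trees_from_supports,
)


def _fs(*items):
    return frozenset(items)


class TestRelation:
    def test_basic_cases_eps_zero(self):
        assert relation(_fs(1, 2, 3), _fs(2, 3)) == INCLUSIVE
        assert relation(_fs(1, 2), _fs(3, 4)) == DISJOINT
        assert relation(_fs(1, 2), _fs(2, 3)) == OVERLAP
        assert relation(_fs(1, 2), _fs(1, 2)) == EQUAL

    def test_eps_tolerance(self):
        s1 = _fs(*range(10))
        s2 = _fs(*range(9), 100)  # 9/10 of s2 inside s1
        assert relation(s1, s2, eps=0.0) == OVERLAP
        assert relation(s1, s2, eps=0.15) == OVERLAP  # same size: cannot be inclusive
        s3 = _fs(*range(9), 100, 101)
        assert relation(s1, s3, eps=0.15) == INCLUSIVE


class TestBinarize:
    def test_tau_zero_support_is_nonzero_cells(self, toy_counts):
        sm = binarize(toy_counts, ["Liga", "Ligc"], tau=0.0, min_cells=1)
        assert sm.supports[sm.entity_ids.index("Liga")] == _fs(0, 1, 3, 5)
        assert sm.supports[sm.entity_ids.index("Ligc")] == _fs(0, 2, 3, 4, 5)

    def test_raising_tau_shrinks_supports(self, toy_counts):
        units = ["Liga", "Recb", "Ligc"]
        prev = binarize(toy_counts, units, tau=0.0, min_cells=0)
        for tau in (1.0, 4.0, 8.0):
            cur = binarize(toy_counts, units, tau=tau, min_cells=0)
            for u in cur.entity_ids:
                assert cur.supports[cur.entity_ids.index(u)] <= prev.supports[
                    prev.entity_ids.index(u)
                ]
            prev = cur

    def test_min_cells_filter(self, toy_counts):
        sm = binarize(toy_counts, ["Liga"], tau=5.0, min_cells=2)
        assert sm.entity_ids == []


class TestCliques:
    def test_triangle_and_path(self):
        import networkx as nx

        tri = nx.complete_graph(3)
        assert maximal_cliques(tri) == [[0, 1, 2]]
        path = nx.path_graph(3)
        assert maximal_cliques(path) == [[0, 1], [1, 2]]

    def test_random_graphs_vs_bruteforce(self, rng):
        import networkx as nx

        for _ in range(50):
            n = int(rng.integers(2, 13))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            got = {frozenset(c) for c in maximal_cliques(g)}
            assert got == _brute_cliques(g)


def _brute_cliques(g):
    nodes = list(g.nodes)
    n = len(nodes)
    cliques = set()
    for r in range(1, n + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.add(frozenset(sub))
    return {c for c in cliques if not any(c < d for d in cliques)}


class TestForest:
    def test_nested_family_single_tree(self):
        fam = {
            "A": _fs(*range(1, 7)),
            "B": _fs(1, 2),
            "C": _fs(3, 4),
            "D": _fs(1),
        }
        trees = forest_from_clique(list(fam), list(fam.values()), min_nodes=2)
        assert len(trees) == 1
        t = trees[0]
        assert t.root.entity == "A"
        pm = t.parent_map()
        assert pm == {"A": None, "B": "A", "C": "A", "D": "B"}

    def test_mutually_disjoint_all_filtered(self):
        fam = {c: _fs(i * 2, i * 2 + 1) for i, c in enumerate("abcd")}
        trees = forest_from_clique(list(fam), list(fam.values()), min_nodes=2)
        assert trees == []

    def test_sibling_supports_pairwise_disjoint(self, rng):
        # random laminar families: children partition a subset of the parent
        for _ in range(20):
            fam = _random_laminar_family(rng)
            trees = forest_from_clique(list(fam), list(fam.values()), min_nodes=1)
            for t in trees:
                for node in t.nodes():
                    for a, b in itertools.combinations(node.children, 2):
                        assert not (a.support & b.support)
                    for ch in node.children:
                        assert ch.support < node.support


def _random_laminar_family(rng, n_cells=30, max_depth=3):
    fam = {}
    counter = itertools.count()

    def split(cells, depth, parent_frac=0.8):
        if depth == 0 or len(cells) < 4:
            return
        take = cells[: int(len(cells) * parent_frac)]
        k = int(rng.integers(1, 3))
        parts = np.array_split(take, k)
        for p in parts:
            if len(p) >= 2:
                name = f"n{next(counter)}"
                fam[name] = frozenset(p.tolist())
                split(p, depth - 1)

    cells = rng.permutation(n_cells)
    root = frozenset(cells[:25].tolist())
    fam["root"] = root
    split(cells[:25], max_depth)
    return fam


class TestLaminarOracle:
    def test_cliques_equal_maximal_laminar_subfamilies(self, rng):
        """Bron-Kerbosch cliques of the relation graph coincide with maximal
        laminar subfamilies found by exhaustive subset enumeration."""
        for _ in range(30):
            n_ent = int(rng.integers(3, 9))
            n_cells = int(rng.integers(5, 20))
            sm = _random_support_matrix(rng, n_ent, n_cells)
            sm = merge_equal_supports(sm)
            rg = build_relation_graph(sm, 0.0)
            got = {
                frozenset(sm.entity_ids[i] for i in c) for c in maximal_cliques(rg)
            }
            assert got == _brute_laminar(sm)


def _random_support_matrix(rng, n_ent, n_cells):
    ids, sups = [], []
    for i in range(n_ent):
        size = int(rng.integers(1, n_cells + 1))
        sups.append(frozenset(rng.choice(n_cells, size=size, replace=False).tolist()))
        ids.append(f"e{i}")
    return SupportMatrix(ids, sups, n_cells)


def _brute_laminar(sm):
    """Maximal subsets of entities that are pairwise disjoint-or-nested."""
    ids = sm.entity_ids
    sup = dict(zip(ids, sm.supports))

    def ok(a, b):
        sa, sb = sup[a], sup[b]
        return not (sa & sb) or sa < sb or sb < sa

    laminar = set()
    for r in range(1, len(ids) + 1):
        for sub in itertools.combinations(ids, r):
            if all(ok(a, b) for a, b in itertools.combinations(sub, 2)):
                laminar.add(frozenset(sub))
    return {s for s in laminar if not any(s < t for t in laminar)}


class TestDetectTrees:
    def test_broad_root_toy(self):
        # Igf2-like broad ligand with nested and disjoint descendants
        counts = np.zeros((12, 4))
        counts[:10, 0] = 1  # broad root
        counts[:4, 1] = 1   # child 1
        counts[5:9, 2] = 1  # child 2 (disjoint from child 1)
        counts[:2, 3] = 1   # grandchild inside child 1
        em = ExpressionMatrix(
            counts, ["Igf2", "Bmp5", "Cdh1", "Ocln"], [f"c{i}" for i in range(12)], RAW_COUNTS
        )
        db = database_for_genes(["Igf2", "Bmp5", "Cdh1", "Ocln"])
        ts = detect_trees(em, db, kind="ligand", min_cells=1)
        assert len(ts) == 1
        assert ts.trees[0].root.entity == "Igf2"
        assert ts.trees[0].parent_map()["Ocln"] == "Bmp5"

    def test_lr_union_support_is_union(self, toy_counts, toy_db):
        from crosschat.trees import _union_supports

        sm = _union_supports(toy_counts, toy_db, tau=0.0, min_cells=1)
        i = sm.entity_ids.index("Liga-Recb")
        lig = {0, 1, 3, 5}
        rec = {1, 2, 3, 5}
        assert sm.supports[i] == frozenset(lig | rec)

    def test_tree_count_nonincreasing_in_tau(self):
        em, _ = simulate_trees(TreeSimConfig(seed=3))
        db = database_for_genes(list(em.gene_ids))
        counts = []
        for tau in (0.0, 0.5, 1.5):
            ts = detect_trees(em, db, kind="ligand", tau=tau)
            counts.append(len(ts))
        assert counts[0] >= counts[1] >= counts[2]

    def test_output_invariant_under_cell_relabeling(self, rng):
        em, truth = simulate_trees(TreeSimConfig(seed=5))
        db = database_for_genes(list(em.gene_ids))
        ts1 = detect_trees(em, db, kind="ligand")
        perm = rng.permutation(em.n_cells)
        em2 = ExpressionMatrix(
            em.dense()[perm], list(em.gene_ids),
            [em.cell_ids[i] for i in perm], RAW_COUNTS,
        )
        ts2 = detect_trees(em2, db, kind="ligand")
        assert sorted(t.to_newick() for t in ts1.trees) == sorted(
            t.to_newick() for t in ts2.trees
        )


class TestDownstream:
    def test_frequency_counts(self):
        em, _ = simulate_trees(TreeSimConfig(seed=1))
        db = database_for_genes(list(em.gene_ids))
        ts = detect_trees(em, db, kind="ligand")
        freq = dict(frequency_ranking(ts))
        n_with_root = sum(1 for t in ts.trees if "T0root" in t.entity_names())
        assert freq["T0root"] == n_with_root
        assert "bg000" not in freq  # background genes join no tree

    def test_pair_trees_bruteforce(self, rng):
        em, _ = simulate_trees(TreeSimConfig(seed=2))
        genes = list(em.gene_ids)
        lig_db = database_for_genes(genes)
        lts = detect_trees(em, lig_db, kind="ligand")
        # receptor trees: reuse the same supports under receptor names
        from crosschat.io import LRDatabase, LRInteraction

        cross = LRDatabase(
            [LRInteraction("T0root", "T1root", "pw"), LRInteraction("T0mid", "T9x", "pw")]
        )
        rts = detect_trees(em, LRDatabase(
            [LRInteraction(f"L{g}", g, "pw") for g in genes]
        ), kind="receptor")
        got = pair_trees(lts, rts, cross)
        expected = []
        for i, lt in enumerate(lts.trees):
            for j, rt in enumerate(rts.trees):
                matched = [
                    it.name for it in cross.interactions
                    if it.ligand in lt.entity_names() and it.receptor in rt.entity_names()
                ]
                if matched:
                    expected.append((i, j, matched))
        assert got == expected

    def test_newick_round_trip_parses(self):
        em, _ = simulate_trees(TreeSimConfig(seed=0))
        db = database_for_genes(list(em.gene_ids))
        ts = detect_trees(em, db, kind="ligand")
        import dendropy

        for t in ts.trees:
            parsed = dendropy.Tree.get(data=t.to_newick(), schema="newick")
            n_labeled = sum(
                1 for nd in parsed if nd.taxon is not None or nd.label is not None
            )
            assert n_labeled == t.n_nodes


class TestPlantedTrees:
    def test_planted_supports_are_laminar(self):
        em, truth = simulate_trees(TreeSimConfig(seed=11))
        sm = binarize(em, [g for t in truth.planted_trees for g in t], min_cells=1)
        for i, j in itertools.combinations(range(len(sm.entity_ids)), 2):
            # within any one planted tree the relation must be disjoint/inclusive
            ti = sm.entity_ids[i][:2]
            tj = sm.entity_ids[j][:2]
            if ti == tj:
                assert relation(sm.supports[i], sm.supports[j]) in (DISJOINT, INCLUSIVE)

    def test_background_support_size(self):
        em, _ = simulate_trees(TreeSimConfig(seed=4))
        sm = binarize(em, ["bg000", "bg042"], min_cells=1)
        assert all(len(s) == 500 for s in sm.supports)

    def test_all_five_trees_detected_single_trial(self):
        em, truth = simulate_trees(TreeSimConfig(seed=123))
        db = database_for_genes(list(em.gene_ids))
        ts = detect_trees(em, db, kind="ligand")
        assert all(tree_recovered(ts, p) for p in truth.planted_trees)
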