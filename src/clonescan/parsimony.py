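"""Fitch parsimony tree lengths: exact for small taxon sets, heuristic otherwise.

The unrooted binary topology is held as an adjacency map (leaves 0..n-1 of
degree 1, internal nodes of degree 3); Fitch's small-parsimony count is
evaluated on an arbitrary rooting, with a missing residue at a leaf standing
for the universal state set.  The exact search enumerates all (2n-5)!!
unrooted topologies (refused above 9 taxa); the heuristic uses random-addition
starting trees improved by nearest-neighbour-interchange hill climbing.
"""

from __future__ import annotations

import numpy as np

from .seqdata import LocusAlignment
from .trees import Tree

__all__ = ["fitch_length", "mp_length_exact", "mp_length_heuristic", "MAX_EXACT_TAXA"]

MAX_EXACT_TAXA = 9

# state bitmasks: A,C,G,T -> 1,2,4,8; missing -> all states
_MASK_LUT = np.array([1, 2, 4, 8, 15], dtype=np.uint8)


def _leaf_masks(aln: LocusAlignment, columns: np.ndarray | None = None) -> np.ndarray:
    codes = aln.codes()
    if columns is not None:
        codes = codes[:, columns]
    return _MASK_LUT[codes]


def _fitch_score(adj: dict[int, list[int]], masks: np.ndarray) -> int:
    """Fitch count summed over columns, rooting on the edge at leaf 0."""
    n_leaves = masks.shape[0]
    if n_leaves == 1:
        return 0
    if n_leaves == 2:
        inter = masks[0] & masks[1]
        return int((inter == 0).sum())
    anchor = min(k for k in adj if k < n_leaves)  # root on this leaf's edge
    root = adj[anchor][0]
    order: list[tuple[int, int]] = []
    stack = [(root, anchor)]
    while stack:
        node, parent = stack.pop()
        order.append((node, parent))
        if node >= n_leaves:
            for nb in adj[node]:
                if nb != parent:
                    stack.append((nb, node))
    node_mask: dict[int, np.ndarray] = {}
    cost = 0
    for node, parent in reversed(order):
        if node < n_leaves:
            node_mask[node] = masks[node]
            continue
        m = None
        for nb in adj[node]:
            if nb == parent:
                continue
            c = node_mask.pop(nb)
            if m is None:
                m = c
                continue
            inter = m & c
            zero = inter == 0
            cost += int(zero.sum())
            m = np.where(zero, m | c, inter)
        node_mask[node] = m
    inter = node_mask[root] & masks[anchor]
    cost += int((inter == 0).sum())
    return cost


def _tree_to_adj(tree: Tree, taxa: list[str]) -> dict[int, list[int]]:
    """Convert a Tree to the adjacency form, suppressing degree-2 nodes."""
    index = {t: i for i, t in enumerate(taxa)}
    names = tree.leaf_names()
    if set(names) != set(taxa) or len(names) != len(taxa):
        raise ValueError("tree leaves do not match alignment taxa")
    adj: dict[int, list[int]] = {}
    next_id = [len(taxa)]

    def add_edge(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def rec(node):
        if node.is_leaf:
            return index[node.label]
        nid = next_id[0]
        next_id[0] += 1
        adj.setdefault(nid, [])
        for c in node.children:
            add_edge(nid, rec(c))
        return nid

    rid = rec(tree.root)
    # suppress degree-2 nodes (e.g. a rooted-binary root)
    for node in [k for k in adj if len(adj[k]) == 2]:
        a, b = adj.pop(node)
        adj[a] = [x for x in adj[a] if x != node] + [b]
        adj[b] = [x for x in adj[b] if x != node] + [a]
    return adj


def fitch_length(aln: LocusAlignment, tree: Tree) -> int:
    """Fitch small-parsimony length of ``tree`` on ``aln`` (all columns)."""
    adj = _tree_to_adj(tree, aln.taxa)
    return _fitch_score(adj, _leaf_masks(aln))


def _star3(next_internal: int) -> dict[int, list[int]]:
    v = next_internal
    return {0: [v], 1: [v], 2: [v], v: [0, 1, 2]}


def _edges(adj) -> list[tuple[int, int]]:
    return [(a, b) for a in adj for b in adj[a] if a < b]


def _insert_leaf(adj, leaf, u, v, new_internal):
    adj[u] = [x if x != v else new_internal for x in adj[u]]
    adj[v] = [x if x != u else new_internal for x in adj[v]]
    adj[new_internal] = [u, v, leaf]
    adj[leaf] = [new_internal]


def _remove_leaf(adj, leaf, u, v, internal):
    del adj[leaf]
    del adj[internal]
    adj[u] = [x if x != internal else v for x in adj[u]]
    adj[v] = [x if x != internal else u for x in adj[v]]


def _enumerate_scores(masks: np.ndarray):
    """Yield the Fitch score of every unrooted binary topology."""
    n = masks.shape[0]
    adj = _star3(n)

    def rec(k, next_internal):
        if k == n:
            yield _fitch_score(adj, masks)
            return
        for u, v in _edges(adj):
            _insert_leaf(adj, k, u, v, next_internal)
            yield from rec(k + 1, next_internal + 1)
            _remove_leaf(adj, k, u, v, next_internal)

    yield from rec(3, n + 1)


def mp_length_exact(aln: LocusAlignment, columns: np.ndarray | None = None) -> int:
    """Minimum Fitch length over all unrooted binary topologies (n <= 9)."""
    n = aln.n_taxa
    if n > MAX_EXACT_TAXA:
        raise ValueError(
            f"exact search enumerates all topologies and is limited to "
            f"{MAX_EXACT_TAXA} taxa (got {n}); use mp_length_heuristic"
        )
    masks = _leaf_masks(aln, columns)
    if n <= 3:
        # single unrooted topology
        if n < 3:
            return _fitch_score({0: [1], 1: [0]} if n == 2 else {}, masks)
        return _fitch_score(_star3(3), masks)
    return min(_enumerate_scores(masks))


def _random_addition_tree(masks: np.ndarray, rng: np.random.Generator):
    n = masks.shape[0]
    order = list(rng.permutation(n))
    # star over the first three taxa in random order, then greedy insertion
    a, b, c = order[:3]
    adj = {a: [n], b: [n], c: [n], n: [a, b, c]}
    next_internal = n + 1
    for leaf in order[3:]:
        best = None
        edges = _edges(adj)
        rng.shuffle(edges)
        for u, v in edges:
            _insert_leaf(adj, leaf, u, v, next_internal)
            s = _fitch_score(adj, masks)
            _remove_leaf(adj, leaf, u, v, next_internal)
            if best is None or s < best[0]:
                best = (s, u, v)
        _, u, v = best
        _insert_leaf(adj, leaf, u, v, next_internal)
        next_internal += 1
    return adj


def _internal_edges(adj, n_leaves):
    return [
        (a, b) for a, b in _edges(adj) if a >= n_leaves and b >= n_leaves
    ]


def _nni_apply(adj, u, v, x, y):
    """Swap subtree x (neighbour of u) with subtree y (neighbour of v)."""
    adj[u] = [z if z != x else y for z in adj[u]]
    adj[v] = [z if z != y else x for z in adj[v]]
    adj[x] = [z if z != u else v for z in adj[x]]
    adj[y] = [z if z != v else u for z in adj[y]]


def _nni_hill_climb(adj, masks, rng):
    """Steepest-descent NNI: each sweep applies the best improving move;
    ties among equally good moves break first-found in a seeded shuffle."""
    n_leaves = masks.shape[0]
    score = _fitch_score(adj, masks)
    while True:
        best = None
        edges = _internal_edges(adj, n_leaves)
        rng.shuffle(edges)
        for u, v in edges:
            us = [x for x in adj[u] if x != v]
            vs = [y for y in adj[v] if y != u]
            moves = [(us[0], vs[0]), (us[0], vs[1])]
            rng.shuffle(moves)
            for x, y in moves:
                _nni_apply(adj, u, v, x, y)
                s = _fitch_score(adj, masks)
                _nni_apply(adj, u, v, y, x)  # undo (swap back)
                if s < score and (best is None or s < best[0]):
                    best = (s, u, v, x, y)
        if best is None:
            return score
        score, u, v, x, y = best
        _nni_apply(adj, u, v, x, y)


def mp_length_heuristic(
    aln: LocusAlignment,
    n_starts: int = 10,
    seed: int | None = None,
    columns: np.ndarray | None = None,
) -> int:
    """Best Fitch length over ``n_starts`` random-addition + NNI searches.

    Deterministic given ``seed``; always an upper bound on the exact length.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if aln.n_taxa < 4:
        return mp_length_exact(aln, columns)
    masks = _leaf_masks(aln, columns)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_starts):
        adj = _random_addition_tree(masks, rng)
        s = _nni_hill_climb(adj, masks, rng)
        if best is None or s < best:
            best = s
    return best


def _mp_length_auto(
    aln: LocusAlignment,
    rng: np.random.Generator,
    n_starts: int = 4,
    columns: np.ndarray | None = None,
) -> int:
    """Exact below the enumeration limit, heuristic otherwise (internal)."""
    if aln.n_taxa <= 7:
        return mp_length_exact(aln, columns)
    return mp_length_heuristic(
        aln, n_starts=n_starts, seed=int(rng.integers(2**31)), columns=columns
    )
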