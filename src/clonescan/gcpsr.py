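"""Genealogical concordance species recognition (GCPSR) and the incremental
Phi boundary-expansion procedure, with neighbor-joining + bootstrap plumbing
for producing supported gene trees.

A clade (bipartition of the shared strain set) is recognised as an
evolutionary lineage when it is supported at or above ``tau`` in at least two
gene trees and no gene tree contains an incompatible bipartition supported at
or above ``tau``.  The species partition is the finest partition of the
strains in which no recognised split separates two members of a block.

The boundary-expansion procedure starts from a non-recombining seed set
(Phi p > alpha), then adds candidate strains -- by whole groups or one at a
time, nearest to the seed first -- re-running the Phi test after each
addition; the addition that first drives p below alpha marks a group that
recombines with the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix, SaturationError, k3st_distance, p_distance
from .recombtests import TestResult, phi_test
from .seqdata import LocusAlignment
from .trees import Tree, TreeNode

__all__ = [
    "CladeSet",
    "ExpansionStep",
    "ExpansionTrajectory",
    "nj_tree",
    "bootstrap_support",
    "gcpsr_recognize",
    "phi_boundary_expand",
    "find_nonrecombining_seed",
]


# ----------------------------------------------------------------------
# neighbor joining
# ----------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix, collapse_tol: float = 1e-10) -> Tree:
    """Neighbor-joining tree (Saitou-Nei, Studier-Keppler selection).

    Returns an unrooted topology with branch lengths; negative lengths are
    clamped to zero with a warning.  Internal edges of length <=
    ``collapse_tol`` are collapsed into polytomies: NJ otherwise resolves
    ties among identical sequences arbitrarily but *deterministically*,
    which would fabricate fully supported clades under bootstrapping.
    """
    if dm.n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if not np.allclose(dm.d, dm.d.T, atol=1e-12):
        raise ValueError("asymmetric distance matrix")
    D = dm.d.astype(float).copy()
    nodes = [TreeNode(label=t) for t in dm.taxa]
    active = list(range(dm.n))
    clamped = False

    def set_len(node, value):
        nonlocal clamped
        if value < 0:
            clamped = True
            value = 0.0
        node.length = float(value)

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        S = sub.sum(axis=1)
        Q = (m - 2) * sub - S[:, None] - S[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (S[i] - S[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        set_len(nodes[active[i]], li)
        set_len(nodes[active[j]], lj)
        parent.add(nodes[active[i]])
        parent.add(nodes[active[j]])
        # distances from the new node
        newd = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        for t_pos, t in enumerate(active):
            D[k, t] = D[t, k] = newd[t_pos]
        D[k, k] = 0.0
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [k]
    # join the last three at a trifurcating root
    a, b, c = active
    root = TreeNode()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        set_len(node, ln)
        root.add(node)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0")
    tree = Tree(root)
    if collapse_tol is not None:
        _collapse_short_edges(tree, collapse_tol)
    return tree


def _collapse_short_edges(tree: Tree, tol: float) -> None:
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node is tree.root or node.is_leaf:
                continue
            if (node.length or 0.0) <= tol:
                parent = node.parent
                k = parent.children.index(node)
                parent.children.pop(k)
                for c in node.children:
                    c.parent = parent
                    parent.children.append(c)
                changed = True
                break


def bootstrap_support(
    aln: LocusAlignment,
    n_boot: int = 500,
    seed: int | None = None,
    model: str = "p",
) -> Tree:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal edge = fraction of replicate NJ trees (columns
    resampled with replacement) containing the same bipartition.  Seeded and
    deterministic.
    """
    if aln.n_taxa < 4:
        raise ValueError("bootstrap supports need >= 4 taxa")
    dist = p_distance if model == "p" else k3st_distance
    base = nj_tree(dist(aln))
    counts: dict[frozenset, int] = {k: 0 for k in base.bipartitions()}
    rng = np.random.default_rng(seed)
    L = aln.length
    done = 0
    attempts = 0
    while done < n_boot and attempts < 10 * n_boot:
        attempts += 1
        cols = rng.integers(0, L, size=L)
        rows = ["".join(r[c] for c in cols) for r in aln.rows]
        rep = LocusAlignment(aln.locus_name, list(aln.taxa), rows)
        try:
            bp = nj_tree(dist(rep)).bipartitions()
        except (SaturationError, ValueError):
            continue  # replicate with an undefined pair; redraw
        done += 1
        for k in counts:
            if k in bp:
                counts[k] += 1
    if done < n_boot:
        warnings.warn(f"only {done}/{n_boot} bootstrap replicates usable")
    # attach supports to the base tree
    taxa = set(aln.taxa)
    ref = min(taxa)
    below: dict[int, set] = {}
    for node in base.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label}
            continue
        s = set()
        for c in node.children:
            s |= below[id(c)]
        below[id(node)] = s
        if node is base.root:
            continue
        side = s if ref not in s else taxa - s
        key = frozenset(side)
        if key in counts and done > 0:
            node.support = counts[key] / done
    return base


# ----------------------------------------------------------------------
# GCPSR
# ----------------------------------------------------------------------

@dataclass
class CladeSet:
    """Bipartitions with supports extracted from one gene tree."""

    tree_id: str
    taxa: frozenset
    clades: dict[frozenset, float]

    @classmethod
    def from_tree(cls, tree: Tree, tree_id: str = "") -> "CladeSet":
        bp = tree.bipartitions()
        return cls(
            tree_id or "tree",
            frozenset(tree.leaf_names()),
            {k: (v if v is not None else 0.0) for k, v in bp.items()},
        )


def _splits_incompatible(a: frozenset, b: frozenset, taxa: frozenset) -> bool:
    ca, cb = taxa - a, taxa - b
    return bool(a & b) and bool(a & cb) and bool(ca & b) and bool(ca & cb)


def gcpsr_recognize(
    clade_sets: list, tau: float = 0.95
) -> tuple[dict[frozenset, dict], list[set]]:
    """Recognise concordant clades and derive the species partition.

    A bipartition is recognised iff supported at >= ``tau`` in at least two
    clade sets and no clade set holds an incompatible bipartition at
    >= ``tau``.  Returns ``(recognized, partition)`` where ``recognized``
    maps each recognised split side to the per-tree supports, and
    ``partition`` is the list of strain blocks never separated by a
    recognised split (strains separated from everything end up as
    singletons).
    """
    sets = [
        cs if isinstance(cs, CladeSet) else CladeSet.from_tree(cs, f"tree{i+1}")
        for i, cs in enumerate(clade_sets)
    ]
    if len(sets) < 2:
        raise ValueError("GCPSR needs >= 2 gene trees")
    taxa = sets[0].taxa
    for cs in sets[1:]:
        if cs.taxa != taxa:
            raise ValueError("clade sets cover different taxa")
    supported = [
        {k for k, v in cs.clades.items() if v >= tau} for cs in sets
    ]
    all_splits = set().union(*(cs.clades.keys() for cs in sets))
    recognized: dict[frozenset, dict] = {}
    for s in sorted(all_splits, key=lambda x: (len(x), sorted(x))):
        n_sup = sum(1 for sup in supported if s in sup)
        if n_sup < 2:
            continue
        contradicted = any(
            _splits_incompatible(s, t, taxa)
            for sup in supported
            for t in sup
        )
        if contradicted:
            continue
        recognized[s] = {
            cs.tree_id: cs.clades.get(s) for cs in sets if s in cs.clades
        }
    # finest partition in which every recognised split is a union of blocks
    signature: dict[str, tuple] = {
        t: tuple(t in s for s in sorted(recognized, key=lambda x: sorted(x)))
        for t in taxa
    }
    blocks: dict[tuple, set] = {}
    for t, sig in signature.items():
        blocks.setdefault(sig, set()).add(t)
    partition = sorted(blocks.values(), key=lambda b: (-len(b), sorted(b)))
    return recognized, partition


# ----------------------------------------------------------------------
# Phi boundary expansion
# ----------------------------------------------------------------------

@dataclass
class ExpansionStep:
    included: list[str]
    added: list[str] | None
    group: str | None
    statistic: float
    p_value: float


@dataclass
class ExpansionTrajectory:
    steps: list[ExpansionStep]
    flagged_group: str | None
    alpha: float
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "flagged_group": self.flagged_group,
            "params": self.params,
            "steps": [
                {
                    "included": s.included,
                    "added": s.added,
                    "group": s.group,
                    "phi": s.statistic,
                    "p": s.p_value,
                }
                for s in self.steps
            ],
        }


def _mean_distance_to_seed(dm: DistanceMatrix, group: list[str], seed_set: list[str]) -> float:
    vals = [dm.value(g, s) for g in group for s in seed_set]
    return float(np.mean(vals))


def phi_boundary_expand(
    concat_aln: LocusAlignment,
    seed_set: list[str],
    candidates: dict[str, list[str]],
    policy: str = "groups",
    alpha: float = 0.05,
    window_w: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ExpansionTrajectory:
    """Gradually add candidate strains to a non-recombining seed set,
    re-running the Phi test after each addition.

    Candidates are added per ``policy``: whole groups (default) or single
    strains (``"single"``), ordered by increasing mean K3ST distance to the
    seed.  The group whose addition first drives p below ``alpha`` is
    classified as recombining with the seed.  The full trajectory is
    returned.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    rng = np.random.default_rng(seed)

    def run_phi(taxa: list[str]) -> TestResult:
        return phi_test(
            concat_aln.subset(taxa),
            window_w=window_w,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )

    res = run_phi(list(seed_set))
    if res.p_value <= alpha:
        raise ValueError(
            f"seed already recombining (Phi p = {res.p_value:.4g} <= {alpha})"
        )
    steps = [ExpansionStep(list(seed_set), None, None, res.statistic, res.p_value)]

    dm = k3st_distance(concat_aln, cap=True)
    units: list[tuple[str, list[str]]] = []
    if policy == "groups":
        units = list(candidates.items())
    elif policy == "single":
        for gname, members in candidates.items():
            units.extend((gname, [m]) for m in members)
    else:
        raise ValueError(f"unknown policy {policy!r}")
    units.sort(key=lambda u: _mean_distance_to_seed(dm, u[1], list(seed_set)))

    included = list(seed_set)
    flagged = None
    for gname, members in units:
        included = included + [m for m in members if m not in included]
        res = run_phi(included)
        steps.append(
            ExpansionStep(list(included), list(members), gname, res.statistic, res.p_value)
        )
        if flagged is None and res.p_value < alpha:
            flagged = gname
    return ExpansionTrajectory(
        steps, flagged, alpha,
        {"policy": policy, "window_w": window_w, "n_perm": n_perm, "seed": seed},
    )


def find_nonrecombining_seed(
    concat_aln: LocusAlignment,
    candidates: list[str],
    size: int = 6,
    alpha: float = 0.05,
    n_tries: int = 50,
    seed: int | None = None,
    window_w: int = 100,
    n_perm: int = 500,
) -> list[str]:
    """Search random subsets for a seed set without a recombination signal.

    Mirrors the first stage of the boundary procedure: draw ``size`` strains
    from ``candidates`` until the Phi test on them gives p > ``alpha``.
    Subsets with too little variation for the test are skipped.
    """
    rng = np.random.default_rng(seed)
    for _ in range(n_tries):
        pick = sorted(rng.choice(candidates, size=size, replace=False).tolist())
        try:
            res = phi_test(
                concat_aln.subset(pick), window_w=window_w,
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
        except ValueError:
            continue
        if res.p_value > alpha:
            return pick
    raise ValueError("no non-recombining seed subset found")
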