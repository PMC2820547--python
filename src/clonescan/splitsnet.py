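"""Bandelt-Dress split decomposition of a distance matrix.

A *d-split* is a bipartition A|B of the strains whose isolation index

    alpha = 1/2 min over a,a' in A and b,b' in B of
            [ max{d(a,b)+d(a',b'), d(a,b')+d(a',b), d(a,a')+d(b,b')}
              - d(a,a') - d(b,b') ]

is positive (repeats among a,a' and b,b' are allowed).  On an additive
(tree) metric the d-splits are exactly the tree's edges with alpha equal to
the branch lengths; conflicting phylogenetic signal -- e.g. from
recombination -- shows up as pairs of incompatible positive-weight splits,
which external viewers draw as an interconnected network of lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix

__all__ = [
    "Split",
    "SplitSystem",
    "isolation_index",
    "split_decomposition",
    "fit_percentage",
    "is_networked",
    "write_splits_nexus",
]


@dataclass(frozen=True)
class Split:
    """A weighted bipartition of the strain set."""

    side_a: frozenset
    side_b: frozenset
    weight: float

    def key(self) -> frozenset:
        """Canonical identity: the side containing the smallest label."""
        return self.side_a if min(self.side_a) <= min(self.side_b) else self.side_b

    def separates(self, x, y) -> bool:
        return (x in self.side_a) != (y in self.side_a)

    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1


@dataclass
class SplitSystem:
    taxa: list[str]
    splits: list[Split]
    source: str = ""

    def __post_init__(self):
        keys = [s.key() for s in self.splits]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate bipartitions in split system")

    @property
    def n_splits(self) -> int:
        return len(self.splits)

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial()]


def _alpha(d: np.ndarray, ai: np.ndarray, bi: np.ndarray) -> float:
    dAA = d[np.ix_(ai, ai)]
    dBB = d[np.ix_(bi, bi)]
    dAB = d[np.ix_(ai, bi)]
    t1 = dAB[:, None, :, None] + dAB[None, :, None, :]   # d(a,b) + d(a',b')
    t2 = dAB[:, None, None, :] + dAB[None, :, :, None]   # d(a,b') + d(a',b)
    t3 = dAA[:, :, None, None] + dBB[None, None, :, :]   # d(a,a') + d(b,b')
    val = np.maximum(np.maximum(t1, t2), t3) - t3
    return 0.5 * float(val.min())


def isolation_index(dm: DistanceMatrix, side_a, side_b=None) -> float:
    """Isolation index alpha of the bipartition ``side_a | side_b``.

    ``side_b`` defaults to the complement of ``side_a`` in ``dm.taxa``.
    """
    A = set(side_a)
    B = set(side_b) if side_b is not None else set(dm.taxa) - A
    if not A or not B or A & B or A | B != set(dm.taxa):
        raise ValueError("invalid bipartition of the taxon set")
    pos = {t: i for i, t in enumerate(dm.taxa)}
    ai = np.asarray(sorted(pos[t] for t in A))
    bi = np.asarray(sorted(pos[t] for t in B))
    return _alpha(dm.d, ai, bi)


def split_decomposition(dm: DistanceMatrix, tol: float = 1e-10) -> SplitSystem:
    """All d-splits of the metric with isolation index above ``tol``.

    Built by incremental taxon insertion: each retained split is extended by
    the new taxon on either side, the new trivial split is added, and
    candidates with non-positive isolation index are discarded.  For
    d-splits the result does not depend on the insertion order.
    """
    if dm.n < 2:
        raise ValueError("need >= 2 taxa")
    if not np.isfinite(dm.d).all():
        raise ValueError("non-finite distances")
    d = dm.d
    current: list[tuple[frozenset, frozenset]] = [
        (frozenset([0]), frozenset([1]))
    ]
    for t in range(2, dm.n):
        candidates: set[tuple[frozenset, frozenset]] = set()
        for A, B in current:
            candidates.add((A | {t}, B))
            candidates.add((A, B | {t}))
        candidates.add((frozenset([t]), frozenset(range(t))))
        nxt = []
        for A, B in candidates:
            ai = np.fromiter(A, int)
            bi = np.fromiter(B, int)
            if _alpha(d, ai, bi) > tol:
                nxt.append((A, B))
        current = nxt
    splits = []
    for A, B in current:
        a = _alpha(d, np.fromiter(A, int), np.fromiter(B, int))
        splits.append(
            Split(
                frozenset(dm.taxa[i] for i in A),
                frozenset(dm.taxa[i] for i in B),
                a,
            )
        )
    splits.sort(key=lambda s: sorted(s.key()))
    return SplitSystem(list(dm.taxa), splits, source=dm.model)


def fit_percentage(ss: SplitSystem, dm: DistanceMatrix) -> float:
    """100 * (split-metric pairwise sum) / (observed pairwise sum)."""
    if set(ss.taxa) != set(dm.taxa):
        raise ValueError("split system and distance matrix taxa differ")
    total = 0.0
    rep = 0.0
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            x, y = dm.taxa[i], dm.taxa[j]
            total += dm.d[i, j]
            rep += sum(s.weight for s in ss.splits if s.separates(x, y))
    if total == 0:
        raise ValueError("zero total distance")
    return 100.0 * rep / total


def _incompatible(s: Split, t: Split) -> bool:
    return all(
        (x & y)
        for x in (s.side_a, s.side_b)
        for y in (t.side_a, t.side_b)
    )


def is_networked(ss: SplitSystem) -> bool:
    """True iff some pair of positive-weight splits is incompatible
    (all four side intersections non-empty) -- the reticulation signature."""
    splits = [s for s in ss.splits if s.weight > 0]
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            if _incompatible(splits[i], splits[j]):
                return True
    return False


def write_splits_nexus(ss: SplitSystem, path) -> None:
    """SplitsTree4-compatible NEXUS with Taxa and Splits blocks."""
    index = {t: i + 1 for i, t in enumerate(ss.taxa)}
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(ss.taxa)};\nTAXLABELS\n")
        for i, t in enumerate(ss.taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND;\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={len(ss.taxa)} nsplits={ss.n_splits};\n")
        fh.write("FORMAT labels=no weights=yes confidences=no intervals=no;\nMATRIX\n")
        for k, s in enumerate(ss.splits, 1):
            side = s.key()
            ids = " ".join(str(index[t]) for t in sorted(side, key=lambda x: index[x]))
            fh.write(f"[{k}, size={len(side)}]\t{s.weight:.8f}\t{ids},\n")
        fh.write(";\nEND;\n")
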