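"""Pairwise distances between strains (Kimura 3ST and p-distance).

Missing characters ('-' and 'N') are handled by pairwise deletion: each pair
of strains is compared over its jointly observed columns only.  The Kimura
three-substitution-type distance distinguishes transitions (A<->G, C<->T)
from the two transversion classes (A<->T / C<->G, and A<->C / G<->T):

    d = -1/4 [ ln(1-2P-2Q) + ln(1-2P-2R) + ln(1-2Q-2R) ]

with P, Q, R the respective difference proportions among comparable sites.
When a log argument is non-positive the pair is saturated; the default is a
hard error, optionally capped at a finite ceiling for downstream network
construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqdata import LocusAlignment, MISSING

__all__ = [
    "DistanceMatrix",
    "SaturationError",
    "k3st_distance",
    "p_distance",
    "check_additivity",
]


class SaturationError(ValueError):
    """K3ST log argument <= 0 for some pair (distance undefined)."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-site counts."""

    taxa: list[str]
    d: np.ndarray
    model: str
    comparable_sites: np.ndarray | None = None
    capped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("asymmetric distance matrix")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def value(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.d[i, j])

    def subset(self, taxa: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        comp = None
        if self.comparable_sites is not None:
            comp = self.comparable_sites[np.ix_(idx, idx)]
        return DistanceMatrix(list(taxa), self.d[np.ix_(idx, idx)], self.model, comp)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.taxa, columns=self.taxa)

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for t, row in zip(self.taxa, self.d):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{t:<12} {vals}\n")

    def write_nexus(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN Taxa;\n")
            fh.write(f"    DIMENSIONS ntax={self.n};\n    TAXLABELS\n")
            for t in self.taxa:
                fh.write(f"        '{t}'\n")
            fh.write("    ;\nEND;\n\nBEGIN Distances;\n")
            fh.write(f"    DIMENSIONS ntax={self.n};\n")
            fh.write("    FORMAT triangle=both diagonal labels=left;\n    MATRIX\n")
            for t, row in zip(self.taxa, self.d):
                vals = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"        '{t}' {vals}\n")
            fh.write("    ;\nEND;\n")


def _pair_masks(codes: np.ndarray):
    obs = codes < MISSING
    return obs


def p_distance(aln: LocusAlignment, counts: bool = False) -> DistanceMatrix:
    """Proportion (or count, ``counts=True``) of differing comparable sites."""
    codes = aln.codes()
    n = aln.n_taxa
    obs = codes < MISSING
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            m = obs[i] & obs[j]
            nc = int(m.sum())
            if nc == 0:
                raise SaturationError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            nd = int((codes[i][m] != codes[j][m]).sum())
            comp[i, j] = comp[j, i] = nc
            d[i, j] = d[j, i] = nd if counts else nd / nc
    model = "p-count" if counts else "p"
    return DistanceMatrix(list(aln.taxa), d, model, comp)


def k3st_distance(
    aln: LocusAlignment, cap: bool = False, d_max: float = 10.0
) -> DistanceMatrix:
    """Kimura 3ST distance with pairwise deletion of missing sites.

    ``cap=True`` replaces saturated pairs by ``d_max`` with a warning instead
    of raising; networks need finite inputs.
    """
    codes = aln.codes()
    n = aln.n_taxa
    obs = codes < MISSING
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    capped: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            m = obs[i] & obs[j]
            nc = int(m.sum())
            if nc == 0:
                raise SaturationError(
                    f"no comparable sites between {aln.taxa[i]!r} and {aln.taxa[j]!r}"
                )
            a, b = codes[i][m], codes[j][m]
            diff = a != b
            s = a[diff].astype(int) + b[diff].astype(int)
            # unordered pair sums: 2 or 4 -> transition; 3 -> A-T/C-G; 1 or 5 -> A-C/G-T
            P = int(((s == 2) | (s == 4)).sum()) / nc
            Q = int((s == 3).sum()) / nc
            R = int(((s == 1) | (s == 5)).sum()) / nc
            args = (1 - 2 * P - 2 * Q, 1 - 2 * P - 2 * R, 1 - 2 * Q - 2 * R)
            comp[i, j] = comp[j, i] = nc
            if min(args) <= 0:
                if not cap:
                    raise SaturationError(
                        f"K3ST saturated for pair ({aln.taxa[i]!r}, {aln.taxa[j]!r}): "
                        f"P={P:.3f} Q={Q:.3f} R={R:.3f}"
                    )
                warnings.warn(
                    f"K3ST saturated for ({aln.taxa[i]}, {aln.taxa[j]}); capped at {d_max}"
                )
                capped.append((aln.taxa[i], aln.taxa[j]))
                val = d_max
            else:
                val = -0.25 * sum(np.log(x) for x in args)
            d[i, j] = d[j, i] = val
    return DistanceMatrix(list(aln.taxa), d, "k3st", comp, capped)


def check_additivity(dm: DistanceMatrix, tol: float = 1e-8) -> bool:
    """True iff every quartet satisfies the four-point condition within tol.

    Vacuously true below 4 taxa.
    """
    d = dm.d
    n = dm.n
    if n < 4:
        return True
    for i, j, k, l in itertools.combinations(range(n), 4):
        sums = sorted(
            (d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k])
        )
        if sums[2] - sums[1] > tol:
            return False
    return True
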