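"""Recombination and population-structure tests for multilocus haploid data.

Implements the pairwise homoplasy index (PHI) test, the index of association
(IA) permutation test, the partition-homogeneity (incongruence length
difference) test, Tajima's D, the Hudson-Kaplan lower bound Rm on the number
of recombination events, and Hudson's FST from mean pairwise differences.

All permutation p-values use the add-one estimator (1 + b) / (1 + m) and are
reproducible given (seed, n_permutations).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqdata import (
    LocusAlignment,
    MultiLocusDataset,
    MISSING,
    allele_index,
    classify_sites,
    clone_correct,
)

__all__ = [
    "TestResult",
    "pairwise_incompatibility",
    "phi_test",
    "ia_test",
    "pht_test",
    "tajimas_d",
    "rm_hudson_kaplan",
    "hudson_fst",
    "fst_all_pairs",
]


@dataclass
class TestResult:
    """Statistic value with its (optional) permutation null."""

    method: str
    statistic: float | None
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "params": self.params,
        }


# ----------------------------------------------------------------------
# refined incompatibility between two site columns
# ----------------------------------------------------------------------

def _incompat_from_codes(ci: np.ndarray, cj: np.ndarray) -> int:
    mask = (ci < MISSING) & (cj < MISSING)
    if int(mask.sum()) < 2:
        raise ValueError("fewer than 2 jointly non-missing taxa")
    a = ci[mask].astype(np.int16)
    b = cj[mask].astype(np.int16)
    joint = np.unique(a * 5 + b)
    sa = np.unique(a)
    sb = np.unique(b)
    V = len(sa) + len(sb)
    E = len(joint)
    # connected components of the partition intersection graph by union-find
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for s in sa:
        parent[("a", int(s))] = ("a", int(s))
    for s in sb:
        parent[("b", int(s))] = ("b", int(s))
    C = V
    for j in joint:
        ra = find(("a", int(j) // 5))
        rb = find(("b", int(j) % 5))
        if ra != rb:
            parent[ra] = rb
            C -= 1
    return E - V + C


def pairwise_incompatibility(col_i, col_j) -> int:
    """Refined incompatibility score of two site columns.

    Score = E - V + C for the partition intersection graph (vertices are the
    observed states of each column, one edge per distinct observed joint
    state, C connected components): the number of independent cycles.  Zero
    iff the pair of sites is compatible with a single tree.  Missing entries
    are dropped pairwise.
    """
    ci = _column_codes(col_i)
    cj = _column_codes(col_j)
    if ci.shape != cj.shape:
        raise ValueError("columns must cover the same taxa")
    return _incompat_from_codes(ci, cj)


def _column_codes(col) -> np.ndarray:
    if isinstance(col, np.ndarray):
        return col.astype(np.uint8)
    # string column over arbitrary symbols; '-'/'N'/'?' missing
    lut = {}
    out = np.empty(len(col), dtype=np.uint8)
    for k, ch in enumerate(col):
        c = ch.upper()
        if c in "-N?":
            out[k] = MISSING
        else:
            if c not in lut:
                if len(lut) >= 4:
                    raise ValueError("more than 4 states in a column")
                lut[c] = len(lut)
            out[k] = lut[c]
    return out


def _incompatibility_matrix(codes: np.ndarray) -> np.ndarray:
    """Symmetric (k, k) matrix of refined incompatibility between columns.

    ``codes`` is (n_taxa, k) with missing = 4.
    """
    k = codes.shape[1]
    M = np.zeros((k, k))
    cols = [codes[:, j] for j in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            M[i, j] = M[j, i] = _incompat_from_codes(cols[i], cols[j])
    return M


# ----------------------------------------------------------------------
# PHI test
# ----------------------------------------------------------------------

def phi_test(
    aln: LocusAlignment,
    window_w: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
    analytic: bool = False,
    exact_perm: bool = False,
) -> TestResult:
    """Pairwise homoplasy index (PHI) test for recombination.

    The statistic is the mean refined incompatibility over all pairs of
    parsimony-informative sites whose original alignment positions differ by
    at most ``window_w``.  Under clonality nearby and distant site pairs are
    equally (in)compatible, so the null permutes the assignment of
    informative-site columns to positions; the one-sided p-value counts
    permutations with a statistic <= the observed one (add-one estimator).

    ``exact_perm=True`` enumerates all k! assignments (k <= 8 informative
    sites) instead of sampling; ``analytic=True`` adds a normal-approximation
    p-value in ``params['p_analytic']``.
    """
    if n_perm < 1 and not exact_perm:
        raise ValueError("n_perm must be >= 1")
    sc = classify_sites(aln)
    pos = sc.informative_positions()
    k = len(pos)
    if k < 2:
        raise ValueError(f"need >=2 parsimony-informative sites, found {k}")
    codes = aln.codes()[:, pos]
    M = _incompatibility_matrix(codes)
    iu, ju = np.triu_indices(k, 1)
    window = (pos[ju] - pos[iu]) <= window_w
    if not window.any():
        raise ValueError("all informative-site pairs lie beyond the window")
    wi, wj = iu[window], ju[window]
    phi_obs = float(M[wi, wj].mean())

    params: dict = {"window_w": window_w, "n_informative": int(k),
                    "n_window_pairs": int(window.sum())}
    if exact_perm:
        if k > 8:
            raise ValueError("exact permutation enumeration limited to 8 sites")
        vals = []
        for perm in itertools.permutations(range(k)):
            p = np.asarray(perm)
            vals.append(M[p[wi], p[wj]].mean())
        vals = np.asarray(vals)
        b = int((vals <= phi_obs + 1e-12).sum())
        pval = b / len(vals)
        nper = len(vals)
        params["exact_permutation"] = True
    else:
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_perm):
            p = rng.permutation(k)
            if M[p[wi], p[wj]].mean() <= phi_obs + 1e-12:
                b += 1
        pval = (1 + b) / (n_perm + 1)
        nper = n_perm
    if analytic:
        mu = float(M[iu, ju].mean())
        var_all = float(M[iu, ju].var())
        m = int(window.sum())
        K = len(iu)
        # window pairs approximated as a simple random sample of all pairs
        var = var_all / m * (1 - (m - 1) / max(K - 1, 1)) if K > 1 else 0.0
        if var <= 0:
            params["p_analytic"] = 1.0 if phi_obs >= mu else 0.0
        else:
            params["p_analytic"] = float(sps.norm.cdf((phi_obs - mu) / math.sqrt(var)))
    return TestResult("phi", phi_obs, pval, nper, seed, params)


# ----------------------------------------------------------------------
# index of association
# ----------------------------------------------------------------------

def _ia_statistic(alleles: np.ndarray) -> float:
    n, m = alleles.shape
    iu, ju = np.triu_indices(n, 1)
    per_locus = np.stack(
        [(alleles[iu, l] != alleles[ju, l]).astype(float) for l in range(m)]
    )  # (m, n_pairs)
    d = per_locus.sum(axis=0)
    v_obs = float(d.var())
    v_exp = float(per_locus.var(axis=1).sum())
    if v_exp == 0:
        raise ValueError("all loci monomorphic: V_E = 0")
    return v_obs / v_exp - 1.0


def ia_test(
    ds: MultiLocusDataset,
    n_perm: int = 1000,
    seed: int | None = None,
    clone_correct_first: bool = True,
) -> TestResult:
    """Index of association (multilocus linkage disequilibrium) test.

    IA = V_O / V_E - 1 where V_O is the variance over strain pairs of the
    number of loci with differing alleles and V_E the sum over loci of the
    variance of the per-locus mismatch indicator.  Complete panmixia gives
    IA = 0; clonality inflates it.  The null shuffles alleles among strains
    independently within each locus ("artificially recombined datasets");
    p counts permutations with IA* >= IA_obs (add-one).
    """
    if len(ds.loci) < 2:
        raise ValueError("IA needs >= 2 loci")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    removed = {}
    if clone_correct_first:
        ds, mapping = clone_correct(ds)
        removed = {k: v for k, v in mapping.items() if v}
    if ds.n_taxa < 3:
        raise ValueError("need >= 3 strains after clone correction")
    alleles = allele_index(ds).to_numpy()
    ia_obs = _ia_statistic(alleles)
    rng = np.random.default_rng(seed)
    b = 0
    n, m = alleles.shape
    for _ in range(n_perm):
        shuffled = np.column_stack(
            [alleles[rng.permutation(n), l] for l in range(m)]
        )
        if _ia_statistic(shuffled) >= ia_obs - 1e-12:
            b += 1
    pval = (1 + b) / (n_perm + 1)
    return TestResult(
        "ia", ia_obs, pval, n_perm, seed,
        {"clone_corrected": clone_correct_first,
         "n_strains": int(n), "n_loci": int(m),
         "n_clones_removed": int(sum(len(v) for v in removed.values()))},
    )


# ----------------------------------------------------------------------
# partition homogeneity (ILD) test
# ----------------------------------------------------------------------

def _variable_columns(ds: MultiLocusDataset) -> tuple[list[np.ndarray], list[int]]:
    cols = []
    sizes = []
    for loc in ds.loci:
        sc = classify_sites(loc)
        vp = sc.variable_positions()
        sizes.append(len(vp))
        codes = loc.codes()
        cols.extend(codes[:, j].copy() for j in vp)
    return cols, sizes


def _mp_of_columns(cols, taxa, rng, exact_limit=7, n_starts=4) -> int:
    from .parsimony import mp_length_exact, mp_length_heuristic
    from .seqdata import LocusAlignment as _LA

    if not cols:
        return 0
    codes = np.column_stack(cols)
    rows = ["".join("ACGTN"[c] for c in codes[i]) for i in range(len(taxa))]
    aln = _LA("pseudo", list(taxa), rows)
    if len(taxa) <= exact_limit:
        return mp_length_exact(aln)
    return mp_length_heuristic(aln, n_starts=n_starts, seed=int(rng.integers(2**31)))


def pht_test(
    ds: MultiLocusDataset,
    n_reps: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    n_starts: int = 4,
) -> TestResult:
    """Partition-homogeneity (incongruence length difference) test.

    Statistic: sum over loci of the maximum-parsimony tree length of each
    locus (variable columns only; constant columns contribute no length).
    Replicates re-partition the pooled variable columns into pseudo-loci of
    the original sizes, sampling without replacement.  Under recombination
    the observed partition is unusually congruent within loci, so its summed
    length is short: p counts replicates with sum* <= sum_obs.

    ``exhaustive=True`` enumerates every re-partition (feasible for toy
    data); the p-value is then the exact proportion, with no add-one term.
    """
    if len(ds.loci) < 2:
        raise ValueError("PHT needs >= 2 loci")
    if n_reps < 1 and not exhaustive:
        raise ValueError("n_reps must be >= 1")
    cols, sizes = _variable_columns(ds)
    if not cols:
        raise ValueError("no variable sites")
    rng = np.random.default_rng(seed)
    taxa = ds.taxa

    def total_for(order: list[int]) -> int:
        out = 0
        start = 0
        for s in sizes:
            out += _mp_of_columns([cols[i] for i in order[start:start + s]],
                                  taxa, rng, n_starts=n_starts)
            start += s
        return out

    obs = total_for(list(range(len(cols))))
    if exhaustive:
        count = 0
        total = 0
        for order in _partitions(len(cols), sizes):
            total += 1
            if total_for(order) <= obs:
                count += 1
        pval = count / total
        nrep = total
    else:
        b = 0
        idx = np.arange(len(cols))
        for _ in range(n_reps):
            perm = rng.permutation(idx)
            if total_for(list(perm)) <= obs:
                b += 1
        pval = (1 + b) / (n_reps + 1)
        nrep = n_reps
    return TestResult(
        "pht", float(obs), pval, nrep, seed,
        {"locus_sizes_variable": sizes, "exhaustive": exhaustive},
    )


def _partitions(n_items: int, sizes: list[int]):
    """All ordered partitions of range(n_items) into blocks of given sizes."""
    def rec(remaining: tuple, sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        s = sizes_left[0]
        if len(sizes_left) == 1:
            yield list(remaining)
            return
        for combo in itertools.combinations(remaining, s):
            rest = tuple(x for x in remaining if x not in combo)
            for tail in rec(rest, sizes_left[1:]):
                yield list(combo) + tail

    yield from rec(tuple(range(n_items)), sizes)


# ----------------------------------------------------------------------
# Tajima's D
# ----------------------------------------------------------------------

def tajimas_d(aln: LocusAlignment) -> TestResult:
    """Tajima's D from segregating sites and mean pairwise differences.

    Sites with more than two states count once in S (any-difference
    definition); pi is the mean pairwise difference count with pairwise
    deletion.  With no segregating site D is undefined and flagged.
    """
    n = aln.n_taxa
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 sequences")
    sc = classify_sites(aln)
    S = sc.n_variable
    if S == 0:
        return TestResult("tajima_d", None, None, 0, None, {"undefined": True, "S": 0})
    codes = aln.codes()
    obs = codes < MISSING
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            m = obs[i] & obs[j]
            total += int((codes[i][m] != codes[j][m]).sum())
    pi = total / (n * (n - 1) / 2)

    a1 = sum(1 / k for k in range(1, n))
    a2 = sum(1 / k**2 for k in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    D = (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
    return TestResult(
        "tajima_d", float(D), None, 0, None,
        {"S": int(S), "pi": float(pi), "n": int(n)},
    )


# ----------------------------------------------------------------------
# Hudson-Kaplan Rm
# ----------------------------------------------------------------------

def rm_hudson_kaplan(aln: LocusAlignment) -> TestResult:
    """Hudson-Kaplan lower bound Rm on the number of recombination events.

    Considers biallelic segregating sites (multistate sites are skipped with
    a warning); a site pair showing all four gametes delimits an interval
    that must contain a recombination event.  Rm is the maximum number of
    pairwise-disjoint such open intervals (interval-reduction algorithm).
    """
    codes = aln.codes()
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    distinct = (counts > 0).sum(axis=0)
    biallelic = np.flatnonzero(distinct == 2)
    multi = int((distinct > 2).sum())
    if multi:
        warnings.warn(f"{multi} site(s) with >2 states skipped for Rm")
    intervals = []
    for a, b in itertools.combinations(biallelic.tolist(), 2):
        ci, cj = codes[:, a], codes[:, b]
        m = (ci < MISSING) & (cj < MISSING)
        joint = np.unique(ci[m].astype(int) * 5 + cj[m].astype(int))
        if len(joint) == 4:
            intervals.append((a, b))
    # greedy disjoint-open-interval packing by right endpoint
    intervals.sort(key=lambda t: t[1])
    rm = 0
    last = -1
    chosen = []
    for l, r in intervals:
        if l >= last:
            rm += 1
            last = r
            chosen.append((l + 1, r + 1))  # report 1-based
    return TestResult(
        "rm", float(rm), None, 0, None,
        {"n_incompatible_pairs": len(intervals), "intervals": chosen},
    )


# ----------------------------------------------------------------------
# Hudson FST
# ----------------------------------------------------------------------

def hudson_fst(aln: LocusAlignment, pop_labels: dict[str, str] | list[str]) -> TestResult:
    """Hudson's FST = 1 - Hw/Hb between two groups of strains.

    Hw is the unweighted mean of the two within-group mean pairwise
    difference counts (a group below two strains contributes no within term);
    Hb the mean difference count across groups.  Pairwise deletion of
    missing sites; negative estimates are reported, not truncated.
    """
    if isinstance(pop_labels, dict):
        labels = [pop_labels[t] for t in aln.taxa]
    else:
        labels = list(pop_labels)
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    idx = {g: [i for i, l in enumerate(labels) if l == g] for g in groups}
    codes = aln.codes()
    obs = codes < MISSING

    def diff(i, j):
        m = obs[i] & obs[j]
        return int((codes[i][m] != codes[j][m]).sum())

    within = []
    for g in groups:
        members = idx[g]
        if len(members) < 2:
            warnings.warn(f"group {g!r} has <2 strains; no within-group term")
            continue
        vals = [diff(i, j) for i, j in itertools.combinations(members, 2)]
        within.append(float(np.mean(vals)))
    hw = float(np.mean(within)) if within else 0.0
    between = [diff(i, j) for i in idx[groups[0]] for j in idx[groups[1]]]
    hb = float(np.mean(between))
    if hb == 0:
        raise ValueError("populations indistinguishable (Hb = 0)")
    fst = 1 - hw / hb
    return TestResult(
        "fst", float(fst), None, 0, None,
        {"groups": groups, "Hw": hw, "Hb": hb,
         "sizes": {g: len(idx[g]) for g in groups}},
    )


def fst_all_pairs(aln: LocusAlignment, metadata: dict[str, dict]) -> pd.DataFrame:
    """FST for every pair of geographic groups found in the metadata.

    Returns a tidy frame (group_a, group_b, fst, n_a, n_b); the maximum is
    the headline scan value.
    """
    geo = {t: metadata.get(t, {}).get("geo_group", "") for t in aln.taxa}
    groups = sorted({g for g in geo.values() if g})
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        taxa = [t for t in aln.taxa if geo[t] in (ga, gb)]
        sub = aln.subset(taxa)
        labels = [geo[t] for t in taxa]
        try:
            res = hudson_fst(sub, labels)
            rows.append({"group_a": ga, "group_b": gb, "fst": res.statistic,
                         "n_a": res.params["sizes"][ga], "n_b": res.params["sizes"][gb]})
        except ValueError:
            rows.append({"group_a": ga, "group_b": gb, "fst": float("nan"),
                         "n_a": labels.count(ga), "n_b": labels.count(gb)})
    return pd.DataFrame(rows)
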