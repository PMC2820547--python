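"""Coalescent simulation of multilocus haploid datasets with known truth.

The generator emulates the sampling structure of a small fungal multilocus
study: three loci of a few hundred aligned nucleotides for a few dozen
haploid strains, with a recombining clade (independent genealogies among and
within loci), a clonal clade (one genealogy shared by every locus), and an
optional small third clade.  Time is measured in coalescent units; theta is
the per-locus population mutation parameter (mutations arrive as a Poisson
process of rate theta/2 per unit of total branch length, sites chosen
uniformly, Jukes-Cantor state changes).

Reproducibility: every public entry point takes one master seed from which
all per-locus / per-segment child seeds are derived deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .seqdata import LocusAlignment, MultiLocusDataset
from .trees import Tree, TreeNode

__all__ = [
    "SimTruth",
    "sim_coalescent_tree",
    "evolve_sequences",
    "sim_clonal_dataset",
    "sim_recombining_dataset",
    "sim_two_species",
    "DEFAULT_LOCUS_LENGTHS",
]

# three loci at typical fragment lengths (~350-510 nt each)
DEFAULT_LOCUS_LENGTHS = (509, 377, 355)
_LOCUS_NAMES = ("tef1", "cal1", "las1")

_NT = "ACGT"


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``genealogies`` maps locus name to a list of (start, end, newick) column
    segments (0-based half-open); the truth object suffices to recompute the
    expected classification of every strain without re-simulation.
    """

    master_seed: int
    params: dict
    species: dict[str, str]
    clonal: dict[str, bool]
    genealogies: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def species_partition(self) -> list[set]:
        out: dict[str, set] = {}
        for strain, sp in self.species.items():
            out.setdefault(sp, set()).add(strain)
        return sorted(out.values(), key=lambda b: (-len(b), sorted(b)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "master_seed": self.master_seed,
                    "params": self.params,
                    "species": self.species,
                    "clonal": self.clonal,
                    "genealogies": self.genealogies,
                },
                fh, indent=1, sort_keys=True,
            )


def _child_rngs(seed: int | None, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def sim_coalescent_tree(
    n: int,
    seed: int | None = None,
    labels: list[str] | None = None,
    rng: np.random.Generator | None = None,
    scale: float = 1.0,
) -> Tree:
    """A Kingman coalescent genealogy for ``n`` lineages.

    Waiting times while k lineages remain are exponential with rate
    k(k-1)/2 (coalescent units); a uniformly chosen pair merges at each
    event.  Branch lengths are coalescent times multiplied by ``scale``.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    rng = rng if rng is not None else np.random.default_rng(seed)
    labels = labels or [f"s{i+1:02d}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count != n")
    lineages = [(TreeNode(label=l), 0.0) for l in labels]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        (a, ta), (b, tb) = lineages[i], lineages[j]
        parent = TreeNode()
        a.length = (t - ta) * scale
        b.length = (t - tb) * scale
        parent.add(a)
        parent.add(b)
        lineages = [lineages[x] for x in range(k) if x not in (i, j)]
        lineages.append((parent, t))
    return Tree(lineages[0][0])


def evolve_sequences(
    tree: Tree,
    length: int,
    theta: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    infinite_sites: bool = False,
    taxa_order: list[str] | None = None,
    locus_name: str = "locus",
) -> LocusAlignment:
    """Evolve a locus of ``length`` sites down a genealogy.

    The total number of mutations is Poisson(theta/2 * total branch length);
    each mutation picks a branch proportionally to its length, a uniform
    site, and a Jukes-Cantor change to one of the other three states.  With
    ``infinite_sites=True`` no site may be hit twice (error if mutations
    exceed ``length``).
    """
    if length < 1:
        raise ValueError("length must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nodes = [n for n in tree.postorder()]
    branches = [n for n in nodes if n is not tree.root]
    blens = np.array([b.length or 0.0 for b in branches])
    total = blens.sum()
    n_mut = int(rng.poisson(theta / 2.0 * total)) if total > 0 else 0
    if infinite_sites:
        if n_mut > length:
            raise ValueError(
                f"infinite-sites violation: {n_mut} mutations for {length} sites"
            )
        sites = rng.choice(length, size=n_mut, replace=False)
    else:
        sites = rng.integers(0, length, size=n_mut)
    if total > 0 and n_mut > 0:
        branch_idx = rng.choice(len(branches), size=n_mut, p=blens / total)
    else:
        branch_idx = np.empty(0, dtype=int)
    shifts = rng.integers(1, 4, size=n_mut)  # JC: move to one of the 3 others
    per_branch: dict[int, list[tuple[int, int]]] = {}
    for b, s, sh in zip(branch_idx, sites, shifts):
        per_branch.setdefault(int(b), []).append((int(s), int(sh)))
    branch_pos = {id(b): i for i, b in enumerate(branches)}

    root_seq = rng.integers(0, 4, size=length).astype(np.int8)
    seqs: dict[str, np.ndarray] = {}

    def walk(node, seq):
        if node is not tree.root:
            muts = per_branch.get(branch_pos[id(node)])
            if muts:
                seq = seq.copy()
                for s, sh in muts:
                    seq[s] = (seq[s] + sh) % 4
        if node.is_leaf:
            seqs[node.label] = seq
            return
        for c in node.children:
            walk(c, seq)

    walk(tree.root, root_seq)
    order = taxa_order or tree.leaf_names()
    rows = ["".join(_NT[v] for v in seqs[t]) for t in order]
    return LocusAlignment(locus_name, list(order), rows)


def _segment_bounds(length: int, n_breakpoints: int, rng) -> list[tuple[int, int]]:
    if n_breakpoints <= 0:
        return [(0, length)]
    cuts = sorted(rng.choice(np.arange(1, length), size=min(n_breakpoints, length - 1),
                             replace=False).tolist())
    bounds = []
    prev = 0
    for c in cuts + [length]:
        bounds.append((prev, c))
        prev = c
    return bounds


def _evolve_segmented(
    locus_name: str,
    length: int,
    theta: float,
    segments: list[tuple[int, int, Tree]],
    taxa: list[str],
    rng,
) -> LocusAlignment:
    parts = []
    for start, end, tree in segments:
        seg_len = end - start
        parts.append(
            evolve_sequences(
                tree, seg_len, theta * seg_len / length, rng=rng,
                taxa_order=taxa, locus_name=locus_name,
            )
        )
    rows = ["".join(p.rows[i] for p in parts) for i in range(len(taxa))]
    return LocusAlignment(locus_name, list(taxa), rows)


def sim_clonal_dataset(
    n: int = 20,
    locus_lengths: tuple[int, ...] = DEFAULT_LOCUS_LENGTHS,
    theta: float = 15.0,
    seed: int | None = None,
    label_prefix: str = "s",
) -> tuple[MultiLocusDataset, SimTruth]:
    """Fully clonal panel: ONE genealogy shared by all loci (complete
    linkage), each locus evolved independently on it."""
    rngs = _child_rngs(seed, len(locus_lengths) + 1)
    labels = [f"{label_prefix}{i+1:02d}" for i in range(n)]
    tree = sim_coalescent_tree(n, labels=labels, rng=rngs[0])
    loci = []
    genealogies = {}
    for k, L in enumerate(locus_lengths):
        name = _LOCUS_NAMES[k] if k < len(_LOCUS_NAMES) else f"locus{k+1}"
        loci.append(
            evolve_sequences(tree, L, theta, rng=rngs[k + 1],
                             taxa_order=labels, locus_name=name)
        )
        genealogies[name] = [(0, L, tree.to_newick())]
    ds = MultiLocusDataset(labels, loci)
    truth = SimTruth(
        master_seed=seed if seed is not None else -1,
        params={"model": "clonal", "n": n, "locus_lengths": list(locus_lengths),
                "theta": theta},
        species={t: "species1" for t in labels},
        clonal={t: True for t in labels},
        genealogies=genealogies,
    )
    return ds, truth


def sim_recombining_dataset(
    n: int = 20,
    locus_lengths: tuple[int, ...] = DEFAULT_LOCUS_LENGTHS,
    theta: float = 15.0,
    breakpoints_per_locus: int = 0,
    seed: int | None = None,
    label_prefix: str = "s",
) -> tuple[MultiLocusDataset, SimTruth]:
    """Freely recombining panel: an independent genealogy per locus, and
    ``breakpoints_per_locus`` uniform within-locus breakpoints each starting
    an independent genealogy segment."""
    rngs = _child_rngs(seed, len(locus_lengths))
    labels = [f"{label_prefix}{i+1:02d}" for i in range(n)]
    loci = []
    genealogies = {}
    for k, L in enumerate(locus_lengths):
        name = _LOCUS_NAMES[k] if k < len(_LOCUS_NAMES) else f"locus{k+1}"
        rng = rngs[k]
        bounds = _segment_bounds(L, breakpoints_per_locus, rng)
        segs = [
            (a, b, sim_coalescent_tree(n, labels=labels, rng=rng))
            for a, b in bounds
        ]
        loci.append(_evolve_segmented(name, L, theta, segs, labels, rng))
        genealogies[name] = [(a, b, t.to_newick()) for a, b, t in segs]
    ds = MultiLocusDataset(labels, loci)
    truth = SimTruth(
        master_seed=seed if seed is not None else -1,
        params={"model": "recombining", "n": n,
                "locus_lengths": list(locus_lengths), "theta": theta,
                "breakpoints_per_locus": breakpoints_per_locus},
        species={t: "species1" for t in labels},
        clonal={t: False for t in labels},
        genealogies=genealogies,
    )
    return ds, truth


def _join_species(subtrees: list[tuple[Tree, float]]) -> Tree:
    """Join species subtrees at the stated divergence above the deeper root.

    ``subtrees`` is [(tree, join_depth), ...] joined left to right: the join
    node sits ``join_depth`` units above the deeper of the two roots (no
    shared ancestral polymorphism across the species boundary).
    """
    def depth(tree: Tree) -> float:
        best = 0.0
        for leaf in tree.leaves():
            d = 0.0
            node = leaf
            while node is not tree.root:
                d += node.length or 0.0
                node = node.parent
            best = max(best, d)
        return best

    current = subtrees[0][0]
    for tree, gap in subtrees[1:]:
        da, db = depth(current), depth(tree)
        top = max(da, db) + gap
        root = TreeNode()
        current.root.length = top - da
        tree.root.length = top - db
        root.add(current.root)
        root.add(tree.root)
        current = Tree(root)
    return current


def sim_two_species(
    n_recomb: int = 25,
    n_clonal: int = 6,
    n_third: int = 2,
    locus_lengths: tuple[int, ...] = DEFAULT_LOCUS_LENGTHS,
    theta: float = 15.0,
    divergence: float = 2.0,
    third_divergence: float = 1.0,
    clonal_scale: float = 0.05,
    breakpoints_per_locus: int = 0,
    geo_groups: tuple[str, ...] = ("SouthAmerica", "Caribbean", "Indopacific", "Africa"),
    seed: int | None = None,
) -> tuple[MultiLocusDataset, SimTruth]:
    """Sympatric mixture: a recombining clade, a clonal clade, and an
    optional small third (recombining) clade.

    Clade A ("speciesA", ``n_recomb`` strains) recombines freely among loci
    and at ``breakpoints_per_locus`` within-locus breakpoints, with
    geographic labels assigned at random (panmixia, low FST).  Clade B
    ("speciesB", ``n_clonal``) is clonal: one genealogy for every locus,
    with within-clade branch lengths scaled by ``clonal_scale`` (a recent
    clonal expansion -- near-uniform genotypes), all strains MAT1-1 except
    one MAT1-2.  Clade C ("speciesC", ``n_third``) splits from A at
    ``third_divergence``; A+C split from B at ``divergence`` (coalescent
    units above the deeper subtree root).
    """
    if n_recomb < 2 or n_clonal < 2:
        raise ValueError("each main clade needs >= 2 strains")
    rngs = _child_rngs(seed, len(locus_lengths) + 2)
    meta_rng = rngs[-2]
    a_labels = [f"A{i+1:02d}" for i in range(n_recomb)]
    b_labels = [f"B{i+1:02d}" for i in range(n_clonal)]
    c_labels = [f"C{i+1:02d}" for i in range(n_third)]
    labels = a_labels + b_labels + c_labels

    # one shared, shrunken genealogy for the clonal clade
    b_tree_master = sim_coalescent_tree(
        n_clonal, labels=b_labels, rng=rngs[-1], scale=clonal_scale
    )

    loci = []
    genealogies = {}
    for k, L in enumerate(locus_lengths):
        name = _LOCUS_NAMES[k] if k < len(_LOCUS_NAMES) else f"locus{k+1}"
        rng = rngs[k]
        bounds = _segment_bounds(L, breakpoints_per_locus, rng)
        segs = []
        for a, b in bounds:
            a_tree = sim_coalescent_tree(n_recomb, labels=a_labels, rng=rng)
            parts = [(a_tree, 0.0)]
            if n_third >= 2:
                c_tree = sim_coalescent_tree(n_third, labels=c_labels, rng=rng)
                parts.append((c_tree, third_divergence))
            elif n_third == 1:
                lone = Tree(TreeNode(label=c_labels[0]))
                parts.append((lone, third_divergence))
            parts.append((b_tree_master.copy(), divergence))
            segs.append((a, b, _join_species(parts)))
        loci.append(_evolve_segmented(name, L, theta, segs, labels, rng))
        genealogies[name] = [(a, b, t.to_newick()) for a, b, t in segs]

    species = {t: "speciesA" for t in a_labels}
    species.update({t: "speciesB" for t in b_labels})
    species.update({t: "speciesC" for t in c_labels})
    clonal = {t: t in set(b_labels) for t in labels}

    metadata = {}
    for t in labels:
        metadata[t] = {
            "species_label": species[t],
            "geo_group": str(meta_rng.choice(geo_groups)),
            "mating_type": "",
        }
    for t in a_labels:
        metadata[t]["mating_type"] = str(meta_rng.choice(["MAT1-1", "MAT1-2"]))
    # agamospecies signature: a single MAT1-2 strain in the clonal clade
    if b_labels:
        odd = b_labels[int(meta_rng.integers(len(b_labels)))]
        for t in b_labels:
            metadata[t]["mating_type"] = "MAT1-2" if t == odd else "MAT1-1"
    for t in c_labels:
        metadata[t]["mating_type"] = "MAT1-1"

    ds = MultiLocusDataset(labels, loci, metadata)
    truth = SimTruth(
        master_seed=seed if seed is not None else -1,
        params={
            "model": "two_species", "n_recomb": n_recomb, "n_clonal": n_clonal,
            "n_third": n_third, "locus_lengths": list(locus_lengths),
            "theta": theta, "divergence": divergence,
            "third_divergence": third_divergence, "clonal_scale": clonal_scale,
            "breakpoints_per_locus": breakpoints_per_locus,
        },
        species=species,
        clonal=clonal,
        genealogies=genealogies,
    )
    return ds, truth
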