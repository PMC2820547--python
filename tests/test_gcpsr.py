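import numpy as np
import pytest

from clonescan import (
    CladeSet,
    DistanceMatrix,
    bootstrap_support,
    find_nonrecombining_seed,
    gcpsr_recognize,
    nj_tree,
    phi_boundary_expand,
    sim_coalescent_tree,
    sim_two_species,
)
from clonescan.trees import Tree


def _canon(bps, taxa):
    ref = min(taxa)
    return {frozenset(b if ref not in b else set(taxa) - b) for b in bps}


class TestNJ:
    def test_recovers_additive_topology(self):
        tree = sim_coalescent_tree(9, seed=21)
        dm = tree.distance_matrix()
        nj = nj_tree(dm)
        taxa = set(dm.taxa)
        assert _canon(nj.bipartitions(), taxa) == _canon(tree.bipartitions(), taxa)

    def test_matches_scikit_bio_on_additive_metric(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        tree = sim_coalescent_tree(8, seed=11)
        dm = tree.distance_matrix()
        mine = nj_tree(dm)
        sk = sknj(SkDM(dm.d, ids=dm.taxa))
        sk_bp = set()
        for node in sk.non_tips():
            names = frozenset(t.name for t in node.tips())
            if 2 <= len(names) <= len(dm.taxa) - 2:
                sk_bp.add(names)
        taxa = set(dm.taxa)
        assert _canon(mine.bipartitions(), taxa) == _canon(sk_bp, taxa)

    def test_three_taxa_single_topology(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d, "x"))
        assert sorted(tree.leaf_names()) == ["a", "b", "c"]
        assert tree.bipartitions() == {}

    def test_asymmetric_matrix_rejected(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)), "x")
        dm.d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="asymmetric"):
            nj_tree(dm)

    def test_identical_sequence_ties_collapse_to_polytomy(self):
        # NJ must not fabricate resolved clades among identical strains
        from clonescan import LocusAlignment, p_distance

        aln = LocusAlignment(
            "l", ["a", "b", "c", "d", "e"],
            ["AAAA", "AAAA", "AAAA", "AAAA", "TTTT"],
        )
        tree = nj_tree(p_distance(aln))
        assert tree.bipartitions() == {}


class TestBootstrap:
    def test_long_internal_branch_gets_high_support(self):
        from clonescan import evolve_sequences
        from clonescan.trees import TreeNode

        # two well separated pairs of clades built by hand
        left = sim_coalescent_tree(4, seed=1, labels=["a1", "a2", "a3", "a4"])
        right = sim_coalescent_tree(4, seed=2, labels=["b1", "b2", "b3", "b4"])
        root = TreeNode()
        for sub in (left, right):
            sub.root.length = 3.0
            root.add(sub.root)
        tree = Tree(root)
        aln = evolve_sequences(tree, 500, 10.0, seed=3)
        boot = bootstrap_support(aln, n_boot=100, seed=4)
        bp = boot.bipartitions()
        key = frozenset({"b1", "b2", "b3", "b4"})
        taxa = set(aln.taxa)
        ref = min(taxa)
        canon = {frozenset(k if ref not in k else taxa - k): v
                 for k, v in bp.items()}
        want = frozenset(key if ref not in key else taxa - key)
        assert canon[want] >= 0.95

    def test_identical_sequences_have_no_supported_edges(self):
        from clonescan import LocusAlignment

        aln = LocusAlignment("l", ["a", "b", "c", "d"], ["ACGT"] * 4)
        tree = bootstrap_support(aln, n_boot=20, seed=0)
        assert all(n.support is None for n in tree.postorder() if not n.is_leaf)

    def test_same_seed_same_supports(self):
        from clonescan import sim_clonal_dataset

        ds, _ = sim_clonal_dataset(n=8, theta=10, seed=5)
        t1 = bootstrap_support(ds.loci[0], n_boot=50, seed=9)
        t2 = bootstrap_support(ds.loci[0], n_boot=50, seed=9)
        assert t1.to_newick(supports=True) == t2.to_newick(supports=True)


def _clade_set(tree_id, taxa, clades):
    return CladeSet(tree_id, frozenset(taxa), {frozenset(k): v for k, v in clades})


class TestGcpsrRules:
    TAXA = ["a", "b", "c", "d", "e", "f"]

    def test_supported_in_two_trees_recognized(self):
        clade = ("a", "b", "c")
        sets = [
            _clade_set("t1", self.TAXA, [(clade, 0.99)]),
            _clade_set("t2", self.TAXA, [(clade, 0.99)]),
            _clade_set("t3", self.TAXA, []),
        ]
        recognized, partition = gcpsr_recognize(sets)
        assert frozenset(clade) in recognized
        assert {frozenset(b) for b in map(frozenset, partition)} == {
            frozenset({"a", "b", "c"}), frozenset({"d", "e", "f"})}

    def test_single_tree_support_not_recognized(self):
        clade = ("a", "b", "c")
        sets = [
            _clade_set("t1", self.TAXA, [(clade, 0.99)]),
            _clade_set("t2", self.TAXA, []),
        ]
        recognized, _ = gcpsr_recognize(sets)
        assert recognized == {}

    def test_contradicted_clade_not_recognized(self):
        clade = ("a", "b", "c")
        conflict = ("b", "c", "d")  # incompatible with abc|def
        sets = [
            _clade_set("t1", self.TAXA, [(clade, 0.99)]),
            _clade_set("t2", self.TAXA, [(clade, 0.99)]),
            _clade_set("t3", self.TAXA, [(conflict, 0.98)]),
        ]
        recognized, _ = gcpsr_recognize(sets)
        assert frozenset(clade) not in recognized

    def test_low_support_conflict_does_not_contradict(self):
        clade = ("a", "b", "c")
        conflict = ("b", "c", "d")
        sets = [
            _clade_set("t1", self.TAXA, [(clade, 0.99)]),
            _clade_set("t2", self.TAXA, [(clade, 0.96)]),
            _clade_set("t3", self.TAXA, [(conflict, 0.5)]),
        ]
        recognized, _ = gcpsr_recognize(sets)
        assert frozenset(clade) in recognized

    def test_invariant_to_tree_order_and_relabeling(self):
        clade = ("a", "b", "c")
        sets = [
            _clade_set("t1", self.TAXA, [(clade, 0.99)]),
            _clade_set("t2", self.TAXA, [(clade, 0.97)]),
            _clade_set("t3", self.TAXA, []),
        ]
        _, part1 = gcpsr_recognize(sets)
        _, part2 = gcpsr_recognize(list(reversed(sets)))
        assert sorted(map(sorted, part1)) == sorted(map(sorted, part2))
        # bijective relabeling a<->z commutes with recognition
        relabel = {t: ("z" if t == "a" else t) for t in self.TAXA}
        taxa2 = [relabel[t] for t in self.TAXA]
        sets2 = [
            _clade_set("t1", taxa2, [(tuple(relabel[x] for x in clade), 0.99)]),
            _clade_set("t2", taxa2, [(tuple(relabel[x] for x in clade), 0.97)]),
            _clade_set("t3", taxa2, []),
        ]
        _, part3 = gcpsr_recognize(sets2)
        mapped = sorted(sorted(relabel[t] for t in b) for b in part1)
        assert mapped == sorted(map(sorted, part3))

    def test_fewer_than_two_trees_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            gcpsr_recognize([_clade_set("t1", self.TAXA, [])])

    def test_taxa_mismatch_rejected(self):
        with pytest.raises(ValueError, match="different taxa"):
            gcpsr_recognize([
                _clade_set("t1", self.TAXA, []),
                _clade_set("t2", self.TAXA[:-1] + ["zz"], []),
            ])

    def test_recognized_splits_pairwise_compatible(self):
        # nested recognized clades yield a well defined partition
        outer = ("a", "b", "c", "d")
        inner = ("a", "b")
        sets = [
            _clade_set("t1", self.TAXA, [(outer, 0.99), (inner, 0.99)]),
            _clade_set("t2", self.TAXA, [(outer, 0.99), (inner, 0.99)]),
        ]
        recognized, partition = gcpsr_recognize(sets)
        assert frozenset(outer) in recognized and frozenset(inner) in recognized
        assert sorted(map(sorted, partition)) == [
            ["a", "b"], ["c", "d"], ["e", "f"]]


@pytest.fixture(scope="module")
def two_species():
    return sim_two_species(seed=424)


class TestBoundaryExpansion:

    def test_empty_candidates_rejected(self, two_species):
        ds, truth = two_species
        cat = ds.concatenated()
        with pytest.raises(ValueError, match="empty candidate"):
            phi_boundary_expand(cat, ["B01", "B02", "B03", "B04"], {})

    def test_recombining_seed_rejected(self, two_species):
        ds, truth = two_species
        a = sorted(t for t, s in truth.species.items() if s == "speciesA")
        cat = ds.concatenated()
        with pytest.raises(ValueError, match="seed already recombining"):
            phi_boundary_expand(cat, a, {"B": ["B01"]}, n_perm=200, seed=0)

    def test_conspecific_strains_flagged_clonal_outgroup_not(self, two_species):
        """Withheld recombining-clade strains trip the Phi alarm; the clonal
        clade, added afterwards, is never the first to trip it."""
        ds, truth = two_species
        cat = ds.concatenated()
        a = sorted(t for t, s in truth.species.items() if s == "speciesA")
        b = sorted(t for t, s in truth.species.items() if s == "speciesB")
        seed_set = find_nonrecombining_seed(
            cat, a, size=6, seed=7, n_perm=300)
        rest = [t for t in a if t not in seed_set]
        traj = phi_boundary_expand(
            cat, seed_set,
            {"A_rest": rest, "B_clade": b},
            n_perm=300, seed=1,
        )
        assert traj.flagged_group == "A_rest"
        assert len(traj.steps) == 3
        assert traj.steps[0].p_value > 0.05

    def test_clonal_outgroup_added_to_clonal_seed_not_flagged(self):
        """Deep divergence plus homoplasy must not fake a recombination
        signal: two clonal clades joined at depth 2, all loci sharing one
        genealogy, stay non-significant at every expansion step."""
        from clonescan import concatenate, evolve_sequences
        from clonescan.simgen import _join_species

        flagged = 0
        for rep in range(3):
            rng = np.random.default_rng(900 + rep)
            seed_tree = sim_coalescent_tree(6, rng=rng,
                                            labels=[f"S{i}" for i in range(6)])
            out_tree = sim_coalescent_tree(6, rng=rng,
                                           labels=[f"O{i}" for i in range(6)])
            joined = _join_species([(seed_tree, 0.0), (out_tree, 2.0)])
            loci = [
                evolve_sequences(joined, L, 15.0, rng=rng, locus_name=f"l{k}")
                for k, L in enumerate((509, 377, 355))
            ]
            cat = concatenate(loci).concatenated()
            try:
                traj = phi_boundary_expand(
                    cat, [f"S{i}" for i in range(6)],
                    {"outgroup": [f"O{i}" for i in range(6)]},
                    n_perm=300, seed=rep)
            except ValueError:
                continue  # seed below the informative-site floor: no signal
            flagged += traj.flagged_group is not None
        assert flagged == 0

    def test_single_strain_policy_records_each_addition(self, two_species):
        ds, truth = two_species
        cat = ds.concatenated()
        a = sorted(t for t, s in truth.species.items() if s == "speciesA")
        seed_set = find_nonrecombining_seed(cat, a, size=6, seed=7, n_perm=300)
        rest = [t for t in a if t not in seed_set][:3]
        traj = phi_boundary_expand(
            cat, seed_set, {"A_rest": rest}, policy="single",
            n_perm=200, seed=3)
        assert len(traj.steps) == 1 + len(rest)
        assert all(s.added is None or len(s.added) == 1 for s in traj.steps)
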