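import itertools

import numpy as np
import pytest

from clonescan import (
    LocusAlignment,
    concatenate,
    hudson_fst,
    fst_all_pairs,
    ia_test,
    pairwise_incompatibility,
    pht_test,
    phi_test,
    rm_hudson_kaplan,
    sim_clonal_dataset,
    sim_recombining_dataset,
    tajimas_d,
)
from .conftest import aln_from_columns


class TestPairwiseIncompatibility:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("AABB", "ABAB", 1),  # all four gametes: one cycle
            ("AABB", "AABB", 0),  # identical partitions
            ("AACC", "ACAC", 1),  # same graph under different state names
            ("AAAA", "ABAB", 0),  # constant column is always compatible
            ("AABBCC", "ABABAB", 2),  # multistate pair: two independent cycles
        ],
    )
    def test_scores(self, a, b, expected):
        assert pairwise_incompatibility(a, b) == expected

    def test_symmetry(self):
        cols = ["AABB", "ABAB", "ABBA", "AABC"]
        for a, b in itertools.combinations(cols, 2):
            assert pairwise_incompatibility(a, b) == pairwise_incompatibility(b, a)

    def test_missing_dropped_pairwise(self):
        # dropping the last taxon leaves only three gametes -> compatible
        assert pairwise_incompatibility("AAB-", "ABAB") == 0

    def test_too_few_joint_taxa(self):
        with pytest.raises(ValueError, match="jointly"):
            pairwise_incompatibility("A--B", "-AB-")


class TestPhi:
    def test_single_tree_infinite_sites_gives_zero_and_p_one(self):
        # every informative site splits along the same tree -> no homoplasy
        aln = aln_from_columns(
            ["AATT", "AATT", "GGCC", "CCAA", "TTGG", "AAGG"],
            taxa=["a", "b", "c", "d"],
        )
        res = phi_test(aln, n_perm=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_two_block_toy_matches_exhaustive_enumeration(self):
        # two adjacent blocks, internally compatible but mutually incompatible
        taxa = ["a", "b", "c", "d"]
        block1 = ["AAGG"] * 3   # split ab|cd
        block2 = ["AGAG"] * 3   # split ac|bd
        aln = aln_from_columns(block1 + block2, taxa=taxa)
        exact = phi_test(aln, window_w=2, exact_perm=True)
        mc = phi_test(aln, window_w=2, n_perm=2000, seed=4)
        assert exact.statistic == mc.statistic
        # nearby pairs are unusually compatible -> low p under both estimators
        assert exact.p_value < 0.2
        assert abs(mc.p_value - exact.p_value) < 0.05

    def test_requires_informative_sites(self):
        aln = aln_from_columns(["AAAT", "AAAA"], taxa=["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="informative"):
            phi_test(aln)

    def test_window_excluding_all_pairs_is_error(self):
        taxa = ["a", "b", "c", "d"]
        cols = ["AAGG"] + ["AAAA"] * 300 + ["AGAG"]
        aln = aln_from_columns(cols, taxa=taxa)
        with pytest.raises(ValueError, match="window"):
            phi_test(aln, window_w=100)

    def test_reproducible_given_seed(self):
        ds, _ = sim_recombining_dataset(n=10, theta=8, seed=5)
        cat = ds.concatenated()
        r1 = phi_test(cat, n_perm=100, seed=42)
        r2 = phi_test(cat, n_perm=100, seed=42)
        assert (r1.statistic, r1.p_value) == (r2.statistic, r2.p_value)

    def test_analytic_p_reported_alongside(self):
        ds, _ = sim_recombining_dataset(n=10, theta=8, seed=5)
        res = phi_test(ds.concatenated(), n_perm=100, seed=1, analytic=True)
        assert 0.0 <= res.params["p_analytic"] <= 1.0


class TestIA:
    def test_perfect_association_toy_is_exactly_one(self, two_locus_toy):
        res = ia_test(two_locus_toy, n_perm=50, seed=0, clone_correct_first=False)
        assert res.statistic == pytest.approx(1.0)

    def test_brute_force_variance_ratio(self):
        # independent recomputation of V_O and V_E over the 6 strain pairs
        taxa = ["s1", "s2", "s3", "s4"]
        l1 = LocusAlignment("l1", taxa, ["AA", "AA", "TT", "AT"])
        l2 = LocusAlignment("l2", taxa, ["CC", "GG", "CC", "GG"])
        ds = concatenate([l1, l2])
        alleles = {"l1": [0, 0, 1, 2], "l2": [0, 1, 0, 1]}
        dvals, per_locus = [], {"l1": [], "l2": []}
        for i, j in itertools.combinations(range(4), 2):
            d = 0
            for loc in ("l1", "l2"):
                m = int(alleles[loc][i] != alleles[loc][j])
                per_locus[loc].append(m)
                d += m
            dvals.append(d)
        v_o = np.var(dvals)
        v_e = sum(np.var(v) for v in per_locus.values())
        res = ia_test(ds, n_perm=50, seed=0, clone_correct_first=False)
        assert res.statistic == pytest.approx(v_o / v_e - 1)

    def test_null_mean_near_zero_on_random_alleles(self):
        # independently assigned alleles per locus emulate panmixia
        rng = np.random.default_rng(0)
        stats = []
        for rep in range(20):
            taxa = [f"s{i}" for i in range(30)]
            loci = []
            for l in range(3):
                alle = rng.integers(0, 6, size=30)
                seqs = ["ACGTA", "CGTAC", "GTACG", "TACGT", "AAGGT", "CCTTA"]
                loci.append(LocusAlignment(f"l{l}", taxa, [seqs[a] for a in alle]))
            ds = concatenate(loci)
            stats.append(ia_test(ds, n_perm=1, seed=rep,
                                 clone_correct_first=False).statistic)
        assert abs(np.mean(stats)) < 0.05

    def test_single_locus_rejected(self):
        taxa = ["a", "b", "c"]
        ds = concatenate([LocusAlignment("l", taxa, ["AA", "AT", "TT"])])
        with pytest.raises(ValueError, match="loci"):
            ia_test(ds)

    def test_monomorphic_loci_rejected(self):
        taxa = ["a", "b", "c"]
        ds = concatenate([
            LocusAlignment("l1", taxa, ["AA"] * 3),
            LocusAlignment("l2", taxa, ["TT"] * 3),
        ])
        with pytest.raises(ValueError, match="V_E"):
            ia_test(ds, clone_correct_first=False)


class TestPHT:
    def test_exhaustive_toy_p(self, conflicting_loci):
        res = pht_test(conflicting_loci, exhaustive=True)
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.1)
        assert res.n_permutations == 20  # C(6,3) re-partitions

    def test_monte_carlo_within_binomial_ci_of_exhaustive(self, conflicting_loci):
        res = pht_test(conflicting_loci, n_reps=1000, seed=1)
        # 99% binomial CI around 0.1 at 1000 reps ~ +-0.025 (+ add-one shift)
        assert abs(res.p_value - 0.1) < 0.03

    def test_same_tree_loci_usually_not_significant(self):
        ps = []
        for i in range(5):
            ds, _ = sim_clonal_dataset(n=8, locus_lengths=(120, 120), theta=6, seed=60 + i)
            ps.append(pht_test(ds, n_reps=60, seed=i).p_value)
        assert sum(p > 0.05 for p in ps) >= 4

    def test_single_locus_rejected(self):
        taxa = ["a", "b", "c", "d"]
        ds = concatenate([LocusAlignment("l", taxa, ["AA", "AT", "TA", "TT"])])
        with pytest.raises(ValueError, match="loci"):
            pht_test(ds)

    def test_zero_reps_rejected(self, conflicting_loci):
        with pytest.raises(ValueError, match="n_reps"):
            pht_test(conflicting_loci, n_reps=0)


class TestTajimasD:
    def test_hand_computed_value(self):
        aln = LocusAlignment("t", ["a", "b", "c", "d"], ["AA", "AT", "TA", "TT"])
        res = tajimas_d(aln)
        # frozen from an independent evaluation of the coefficient formulas
        assert res.statistic == pytest.approx(1.8931, abs=1e-4)

    def test_no_segregating_sites_flagged_undefined(self):
        res = tajimas_d(LocusAlignment("t", ["a", "b", "c", "d"], ["ACG"] * 4))
        assert res.statistic is None
        assert res.params["undefined"]

    def test_single_singleton_is_negative(self):
        aln = LocusAlignment("t", ["a", "b", "c", "d"], ["AT", "AA", "AA", "AA"])
        assert tajimas_d(aln).statistic < 0


class TestRm:
    def test_four_gamete_pair_gives_one(self):
        aln = aln_from_columns(["AATT", "ATAT"], taxa=["a", "b", "c", "d"])
        assert rm_hudson_kaplan(aln).statistic == 1

    def test_tree_compatible_alignment_gives_zero(self):
        aln = aln_from_columns(["AATT", "AATT", "ATTT"], taxa=["a", "b", "c", "d"])
        assert rm_hudson_kaplan(aln).statistic == 0

    def test_disjoint_intervals_counted(self):
        # incompatible pairs only at (1,5) and (5,9): two disjoint open intervals
        c14 = "AATT"
        c5 = "ATAT"
        c69 = "TTAA"
        filler = "AAAA"
        cols = [c14, filler, filler, c14, c5, filler, filler, filler, c69]
        aln = aln_from_columns(cols, taxa=["a", "b", "c", "d"])
        res = rm_hudson_kaplan(aln)
        assert res.statistic == 2

    def test_multistate_sites_skipped_with_warning(self):
        aln = aln_from_columns(["ACGT", "AATT", "ATAT"], taxa=["a", "b", "c", "d"])
        with pytest.warns(UserWarning, match="skipped"):
            res = rm_hudson_kaplan(aln)
        assert res.statistic == 1


class TestFst:
    def test_brute_force_two_population_value(self):
        aln = LocusAlignment("f", ["a", "b", "c", "d"],
                             ["AAAA", "AAAT", "TTTA", "TTTT"])
        res = hudson_fst(aln, ["p1", "p1", "p2", "p2"])
        assert res.statistic == pytest.approx(1 - 1 / 3.5)

    def test_fixed_difference_gives_one(self):
        aln = LocusAlignment("f", ["a", "b", "c", "d"],
                             ["AAAA", "AAAA", "TTTT", "TTTT"])
        assert hudson_fst(aln, ["p1", "p1", "p2", "p2"]).statistic == 1.0

    def test_identical_monomorphic_groups_error(self):
        aln = LocusAlignment("f", ["a", "b", "c", "d"], ["AAAA"] * 4)
        with pytest.raises(ValueError, match="indistinguishable"):
            hudson_fst(aln, ["p1", "p1", "p2", "p2"])

    def test_singleton_group_warns(self):
        aln = LocusAlignment("f", ["a", "b", "c"], ["AAAA", "AAAT", "TTTT"])
        with pytest.warns(UserWarning, match="within"):
            res = hudson_fst(aln, ["p1", "p1", "p2"])
        assert res.p_value is None

    def test_random_split_of_panmictic_sample_near_zero(self):
        ds, _ = sim_recombining_dataset(n=50, theta=15, seed=9)
        cat = ds.concatenated()
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(5):
            labels = ["p1"] * 25 + ["p2"] * 25
            labels = [labels[i] for i in rng.permutation(50)]
            vals.append(hudson_fst(cat, labels).statistic)
        assert abs(np.median(vals)) < 0.05

    def test_all_pairs_table(self):
        aln = LocusAlignment("f", ["a", "b", "c", "d", "e", "f"],
                             ["AAAA", "AAAT", "TTTA", "TTTT", "ATAT", "ATTT"])
        meta = {t: {"geo_group": g} for t, g in
                zip(aln.taxa, ["x", "x", "y", "y", "z", "z"])}
        table = fst_all_pairs(aln, meta)
        assert len(table) == 3
        assert set(table.columns) == {"group_a", "group_b", "fst", "n_a", "n_b"}
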