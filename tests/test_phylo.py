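"""Tree machinery: NJ exactness on additive matrices, bootstrap
behavior, and the per-locus screening filters."""

import numpy as np
import pytest

import hgtscreen as hs
from hgtscreen.io_formats import SequenceRecord
from hgtscreen.kaks import CodonAlignment
from hgtscreen.phylo import (
    Tree,
    bootstrap_support,
    branch_length_filter,
    distance_matrix,
    ks_filter,
    neighbor_joining,
    placement_test,
)
from conftest import random_sense_codons


def random_additive(rng, n_tips, prefix="t"):
    """Random binary tree and its exact additive distance matrix."""
    names = [f"{prefix}{i}" for i in range(n_tips)]

    def grow(lo, hi):
        if hi - lo == 1:
            return f"{names[lo]}:{rng.uniform(0.1, 1.0):.6f}"
        k = int(rng.integers(lo + 1, hi))
        return f"({grow(lo, k)},{grow(k, hi)}):{rng.uniform(0.1, 1.0):.6f}"

    text = grow(0, n_tips).rsplit(":", 1)[0] + ";"
    tree = Tree.from_newick(text)
    M = np.zeros((n_tips, n_tips))
    for i in range(n_tips):
        for j in range(i + 1, n_tips):
            M[i, j] = M[j, i] = tree.patristic(names[i], names[j])
    return tree, M, names


class TestNeighborJoining:
    def test_exact_on_known_additive_matrix(self):
        # matrix realized by ((A:1,B:2):1,(C:3,D:4):0)
        truth = Tree.from_newick("((A:1,B:2):1,(C:3,D:4):0);")
        names = list("ABCD")
        M = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                M[i, j] = M[j, i] = truth.patristic(names[i], names[j])
        nj = neighbor_joining(M, names)
        assert nj.same_topology(truth)
        # four-point condition: patristic distances reproduced exactly
        for i in range(4):
            for j in range(i + 1, 4):
                assert nj.patristic(names[i], names[j]) == pytest.approx(
                    M[i, j], abs=1e-10
                )

    def test_three_taxa_closed_form(self):
        M = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = neighbor_joining(M, list("ABC"))
        lens = {n.name: n.length for n in t.tips()}
        assert lens["A"] == pytest.approx(1.0)
        assert lens["B"] == pytest.approx(2.0)
        assert lens["C"] == pytest.approx(3.0)

    @pytest.mark.parametrize("n_tips", [4, 5, 6, 7, 8])
    def test_recovers_random_additive_trees(self, n_tips):
        rng = np.random.default_rng(100 + n_tips)
        for _ in range(20):
            truth, M, names = random_additive(rng, n_tips)
            nj = neighbor_joining(M, names)
            assert nj.same_topology(truth)

    def test_masked_entries_refused(self):
        M = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError, match="saturated"):
            neighbor_joining(M, list("ABC"))

    def test_negative_estimates_clamped(self):
        # a non-additive matrix that drives a branch estimate negative
        M = np.array(
            [[0, 0.1, 1, 1], [0.1, 0, 1, 1.4], [1, 1, 0, 0.1], [1, 1.4, 0.1, 0]]
        )
        t = neighbor_joining(M, list("ABCD"))
        assert all((n.length or 0) >= 0 for n in t.postorder())


class TestDistanceMatrix:
    def _aln_from_sim(self, seed=2):
        cfg = hs.SimConfig(
            seed=seed,
            host_tree="((A:0.05,B:0.05)x:0.1,(C:0.05,D:0.05)y:0.1)hostroot;",
            outer_tree="(hosts:0.0,(outgroup:0.01,parasite:0.01)op:0.01)root;",
            n_families=1,
            rate_range=(1.0, 1.0),
        )
        data = hs.simulate_dataset(cfg)
        fam = data.families[0]
        taxa = ["A", "B", "C", "D"]
        return CodonAlignment(taxa, [fam.cds(t) for t in taxa])

    def test_symmetry_zero_diagonal(self):
        aln = self._aln_from_sim()
        M = distance_matrix(aln, metric="ks")
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0.0)

    def test_identical_sequences_zero_matrix(self, rng):
        s = random_sense_codons(rng, 50)
        aln = CodonAlignment(["a", "b", "c"], [s, s, s])
        assert np.allclose(distance_matrix(aln, "ks"), 0.0)

    def test_matches_generating_tree_on_average(self):
        # mean pairwise Ks across replicate families tracks the true path
        # length on the generating tree
        pairs = {("A", "B"): 0.1, ("A", "C"): 0.3, ("C", "D"): 0.1}
        sums = {k: [] for k in pairs}
        for seed in range(40):
            aln = self._aln_from_sim(seed)
            M = distance_matrix(aln, "ks")
            idx = {t: i for i, t in enumerate(aln.taxa)}
            for (a, b) in pairs:
                sums[(a, b)].append(M[idx[a], idx[b]])
        for (a, b), want in pairs.items():
            vals = np.asarray(sums[(a, b)])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - want) < 3 * se + 0.01


class TestBootstrap:
    def _aln(self, n_codons=300, seed=5):
        cfg = hs.SimConfig(
            seed=seed,
            host_tree="((A:0.1,B:0.1)x:0.15,(C:0.1,D:0.1)y:0.15)hostroot;",
            outer_tree="(hosts:0.0,(outgroup:0.01,parasite:0.01)op:0.01)root;",
            n_families=1,
            n_codons=n_codons,
            rate_range=(1.0, 1.0),
        )
        data = hs.simulate_dataset(cfg)
        fam = data.families[0]
        taxa = ["A", "B", "C", "D"]
        return CodonAlignment(taxa, [fam.cds(t) for t in taxa])

    def test_long_congruent_alignment_high_support(self):
        aln = self._aln(n_codons=1000)
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        sups = [
            n.support
            for n in tree.postorder()
            if n.support is not None and n.parent is not None
        ]
        assert sups and min(sups) >= 95.0

    def test_single_replicate_support_extremes(self):
        aln = self._aln()
        tree = bootstrap_support(aln, n_reps=1, seed=3)
        for n in tree.postorder():
            if n.support is not None:
                assert n.support in (0.0, 100.0)

    def test_same_seed_identical(self):
        aln = self._aln()
        t1 = bootstrap_support(aln, n_reps=25, seed=7)
        t2 = bootstrap_support(aln, n_reps=25, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_nonpositive_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._aln(), n_reps=0, seed=1)


class TestBranchLengthFilter:
    TREE = "(((P:{p},H1:0.1):0.05,H2:0.2):0.05,(H3:0.1,O:0.5):0.05);"

    def _tree(self, p):
        return Tree.from_newick(self.TREE.format(p=p))

    def test_long_external_branch_fails(self):
        t = Tree.from_newick("((P:0.5,H1:0.1):0.1,(H2:0.2,H3:0.05):0.1);")
        passed, res = branch_length_filter(t, "P", ["H1", "H2", "H3"])
        # longest host edge is 0.2; 0.5 > 2 x 0.2
        assert res.longest_host_branch == pytest.approx(0.2)
        assert not passed

    def test_short_external_branch_passes(self):
        t = Tree.from_newick("((P:0.39,H1:0.1):0.1,(H2:0.2,H3:0.05):0.1);")
        passed, _ = branch_length_filter(t, "P", ["H1", "H2", "H3"])
        assert passed

    def test_exactly_twice_passes(self):
        t = Tree.from_newick("((P:0.4,H1:0.1):0.1,(H2:0.2,H3:0.05):0.1);")
        passed, res = branch_length_filter(t, "P", ["H1", "H2", "H3"])
        assert res.external_branch_len == pytest.approx(0.4)
        assert passed  # strict '>' comparison

    def test_missing_parasite_tip_rejected(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.raises(KeyError):
            branch_length_filter(t, "P", ["A", "B"])


class TestKsFilter:
    def _host(self, rng, base, n_sub):
        seq = list(base)
        # synonymous-ish random substitutions
        idx = rng.choice(len(base) // 3, size=n_sub, replace=False)
        from hgtscreen._codon import CODONS, SENSE

        for k in idx:
            seq[3 * k : 3 * k + 3] = CODONS[SENSE[rng.integers(0, 61)]]
        return "".join(seq)

    def test_closest_host_below_threshold_passes(self, rng):
        base = random_sense_codons(rng, 200)
        par = SequenceRecord("P", "parasite", base)
        near = SequenceRecord("H1|g", "H1", self._host(rng, base, 20))
        far = SequenceRecord("H2|g", "H2", self._host(rng, base, 60))
        passed, closest, res = ks_filter(par, [far, near])
        assert passed and closest == "H1|g"
        assert res.Ks < 1

    def test_all_saturated_fails(self):
        # every codon differs synonymously at a saturating fraction:
        # Leu CTA vs CTG gives pS = 1/(4/3) = 0.75, the JC boundary
        par = SequenceRecord("P", "parasite", "CTA" * 150)
        other = SequenceRecord("H1|g", "H1", "CTG" * 150)
        passed, closest, res = ks_filter(par, [other])
        assert not passed and closest is None and res is None


class TestPlacement:
    def test_parasite_inside_host_clade(self):
        t = Tree.from_newick("(Out,(H1,(H2,Par)));")
        res = placement_test(t, "Par", ["H1", "H2"], ["Out"])
        assert res.nested_in_host_clade

    def test_vertical_pattern(self):
        t = Tree.from_newick("((Out,Par),(H1,H2));")
        res = placement_test(t, "Par", ["H1", "H2"], ["Out"])
        assert not res.nested_in_host_clade

    def test_sister_to_whole_host_clade_counts(self):
        t = Tree.from_newick("(Out,(Par,(H1,H2)));")
        res = placement_test(t, "Par", ["H1", "H2"], ["Out"])
        assert res.nested_in_host_clade

    def test_unrooted_tree_rooted_on_outgroup(self):
        t = Tree.from_newick("(H1,(H2,Par),Out);")
        res = placement_test(t, "Par", ["H1", "H2"], ["Out"])
        assert res.nested_in_host_clade

    def test_missing_outgroup_unrootable(self):
        t = Tree.from_newick("((H1,Par),(H2,H3));")
        with pytest.raises(ValueError, match="outgroup"):
            placement_test(t, "Par", ["H1", "H2", "H3"], ["Out"])
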