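"""Single-copy selection, JC distances, NJ reconstruction, dating."""

import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from panclade import (
    InputError,
    calibrate_ages,
    distance_matrix,
    nj_tree,
    select_single_copy,
)
from panclade.pav import GeneFamily
from panclade.phylo import SingleCopySet, jc_correct, leaf_sets
from panclade.simulate import node_ages, simulate_sequences, yule_tree


def _patristic_matrix(tree):
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {x.label: x for x in tree.taxon_namespace}
    pdm = tree.phylogenetic_distance_matrix()
    m = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        d = pdm.patristic_distance(taxa[a], taxa[b])
        m.loc[a, b] = m.loc[b, a] = d
    return m


def _unrooted_rf(t1, t2):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=t1.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    b = dendropy.Tree.get(data=t2.as_string(schema="newick"), schema="newick",
                          taxon_namespace=tns)
    a.is_rooted = b.is_rooted = False
    a.update_bipartitions()
    b.update_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestSingleCopy:
    def test_absent_and_duplicated_families_excluded(self):
        fams = [
            GeneFamily("f1", [("a", "a1"), ("b", "b1")]),          # complete
            GeneFamily("f2", [("a", "a2")]),                        # absent in b
            GeneFamily("f3", [("a", "a3"), ("a", "a4"), ("b", "b3")]),  # dup
        ]
        scs = select_single_copy(fams, ["a", "b"])
        assert scs.families == ["f1"]

    def test_no_qualifying_families_is_an_error(self):
        with pytest.raises(InputError, match="relax"):
            select_single_copy([GeneFamily("f", [("a", "x")])], ["a", "b"])

    def test_loss_free_simulation_selects_all_ancestral(self, two_leaf_sv_sim):
        from panclade import cluster_gene_families

        sim = two_leaf_sv_sim  # no gains/losses planted
        fams = cluster_gene_families(sim.cds_sequences())
        scs = select_single_copy(fams, sorted(sim.genomes))
        assert len(scs.families) == len(fams)


class TestDistances:
    def test_identical_sequences_zero(self):
        scs = SingleCopySet(["f"], {"f": {"a": "ACGT" * 50, "b": "ACGT" * 50}},
                            ["a", "b"])
        dm = distance_matrix(scs)
        assert dm.loc["a", "b"] == 0.0

    def test_jc_closed_form(self):
        assert jc_correct(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))

    def test_saturated_distance_hits_ceiling(self):
        with pytest.warns(UserWarning, match="ceiling"):
            assert jc_correct(0.8) == 5.0

    def test_two_leaf_generative_recovery(self):
        """Estimated distance within 3 SE of 2rt on repeated simulations."""
        r, t, L, n_loci = 0.05, 1.0, 400, 60
        est = []
        for seed in range(30):
            _, seqs = simulate_sequences(f"(a:{t},b:{t});", n_loci, L, r, seed)
            scs = SingleCopySet(
                [f"f{i}" for i in range(n_loci)],
                {f"f{i}": {g: seqs[g][i] for g in seqs} for i in range(n_loci)},
                ["a", "b"],
            )
            est.append(distance_matrix(scs).loc["a", "b"])
        expected = 2 * r * t
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - expected) < 3 * se + 1e-4

    def test_invariant_to_genome_order(self):
        rng = np.random.default_rng(0)
        _, seqs = simulate_sequences("(a:0.2,(b:0.1,c:0.1):0.1);", 10, 200, 0.05, 3)
        fams = [f"f{i}" for i in range(10)]
        s1 = SingleCopySet(fams, {f: {g: seqs[g][i] for g in ["a", "b", "c"]}
                                  for i, f in enumerate(fams)}, ["a", "b", "c"])
        s2 = SingleCopySet(fams, {f: {g: seqs[g][i] for g in ["c", "a", "b"]}
                                  for i, f in enumerate(fams)}, ["c", "a", "b"])
        assert distance_matrix(s1).equals(distance_matrix(s2))


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # ((a:2,b:3):1,(c:4,d:5):1) patristic distances, hand-checkable
        m = pd.DataFrame(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        tree = nj_tree(m, outgroup="d")
        sets = set(leaf_sets(tree).values())
        assert frozenset({"a", "b"}) in sets
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.taxon_namespace}
        for a, b in itertools.combinations("abcd", 2):
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                m.loc[a, b]
            )

    def test_two_leaves_split_evenly(self):
        m = pd.DataFrame([[0, 4], [4, 0]], index=["a", "b"],
                         columns=["a", "b"], dtype=float)
        tree = nj_tree(m, outgroup="a")
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": pytest.approx(2.0), "b": pytest.approx(2.0)}

    def test_additive_fuzz_recovers_topology(self):
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 13))
            t = yule_tree(n, 1.0, rng)
            for node in t.preorder_node_iter():  # break ultrametry
                if node.edge.length is not None:
                    node.edge.length += float(rng.uniform(0, 0.5))
            m = _patristic_matrix(t)
            tree = nj_tree(m, outgroup=m.index[0])
            assert _unrooted_rf(t, tree) == 0

    def test_asymmetric_matrix_rejected(self):
        m = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"],
                         columns=["a", "b"], dtype=float)
        with pytest.raises(InputError):
            nj_tree(m, outgroup="a")

    def test_unknown_outgroup_rejected(self):
        m = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"],
                         columns=["a", "b"], dtype=float)
        with pytest.raises(InputError):
            nj_tree(m, outgroup="z")


class TestCalibration:
    def _tree(self):
        m = _patristic_matrix(yule_tree(6, 1.0, np.random.default_rng(5)))
        return nj_tree(m, outgroup=m.index[0])

    def test_root_calibration_sets_root_age(self):
        cal = calibrate_ages(self._tree(), "root", 42.0)
        assert cal.ages["root"] == pytest.approx(42.0)

    def test_ultrametric_within_tolerance(self):
        cal = calibrate_ages(self._tree(), "root", 10.0)
        depths = []
        for leaf in cal.tree.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length
                node = node.parent_node
            depths.append(d)
        assert np.ptp(depths) < 1e-9 * 10.0
        ages = cal.ages
        for node in cal.tree.preorder_node_iter():
            if node.parent_node is not None:
                assert ages[node.label] <= ages[node.parent_node.label] + 1e-12

    def test_rescaling_preserves_relative_depths(self):
        tree = self._tree()
        c1 = calibrate_ages(tree, "root", 10.0)
        internal = [
            lab for lab, s in leaf_sets(tree).items()
            if 1 < len(s) < len(c1.ages)
        ]
        target = internal[0]
        c2 = calibrate_ages(tree, target, c1.ages[target] * 2)
        for lab in internal:
            assert c2.ages[lab] == pytest.approx(c1.ages[lab] * 2)

    def test_nonpositive_age_rejected(self):
        with pytest.raises(InputError):
            calibrate_ages(self._tree(), "root", 0.0)

    def test_leaf_calibration_rejected(self):
        tree = self._tree()
        leaf = next(iter(tree.leaf_node_iter())).taxon.label
        with pytest.raises(InputError):
            calibrate_ages(tree, leaf, 5.0)


class TestCladeRecovery:
    def test_planted_two_clade_design_is_monophyletic(self):
        """An ingroup split into A-like and D-like subclades keeps the
        D-like leaves monophyletic in the inferred tree."""
        newick = ("(out:0.5,((a1:0.1,a2:0.1):0.25,(d1:0.15,(d2:0.1,"
                  "(d3:0.05,d4:0.05):0.05):0.05):0.2):0.15);")
        _, seqs = simulate_sequences(newick, 100, 300, 0.05, 17)
        fams = [f"f{i}" for i in range(100)]
        scs = SingleCopySet(
            fams,
            {f: {g: seqs[g][i] for g in seqs} for i, f in enumerate(fams)},
            list(seqs),
        )
        tree = nj_tree(distance_matrix(scs), outgroup="out")
        assert frozenset({"d1", "d2", "d3", "d4"}) in set(leaf_sets(tree).values())
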