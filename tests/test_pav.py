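"""Pan-genome clustering, occupancy partition, accumulation, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import comb

from panclade import (
    InputError,
    PAVMatrix,
    accumulation_curves,
    build_pav_matrix,
    classify_occupancy,
    cluster_gene_families,
    cluster_genomes_by_pav,
    enrich_terms,
    family_rand_index,
)
from panclade.pav import pav_linkage
from panclade._util import random_dna


class TestClustering:
    def test_identical_copies_form_one_family(self):
        seq = random_dna(np.random.default_rng(0), 300)
        fams = cluster_gene_families({g: {"x": seq} for g in "abc"})
        assert len(fams) == 1 and fams[0].occupancy == 3

    def test_disjoint_kmers_stay_separate(self):
        fams = cluster_gene_families({"a": {"x": "A" * 100}, "b": {"y": "C" * 100}})
        assert len(fams) == 2
        assert all(f.occupancy == 1 for f in fams)

    def test_duplicate_gene_id_rejected(self):
        with pytest.raises(InputError):
            cluster_gene_families({"a": [("x", "ACGT" * 10), ("x", "ACGT" * 10)]})

    def test_empty_input_gives_empty_families(self):
        assert cluster_gene_families({}) == []

    def test_zero_substitution_truth_recovery_is_exact(self, small_clade_sim):
        # substitutions present but mild: families must still match truth
        fams = cluster_gene_families(small_clade_sim.cds_sequences())
        assert family_rand_index(fams, small_clade_sim.truth.gene_families) == 1.0


class TestOccupancyPartition:
    def test_all_ones_matrix_is_core(self):
        pm = PAVMatrix(pd.DataFrame(np.ones((5, 4), dtype=int),
                                    index=[f"f{i}" for i in range(5)],
                                    columns=list("abcd")))
        assert classify_occupancy(pm) == {"core": 5, "variable": 0,
                                          "specific": 0, "total": 5}

    def test_identity_matrix_is_specific(self):
        pm = PAVMatrix(pd.DataFrame(np.eye(4, dtype=int),
                                    index=list("wxyz"), columns=list("abcd")))
        assert classify_occupancy(pm) == {"core": 0, "variable": 0,
                                          "specific": 4, "total": 4}

    def test_zero_occupancy_row_rejected(self):
        pm = PAVMatrix(pd.DataFrame([[1, 1], [0, 0]], columns=["a", "b"]))
        with pytest.raises(InputError):
            classify_occupancy(pm)

    @given(st.integers(2, 6), st.integers(1, 30), st.integers(0, 10**6))
    def test_partition_sums_to_total(self, n_genomes, n_fams, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=(n_fams, n_genomes))
        m[m.sum(axis=1) == 0, 0] = 1
        pm = PAVMatrix(pd.DataFrame(m, columns=[f"g{i}" for i in range(n_genomes)]))
        c = classify_occupancy(pm)
        assert c["core"] + c["variable"] + c["specific"] == c["total"] == n_fams


class TestAccumulation:
    def _matrix(self, rows, genomes):
        return PAVMatrix(pd.DataFrame(rows, columns=genomes))

    def test_identical_genomes_flat_curves(self):
        pm = self._matrix(np.ones((7, 4), dtype=int), list("abcd"))
        acc = accumulation_curves(pm, n_orderings=10, seed=0)
        assert (acc.pan_mean == 7).all() and (acc.core_mean == 7).all()
        assert (acc.pan_sd == 0).all()

    def test_k1_equals_mean_genome_size(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 2, size=(40, 5))
        m[m.sum(axis=1) == 0, 0] = 1
        pm = self._matrix(m, [f"g{i}" for i in range(5)])
        acc = accumulation_curves(pm, n_orderings="all")
        assert acc.pan_mean[0] == pytest.approx(m.sum(axis=0).mean())
        assert acc.core_mean[0] == pytest.approx(m.sum(axis=0).mean())

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 2, size=(30, 4))
        m[m.sum(axis=1) == 0, 0] = 1
        pm = self._matrix(m, list("abcd"))
        acc = accumulation_curves(pm, n_orderings="all")
        # independent brute force with python sets
        sets = [frozenset(np.nonzero(m[:, j])[0]) for j in range(4)]
        for k in range(1, 5):
            pans, cores = [], []
            for perm in itertools.permutations(range(4)):
                chosen = [sets[j] for j in perm[:k]]
                pans.append(len(frozenset().union(*chosen)))
                cores.append(len(frozenset.intersection(*chosen)))
            assert acc.pan_mean[k - 1] == pytest.approx(np.mean(pans))
            assert acc.core_mean[k - 1] == pytest.approx(np.mean(cores))
            assert acc.pan_sd[k - 1] == pytest.approx(np.std(pans))

    @given(st.integers(0, 10**6))
    def test_monotone_along_orderings(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=(25, 5))
        m[m.sum(axis=1) == 0, 0] = 1
        pm = self._matrix(m, [f"g{i}" for i in range(5)])
        acc = accumulation_curves(pm, n_orderings=5, seed=seed % 1000)
        assert (np.diff(acc.pan_mean) >= -1e-9).all()
        assert (np.diff(acc.core_mean) <= 1e-9).all()

    def test_endpoints_match_partition(self, small_clade_sim):
        fams = cluster_gene_families(small_clade_sim.cds_sequences())
        pm = build_pav_matrix(fams, sorted(small_clade_sim.genomes))
        counts = classify_occupancy(pm)
        acc = accumulation_curves(pm, n_orderings=20, seed=1)
        assert acc.pan_mean.iloc[-1] == counts["total"]
        assert acc.core_mean.iloc[-1] == counts["core"]


class TestGenomeClustering:
    def test_identical_genomes_at_distance_zero(self):
        pm = PAVMatrix(pd.DataFrame([[1, 1, 0], [1, 1, 1], [0, 0, 1]],
                                    columns=list("abc")))
        z, labels = pav_linkage(pm)
        assert labels == ["a", "b", "c"]
        assert z[0][2] == pytest.approx(0.0)

    def test_jaccard_distance_hand_computed(self):
        # columns (1,1,0,0) vs (1,0,1,0): |intersection|=1, |union|=3
        pm = PAVMatrix(pd.DataFrame({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]}))
        z, _ = pav_linkage(pm)
        assert z[0][2] == pytest.approx(2 / 3)

    def test_newick_contains_all_genomes(self, small_clade_sim):
        fams = cluster_gene_families(small_clade_sim.cds_sequences())
        pm = build_pav_matrix(fams, sorted(small_clade_sim.genomes))
        nwk = cluster_genomes_by_pav(pm)
        for g in small_clade_sim.genomes:
            assert g in nwk

    def test_single_genome_rejected(self):
        pm = PAVMatrix(pd.DataFrame({"a": [1, 1]}))
        with pytest.raises(InputError):
            cluster_genomes_by_pav(pm)


class TestEnrichment:
    def test_term_covering_background_has_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        ann = {g: ["T"] for g in bg}
        res = enrich_terms(bg[:4], ann, bg)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_exact_hypergeometric_tail(self):
        bg = [f"g{i}" for i in range(10)]
        ann = {g: ["T"] for g in bg[:5]}
        res = enrich_terms(bg[:4], ann, bg)
        # all 4 drawn from the 5 annotated: p = C(5,4)*C(5,0)/C(10,4)
        assert res.loc[0, "p"] == pytest.approx(comb(5, 4) / comb(10, 4))

    def test_gene_outside_background_rejected(self):
        with pytest.raises(InputError):
            enrich_terms(["z"], {"a": ["T"]}, ["a", "b"])

    def test_empty_set_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            res = enrich_terms([], {"a": ["T"]}, ["a"])
        assert res.empty

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(4)
        bg = [f"g{i}" for i in range(40)]
        ann = {}
        for t in range(8):
            for g in rng.choice(bg, size=rng.integers(3, 20), replace=False):
                ann.setdefault(g, []).append(f"T{t}")
        res = enrich_terms(list(rng.choice(bg, 12, replace=False)), ann, bg)
        by_p = res.sort_values("p")
        assert (np.diff(by_p["q"].to_numpy()) >= -1e-12).all()
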