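"""Simulator: determinism, event bookkeeping, truth serialization."""

import numpy as np
import pytest
from scipy import stats

from panclade import (
    ConfigurationError,
    GenerationError,
    SimConfig,
    emit_fixtures,
    read_fixtures,
    simulate_clade,
)
from panclade.simulate import (
    TruthSet,
    PromoterIndel,
    mutate_jc,
    node_ages,
    parse_tree,
    promoter_sequence,
    yule_tree,
)


def _zero_cfg(**kw):
    base = dict(tree="(x:0.1,y:0.1,z:0.1);", n_chromosomes=2,
                genes_per_chromosome=8, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestZeroRateIdentity:
    def test_leaves_match_ancestor_byte_for_byte(self, tmp_path):
        sim = simulate_clade(_zero_cfg(), out_dir=tmp_path)
        anc_fa = (tmp_path / "ancestor.fa").read_text()
        for leaf in ("x", "y", "z"):
            assert (tmp_path / f"{leaf}.fa").read_text() == anc_fa

    def test_gene_content_and_order_identical(self):
        sim = simulate_clade(_zero_cfg())
        anc = [(g.family, g.chrom, g.rank) for g in sim.ancestor.genes()]
        for g in sim.genomes.values():
            assert [(x.family, x.chrom, x.rank) for x in g.genes()] == anc


class TestDeterminism:
    def test_same_seed_identical_outputs(self, tmp_path):
        cfg = dict(tree="(x:0.3,y:0.3);", n_chromosomes=2,
                   genes_per_chromosome=10, rate_gene_gain=5.0,
                   rate_gene_loss=3.0, rate_inversion=1.0,
                   sv_rates={"deletion": 3.0}, substitution_rate=0.02, seed=9)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        s1 = simulate_clade(SimConfig(**cfg), out_dir=d1)
        s2 = simulate_clade(SimConfig(**cfg), out_dir=d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()
        assert s1.truth == s2.truth

    def test_realized_inversions_recorded_exactly(self):
        cfg = SimConfig(tree="(x:1.0,y:1.0);", n_chromosomes=2,
                        genes_per_chromosome=15, rate_inversion=2.0, seed=4)
        s1 = simulate_clade(cfg)
        s2 = simulate_clade(cfg)
        inv1 = [e for e in s1.truth.rearrangement_events if e.kind == "inversion"]
        inv2 = [e for e in s2.truth.rearrangement_events if e.kind == "inversion"]
        assert inv1 == inv2
        assert all(e.branch in ("x", "y") for e in inv1)


class TestEventSampling:
    def test_deletion_counts_follow_poisson(self):
        """Realized per-branch deletion counts over 200 replicates match
        direct Poisson sampling (3 SE on the mean, chi-square GoF)."""
        mean = 20.0
        counts = []
        for seed in range(200):
            cfg = SimConfig(tree="(x:1.0,y:1.0);", n_chromosomes=1,
                            genes_per_chromosome=25, intergenic_bp=3000,
                            sv_rates={"deletion": mean},
                            sv_size_range=(50, 60), seed=seed)
            sim = simulate_clade(cfg)
            per_branch = {"x": 0, "y": 0}
            for e in sim.truth.sv_events:
                per_branch[e.branch] += 1
            counts.extend(per_branch.values())
        counts = np.asarray(counts)
        se = np.sqrt(mean / len(counts))
        assert abs(counts.mean() - mean) < 3 * se
        # chi-square against Poisson(20) with pooled tails
        edges = [0, 14, 17, 20, 23, 26, 1000]
        obs = np.histogram(counts, bins=edges)[0]
        probs = np.diff([stats.poisson.cdf(e - 1, mean) for e in edges])
        chi = stats.chisquare(obs, probs * len(counts))
        assert chi.pvalue > 0.01

    def test_gene_count_bookkeeping(self, small_clade_sim):
        sim = small_clade_sim
        anc_count = sum(1 for _ in sim.ancestor.genes())
        by_branch = {}
        for e in sim.truth.family_events:
            by_branch.setdefault(e.branch, []).append(e.kind)
        for leaf, genome in sim.genomes.items():
            gains = losses = 0
            for b in sim.truth.leaf_paths[leaf]:
                kinds = by_branch.get(b, [])
                gains += kinds.count("gain")
                losses += kinds.count("loss")
            assert sum(1 for _ in genome.genes()) == anc_count + gains - losses


class TestErrors:
    def test_single_leaf_tree_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_clade(SimConfig(tree="(x:1.0);", seed=1))

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(rate_inversion=-1.0).validate()

    def test_sv_floor_enforced(self):
        with pytest.raises(ConfigurationError):
            SimConfig(sv_size_range=(10, 100)).validate()

    def test_unhostable_sv_names_branch(self):
        cfg = SimConfig(tree="(x:1.0,y:1.0);", n_chromosomes=1,
                        genes_per_chromosome=2, intergenic_bp=300,
                        sv_rates={"deletion": 5.0}, sv_size_range=(290, 300),
                        seed=2)
        with pytest.raises(GenerationError, match="branch"):
            simulate_clade(cfg)


class TestSubstitutionModel:
    def test_jc_expected_divergence(self):
        rng = np.random.default_rng(0)
        seq = "A" * 100000
        mu = 0.1
        out = mutate_jc(seq, mu, rng)
        p_obs = sum(a != b for a, b in zip(seq, out)) / len(seq)
        p_exp = 0.75 * (1 - np.exp(-4 * mu / 3))
        assert abs(p_obs - p_exp) < 0.005


class TestTrees:
    def test_yule_tree_is_ultrametric_with_requested_depth(self):
        rng = np.random.default_rng(1)
        t = yule_tree(9, 2.5, rng)
        ages = node_ages(t)
        assert ages["root"] == pytest.approx(2.5)
        assert all(ages[l.label] == pytest.approx(0.0, abs=1e-9)
                   for l in t.leaf_node_iter())

    def test_branch_lengths_required(self):
        with pytest.raises(ConfigurationError):
            parse_tree("(a,b);")


class TestPromoter:
    def test_planted_deletion_shortens_promoter(self):
        cfg = SimConfig(tree="(x:0.1,y:0.1);", n_chromosomes=1,
                        genes_per_chromosome=5,
                        promoter_deletion_spec=[(("y",), "fam00003", 444, 800)],
                        seed=6)
        sim = simulate_clade(cfg)
        px = promoter_sequence(sim.genomes["x"], "fam00003", 2500)
        py = promoter_sequence(sim.genomes["y"], "fam00003", 2500)
        assert len(sim.truth.promoter_indels) == 1
        rec = sim.truth.promoter_indels[0]
        assert (rec.genome, rec.length, rec.offset) == ("y", 444, 800)
        assert rec.gene_id
        # the deleted window is absent from y's promoter
        assert px[-800:] == py[-800:]
        assert px[-(800 + 444 + 100):-(800 + 444)] == py[-(800 + 100):-800]


class TestFixtures:
    def test_round_trip_identity(self, two_leaf_sv_sim, tmp_path):
        truth = two_leaf_sv_sim.truth
        manifest = emit_fixtures(truth, tmp_path)
        assert set(manifest["files"])
        assert read_fixtures(tmp_path) == truth

    def test_empty_truth_set(self, tmp_path):
        manifest = emit_fixtures(TruthSet(), tmp_path)
        back = read_fixtures(tmp_path)
        assert back.sv_events == [] and back.family_events == []
        assert "manifest" not in manifest["files"]

    def test_single_444_promoter_row(self, tmp_path):
        truth = TruthSet(promoter_indels=[PromoterIndel("g1", "g1_g1", "f", 444, 800)])
        emit_fixtures(truth, tmp_path)
        lines = (tmp_path / "promoter_indels.tsv").read_text().strip().split("\n")
        assert len(lines) == 2 and "\t444\t" in lines[1]
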