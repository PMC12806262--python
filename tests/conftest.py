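import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


from panclade import SimConfig, simulate_clade  # noqa: E402


@pytest.fixture(scope="session")
def two_leaf_sv_sim():
    """Two leaves diverging from the ancestor with all six SV classes."""
    cfg = SimConfig(
        tree="(a:0.1,b:0.1);",
        n_chromosomes=3,
        genes_per_chromosome=40,
        intergenic_bp=4000,
        sv_rates={t: 6.0 for t in (
            "insertion", "deletion", "tandem_expansion", "tandem_contraction",
            "repeat_expansion", "repeat_contraction")},
        sv_size_range=(50, 1500),
        substitution_rate=0.01,
        seed=7,
    )
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def small_clade_sim():
    """Five-leaf clade with gains, losses and substitutions (no SVs)."""
    cfg = SimConfig(
        tree="((a:0.1,b:0.1):0.1,(c:0.1,(d:0.05,e:0.05):0.05):0.1);",
        n_chromosomes=2,
        genes_per_chromosome=25,
        rate_gene_gain=10.0,
        rate_gene_loss=6.0,
        substitution_rate=0.02,
        seed=11,
    )
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def rearranged_star_sim():
    """Three leaves radiating from the ancestor with rearrangements only."""
    cfg = SimConfig(
        tree="(a:0.1,b:0.1,c:0.1);",
        n_chromosomes=3,
        genes_per_chromosome=25,
        rate_inversion=1.0,
        rate_fission=0.2,
        rate_fusion=0.1,
        rate_translocation=0.2,
        seed=5,
    )
    return simulate_clade(cfg)
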