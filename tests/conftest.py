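import numpy as np
import pandas as pd
import pytest

from symscreen.synthetic_data import (
    CiliacutSpec,
    ClusterSpec,
    ExpressionSpec,
    IslandSpec,
    RateSpec,
    SecretomeSpec,
    SimulationConfig,
    simulate_genome,
)


@pytest.fixture(scope="session")
def island_config() -> SimulationConfig:
    """300 kb scaffold with a 100 kb low-GC island ending at the repeat array."""
    return SimulationConfig(
        seed=11,
        genome_length=300_000,
        n_genes=200,
        background_gc=0.58,
        island=IslandSpec(start=150_001, length=100_000, gc=0.49),
        expression=ExpressionSpec(n_induced=20, n_repressed=20, dispersion=0.02),
        secretome=SecretomeSpec(n_true_secreted=30, concordance=1.0),
        rates=RateSpec(n_orthogroups=10, alignment_length=300, n_slow=1, n_fast=1),
    )


@pytest.fixture(scope="session")
def island_genome(island_config):
    return simulate_genome(island_config)


def toy_gene_table(n: int = 20, scaffold: str = "s1", spacing: int = 1000):
    """Evenly spaced single-scaffold gene table for cluster/region tests."""
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "scaffold": scaffold,
            "ordinal": range(n),
            "start": [i * spacing + 1 for i in range(n)],
            "end": [i * spacing + spacing // 2 for i in range(n)],
            "strand": "+",
            "intron_count": 0,
            "protein_length": 100,
            "affinity": "no_hit",
        }
    )


@pytest.fixture
def gene_table_20():
    return toy_gene_table(20)


def make_alignment(n_focal: int, n_ref: int, length: int = 200):
    """Alignment where exactly n_focal / n_ref columns are lineage-private."""
    if n_focal + n_ref > length:
        raise ValueError("too many private sites for length")
    focal = ["A"] * length
    ref = ["A"] * length
    out = ["A"] * length
    for i in range(n_focal):
        focal[i] = "C"
    for i in range(n_focal, n_focal + n_ref):
        ref[i] = "D"
    return {"focal": "".join(focal), "ref": "".join(ref), "out": "".join(out)}


@pytest.fixture
def rng():
    return np.random.default_rng(123)
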