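import numpy as np
import pandas as pd
import pytest

import memoryseq as m


@pytest.fixture(scope="session")
def planted_expression():
    """Small seeded simulation with planted trajectory shapes, shared across
    expression / profile tests."""
    cfg = m.SimulationConfig(n_genes=600, seed=101)
    table, truth = m.simulate_expression(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def planted_de(planted_expression):
    _, table, _ = planted_expression
    return m.run_contrasts(table, m.default_contrasts(table.conditions))


@pytest.fixture(scope="session")
def planted_methylome():
    cfg = m.MethylomeSimConfig(seed=202, genome_length=100_000, n_dmrs=16,
                               n_cytosines_per_context={"CG": 9000, "CHG": 7000,
                                                        "CHH": 25000})
    cyt_a, cyt_b, truth = m.simulate_methylome(cfg)
    return cfg, cyt_a, cyt_b, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """Hand-built two-condition expression table for exact checks."""
    counts = pd.DataFrame(
        {"R0_1": [10, 100, 0], "R0_2": [12, 90, 0],
         "S1_1": [40, 95, 0], "S1_2": [44, 110, 0]},
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"))
    lengths = pd.Series([1000, 2000, 500], index=counts.index)
    samples = pd.DataFrame(
        {"condition": ["R0", "R0", "S1", "S1"], "replicate": [1, 2, 1, 2]},
        index=pd.Index(counts.columns, name="sample"))
    return m.ExpressionTable(counts=counts, lengths=lengths, samples=samples)
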