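import numpy as np
import pandas as pd
import pytest

from cageatlas import CTSSTable, SimConfig, simulate_ctss_experiment, simulate_genome


def make_ctss(records, sample_id="s1", normalized=False):
    """CTSSTable from (chrom, pos, strand, raw_count[, tpm]) tuples."""
    cols = ["chrom", "pos", "strand", "raw_count"]
    if normalized:
        cols.append("norm_tpm")
    df = pd.DataFrame(list(records), columns=cols)
    df = df.sort_values(["chrom", "strand", "pos"], kind="mergesort").reset_index(drop=True)
    return CTSSTable(sample_id=sample_id, data=df)


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete 8-tissue simulation shared across tests."""
    cfg = SimConfig(
        n_genes=10, seed=11, n_chroms=2, chrom_length=1_500_000,
        background_positions=4000,
    )
    tables, truth = simulate_ctss_experiment(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def small_genome(small_sim):
    cfg, _, _ = small_sim
    return simulate_genome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
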