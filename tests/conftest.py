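import numpy as np
import pandas as pd
import pytest

from methylfootprint import SimConfig, assign_wt_landscape, generate_genome


@pytest.fixture(scope="session")
def small_config():
    """A 100 kb configuration small enough for per-test simulation."""
    return SimConfig(genome_length=100_000, n_cgis=6, seed=7)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config, np.random.default_rng(small_config.seed))


@pytest.fixture(scope="session")
def small_truth(small_config, small_genome):
    return assign_wt_landscape(small_genome, small_config, np.random.default_rng(11))


def make_calls(records):
    """Build an in-memory call table from (chrom, pos, n_meth, n_total) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "n_meth", "n_total"])
    df["level"] = df["n_meth"] / df["n_total"]
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)
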