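import numpy as np
import pandas as pd
import pytest

from chipsip import simulate_dataset
from chipsip.io import validate_probe_table


def make_table(rows):
    """Probe table from (probe, taxon, treatment, fluor, delta) tuples."""
    df = pd.DataFrame(rows, columns=["probe_id", "taxon_id", "treatment",
                                     "fluorescence", "delta_permil"])
    df["count_14N"] = pd.NA
    df["count_15N"] = pd.NA
    return validate_probe_table(df)


def taxon_spots(rng, slopes, n_spots=20, noise_sd=1.0, taxon="tx"):
    """One taxon's spots across H/M/L with given true slopes and noise."""
    fluor = rng.lognormal(np.log(30.0), 0.6, n_spots)
    rows = []
    for treatment, slope in zip(("H", "M", "L"), slopes):
        delta = slope * fluor + rng.normal(0.0, noise_sd, n_spots)
        for j in range(n_spots):
            rows.append((f"p{j}", taxon, treatment, fluor[j], delta[j]))
    return make_table(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """30-taxon default-condition synthetic dataset with ground truth."""
    table, tree, truths = simulate_dataset(n_taxa=30, rng_seed=11)
    return table, tree, truths


@pytest.fixture
def rng():
    return np.random.default_rng(0)
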