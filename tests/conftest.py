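import numpy as np
import pytest

from genopanel import GenotypeTable, SimConfig, SiteKey, simulate_collection


def table_from_array(arr, labels=None, groups=None, chrom="1"):
    """Build a GenotypeTable from a (sites x accessions) array of dosages.

    Sites are placed at 100, 200, ... on one canonical chromosome with
    alleles A>G.
    """
    arr = np.asarray(arr, dtype=np.int8)
    if labels is None:
        labels = [f"acc{j + 1}" for j in range(arr.shape[1])]
    sites = [SiteKey(chrom, 100 * (i + 1), "A", "G") for i in range(arr.shape[0])]
    return GenotypeTable(sites=sites, accessions=list(labels), dosages=arr,
                         groups=groups)


def random_table(rng, n_sites, n_accessions, missing_rate=0.1):
    """Random dosage table with a sprinkle of missing calls."""
    d = rng.integers(0, 3, size=(n_sites, n_accessions)).astype(np.int8)
    if missing_rate > 0:
        d = np.where(rng.random(d.shape) < missing_rate, np.int8(-1), d)
    return table_from_array(d)


@pytest.fixture(scope="session")
def sim_small():
    """A small structured collection shared by read-only tests."""
    config = SimConfig(n_populations=3, fst=0.2, n_sites=600,
                       n_accessions_per_pop=8, n_redundant=2,
                       n_cross_offspring=2, missing_rate=0.02, seed=11)
    return simulate_collection(config)
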