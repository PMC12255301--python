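import numpy as np
import pytest

from tadedit.discovery import CROSS_SPECIES
from tadedit.pipeline import discover
from tadedit.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def reference_config() -> SimConfig:
    """The reference study conditions: 30 planted sites at 10-60% levels,
    50x coverage, 3 replicates, 0.1% error, 5 strain SNPs."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(reference_config):
    return simulate_dataset(reference_config)


@pytest.fixture(scope="session")
def discovery_run(dataset):
    """Full cascade (trim -> map -> call -> filters -> rescue) on the
    reference dataset; shared because it is the most expensive fixture."""
    sites, table, pileups = discover(
        dataset.genome, reads_by_sample=dataset.reads, profile=CROSS_SPECIES
    )
    return sites, table, pileups


def site_read_counts(ds, truth, sample):
    """(ref A, edited G) read counts at a truth site, straight from the
    simulated reads (origin encoded in read ids; no mapping involved)."""
    gene = ds.genome.gene_by_id(truth.gene_id)
    rl = ds.config.read_length
    n_a = n_g = 0
    for read in ds.reads[sample]:
        _, gene_id, start, _ = read.id.split(":")
        if gene_id != truth.gene_id:
            continue
        start = int(start)
        if not start <= truth.position < start + rl:
            continue
        idx = (truth.position - start if gene.strand == "+"
               else start + rl - 1 - truth.position)
        base = read.sequence[idx]
        if base == "A":
            n_a += 1
        elif base == "G":
            n_g += 1
    return n_a, n_g
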