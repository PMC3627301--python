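"""Shared fixtures: small synthetic datasets built at test time."""

import numpy as np
import pytest

from zfpg import synthgen
from zfpg.popio import GenotypeDataset, LocusRecord


def make_dataset(genotypes, popmap=None, positions=None, chrom="chr01", groupmap=None):
    """Small GenotypeDataset from a plain genotype matrix."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = [f"S{i+1}" for i in range(n)]
    if popmap is None:
        popmap = {s: "pop1" for s in samples}
    elif isinstance(popmap, (list, tuple)):
        popmap = dict(zip(samples, popmap))
    if positions is None:
        positions = [(chrom, 1000 * (j + 1)) for j in range(m)]
    loci = [
        LocusRecord(f"L{j+1}", c, p) for j, (c, p) in enumerate(positions)
    ]
    return GenotypeDataset(samples, loci, g, popmap, groupmap)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-locus, 2-group simulated dataset with moderate structure."""
    cfg = synthgen.SimConfig(
        sampled_pops=[("A", 0, 0, 12), ("B", 0, 1, 12), ("C", 1, 0, 12), ("D", 1, 1, 12)],
        n_loci=300,
        n_groups=2,
        demes_per_group=5,
        chrom_lengths=[40_000_000] * 5,
        M1=5.0,
        M2=0.5,
        seed=11,
    )
    return synthgen.simulate_snp_dataset(cfg)
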