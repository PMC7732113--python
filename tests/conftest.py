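import numpy as np
import pytest

import hexapop as hp
from hexapop.model import AllelePhenotype, GenotypeMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale synthetic dataset shared by read-only tests."""
    cfg = hp.SimConfig(seed=11, n_populations=2, n_samples=16)
    return hp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def two_pop_genotypes():
    """Hand-sized two-population genotype matrix with known phenotypes."""
    cells = {}
    layout = {
        "a1": {"L1": {0, 2}, "L2": {5}},
        "a2": {"L1": {0, 3}, "L2": {5, 6}},
        "a3": {"L1": {1, 2}, "L2": {5}},
        "b1": {"L1": {7, 8}, "L2": {9}},
        "b2": {"L1": {7}, "L2": {9, 10}},
        "b3": {"L1": {8}, "L2": {10}},
    }
    for s, loci in layout.items():
        for l, alleles in loci.items():
            cells[(s, l)] = AllelePhenotype(s, l, frozenset(alleles))
    pops = {s: ("A" if s.startswith("a") else "B") for s in layout}
    return GenotypeMatrix(sorted(layout), ["L1", "L2"], cells, pops)


def build_genotypes(layout, population_of=None, loci=None):
    """Helper: GenotypeMatrix from {sample: {locus: set}}."""
    loci = loci or sorted({l for v in layout.values() for l in v})
    cells = {
        (s, l): AllelePhenotype(s, l, frozenset(v.get(l, set())))
        for s, v in layout.items()
        for l in loci
    }
    pops = population_of or {s: "P" for s in layout}
    return GenotypeMatrix(sorted(layout), loci, cells, pops)
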