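import numpy as np
import pytest

import hybkit as hk
from hybkit.pedigrees import standard_class_sets


@pytest.fixture(scope="session")
def six_classes():
    return dict(standard_class_sets("six"))


@pytest.fixture(scope="session")
def fmodel_pools():
    """Standard study conditions: 11 loci, F = 0.35 parental pools."""
    cfg = hk.SimConfig(seed=101)
    return hk.make_parental_frequencies(cfg)


@pytest.fixture(scope="session")
def diagnostic_pools():
    """20 fully diagnostic loci (allele 1 fixed in A, allele 2 in B)."""
    return hk.diagnostic_frequencies(20)


@pytest.fixture()
def toy_table():
    """Two populations, two loci, one missing call."""
    calls = np.array([
        [[1, 2], [5, 5]],
        [[1, 1], [5, 6]],
        [[2, 2], [-1, -1]],
        [[2, 3], [6, 6]],
    ])
    return hk.GenotypeTable(
        ["a1", "a2", "b1", "b2"], ["locA", "locB"], calls,
        np.array(["p1", "p1", "p2", "p2"], dtype=object),
        np.array(["savanna", "savanna", "forest", "forest"], dtype=object),
    )


@pytest.fixture(scope="session")
def two_ecotype_table():
    """Six populations (3 per ecotype) sampled from diverged pools."""
    cfg = hk.SimConfig(seed=202)
    pA, pB = hk.make_parental_frequencies(cfg)
    classes = dict(standard_class_sets("six"))
    rng = np.random.default_rng(202)
    parts = []
    for eco, cls, pool_tag in (("savanna", "P1", "s"), ("forest", "P2", "f")):
        for k in range(3):
            g = hk.simulate_class(pA, pB, classes[cls], 12, rng,
                                  class_name=cls, id_prefix=f"{pool_tag}{k}")
            g.populations[:] = f"{pool_tag}-pop{k}"
            g.ecotypes[:] = eco
            parts.append(g)
    return hk.GenotypeTable.concatenate(parts)
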