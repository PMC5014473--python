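import numpy as np
import pytest

import recsweep as rs


@pytest.fixture(scope="session")
def bench_triplet():
    """Benchmark recombinant triplet: C descends from A, carries
    B's [300, 700) region; parents A, B at JC distance 0.2."""
    aln, truth = rs.recombinant_triplet(seed=11)
    return aln, truth


@pytest.fixture(scope="session")
def bench_quartet():
    """Benchmark quartet with a distant outgroup O for bootscan."""
    tree = "(((A:0.02,C:0.02):0.08,B:0.10):0.15,O:0.15);"
    aln = rs.simulate_tree_alignment(tree, 2000, seed=3)
    aln, truth = rs.implant_recombination(aln, "B", "C", (600, 1400))
    return aln, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
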