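import numpy as np
import pytest

from quatevol import MSA, PhyloTree, discrete_gamma, lg_model


@pytest.fixture(scope="session")
def lg():
    return lg_model()


@pytest.fixture(scope="session")
def gamma4():
    return discrete_gamma(1.0, 4)


@pytest.fixture(scope="session")
def gamma1():
    return discrete_gamma(1.0, 1)


@pytest.fixture
def quartet_tree():
    return PhyloTree.from_newick(
        "((A:0.12,B:0.27):0.18,(C:0.33,D:0.08):0.21);")


@pytest.fixture
def quartet_msa():
    return MSA(labels=list("ABCD"),
               sequences=["ARNDC", "ARNEC", "ARKDC", "A-NDW"])


def random_column_msa(n_leaves, n_cols, seed, gap_fraction=0.0):
    """Random 20-state columns (optionally gapped) for t1..tN leaf labels."""
    from quatevol.phylo import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    data = rng.integers(0, 20, size=(n_leaves, n_cols))
    chars = np.array(list(AMINO_ACIDS + "-"))
    if gap_fraction > 0:
        data[rng.random(data.shape) < gap_fraction] = 20
    return MSA(labels=[f"t{i+1}" for i in range(n_leaves)],
               sequences=["".join(chars[row]) for row in data])
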