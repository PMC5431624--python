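import pandas as pd
import pytest

from mitohet.genotypes import GenotypeMatrix
from mitohet.io import load_cox3_survey, load_qpcr_survey


def make_matrix(rows, loci, populations=None, ids=None):
    """Build a small GenotypeMatrix from a list of allele tuples."""
    ids = ids or [f"i{k + 1}" for k in range(len(rows))]
    pops = populations or ["p"] * len(rows)
    data = pd.DataFrame(list(rows), index=ids, columns=list(loci), dtype=object)
    return GenotypeMatrix(data, pd.Series(pops, index=ids))


@pytest.fixture(scope="session")
def cox3_catalog():
    return load_cox3_survey()


@pytest.fixture(scope="session")
def qpcr_survey():
    return load_qpcr_survey()


@pytest.fixture
def two_founder_matrix():
    """Two clonal founders AB and ab in equal numbers (n=4)."""
    return make_matrix([("A", "B"), ("A", "B"), ("a", "b"), ("a", "b")], ["L1", "L2"])
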