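import numpy as np
import pytest

from multiblup import make_fixture
from multiblup.datamodel import (
    GenotypeMatrix,
    MultiPopulationDataset,
    PopulationRecords,
    VarianceComponents,
)


@pytest.fixture(scope="session")
def tiny2():
    return make_fixture("tiny-2pop")


@pytest.fixture(scope="session")
def equiv3():
    return make_fixture("equiv-3pop")


@pytest.fixture(scope="session")
def crossbred3():
    return make_fixture("crossbred-3pop")


@pytest.fixture(scope="session")
def clones():
    return make_fixture("singular-clones")


def manual_genotypes(Z, W, dosage=None, ids=None):
    """GenotypeMatrix with hand-set codings for scalar algebra checks."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if dosage is None:
        dosage = np.ones_like(Z, dtype=np.int64)
    n, m = Z.shape
    if ids is None:
        ids = tuple(f"i{q}" for q in range(n))
    return GenotypeMatrix(
        tuple(ids), tuple(f"s{j}" for j in range(m)), np.asarray(dosage), Z, W
    )


def manual_dataset(Z, W, y, sigma_a2=1.0, sigma_d2=1.0, sigma_e2=1.0, X=None):
    """Single-population dataset with hand-set codings and intercept design."""
    g = manual_genotypes(Z, W)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if X is None:
        X = np.ones((g.n, 1))
    ds = MultiPopulationDataset([PopulationRecords(1, y, X, g, ["intercept"])])
    vc = VarianceComponents([[sigma_a2]], [[sigma_d2]], [sigma_e2])
    return ds, vc
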