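import numpy as np
import pandas as pd
import pytest

from radpheno import simdata


@pytest.fixture(scope="session")
def manifest():
    return simdata.make_manifest_fixture()


@pytest.fixture(scope="session")
def small_scenario():
    """Six-individual scenario for read-level pipeline tests."""
    mf = simdata.make_manifest_fixture().head(6).copy()
    return simdata.SimScenario(
        manifest=mf, seed=5, error_rate=0.0, n_loci=30, mean_coverage=10.0
    )


@pytest.fixture(scope="session")
def pileup_88():
    """Pileup over the full manifest at study-like coverage."""
    sc = simdata.SimScenario(seed=3, n_sites=400)
    return sc, simdata.simulate_pileup(sc)


def random_distance_matrix(rng, n, dim=3):
    """Euclidean distances among random points (valid distance matrix)."""
    pts = rng.normal(size=(n, dim))
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
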