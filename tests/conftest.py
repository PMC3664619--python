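import numpy as np
import pytest

from betaspace.core_data import IncidenceMatrix, SiteTable


def random_sites(n: int, seed: int, extent: float = 30.0) -> SiteTable:
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, extent, (n, 2))
    return SiteTable([f"s{i:02d}" for i in range(n)], pts[:, 0], pts[:, 1])


def random_incidence(n_sites: int, n_species: int, seed: int,
                     p: float = 0.3) -> IncidenceMatrix:
    rng = np.random.default_rng(seed)
    X = (rng.random((n_sites, n_species)) < p).astype(int)
    # guarantee no empty site so the strict beta partition applies
    empty = X.sum(axis=1) == 0
    X[empty, 0] = 1
    return IncidenceMatrix([f"s{i:02d}" for i in range(n_sites)],
                           [f"sp{j:02d}" for j in range(n_species)], X)


@pytest.fixture
def square_sites() -> SiteTable:
    """Four corners of the unit square."""
    return SiteTable(["a", "b", "c", "d"],
                     np.array([0.0, 1.0, 1.0, 0.0]),
                     np.array([0.0, 0.0, 1.0, 1.0]))
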