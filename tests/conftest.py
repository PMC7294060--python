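import numpy as np
import pandas as pd
import pytest

from fcgraph.atlas import load_packaged_atlas
from fcgraph.connectome import ConnectivityMatrix
from fcgraph.synth import CohortConfig, make_synthetic_atlas


@pytest.fixture(scope="session")
def packaged_atlas():
    return load_packaged_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    return make_synthetic_atlas()


@pytest.fixture
def rng():
    return np.random.default_rng(20231105)


def random_symmetric_matrix(n, rng, positive=True):
    """A random symmetric zero-diagonal matrix with distinct off-diagonals."""
    a = rng.uniform(0.05, 1.0, size=(n, n)) if positive else rng.uniform(-1, 1, size=(n, n))
    w = np.triu(a, k=1)
    w = w + w.T
    return w


def make_cm(weights, **kw):
    return ConnectivityMatrix(weights=np.asarray(weights, dtype=float), **kw)


@pytest.fixture(scope="session")
def scaled_config():
    """Scaled-down acquisition: 100-node atlas, TR 2 s, 165 volumes (330 s),
    so the 300 s duration gate is live but replicates stay cheap."""
    return CohortConfig(n_subjects=41, tr=2.0, n_volumes=165, seed=11)


@pytest.fixture(scope="session")
def serial_table():
    """Balanced serial design: 30 subjects x 6 visits, variance ratio 1."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(30):
        mu = rng.standard_normal()
        for v in range(6):
            rows.append(
                {
                    "subject_id": f"s{i:03d}",
                    "visit_id": f"v{v}",
                    "time_days": 30.0 * v,
                    "value": mu + rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)
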