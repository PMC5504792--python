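import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phredlogit import features, model, simulator

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_fixture():
    return simulator.make_fixture("clean")


@pytest.fixture(scope="session")
def noisy_fixture():
    return simulator.make_fixture("noisy-mixed")


@pytest.fixture(scope="session")
def quenched_fixture():
    return simulator.make_fixture("quenched")


@pytest.fixture(scope="session")
def noisy_design(noisy_fixture):
    """Design matrix + labels of the noisy-mixed fixture (10k bases)."""
    fm = features.build_design_matrix(noisy_fixture.tile)
    y = noisy_fixture.labels.flat().astype(int)
    return fm, y


@pytest.fixture(scope="session")
def trained_l1(noisy_design):
    """An L1 model at a fixed moderate penalty, for scoring tests."""
    fm, y = noisy_design
    return model.fit_l1(fm.X, y, 10.0, feature_names=fm.feature_names,
                        metadata=fm)


def random_tile(seed, n_reads=5, length=8):
    """Small random but valid IntensityTile for IO round-trip tests."""
    from phredlogit.io_formats import IntensityTile

    rng = np.random.default_rng(seed)
    intens = rng.gamma(2.0, 0.4, size=(n_reads, length, 4)).round(6)
    called = ["".join("ACGT"[k] for k in row)
              for row in intens.argmax(axis=2)]
    ids = [f"r{seed}_{i}" for i in range(n_reads)]
    return IntensityTile(ids, intens, called, length)
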