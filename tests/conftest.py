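import numpy as np
import pytest

from pyroplast.core_model import Spectrum, TgaFtirRun, WavenumberGrid
from pyroplast.ml_pipeline import TrainConfig, train
from pyroplast.synthetic_data import make_fixture_library, make_mixture_dataset


@pytest.fixture(scope="session")
def fixture_library():
    """Default 12-archetype library plus its source runs (seed-fixed)."""
    return make_fixture_library(seed=1)


@pytest.fixture(scope="session")
def lib(fixture_library):
    return fixture_library[0]


@pytest.fixture(scope="session")
def runs_by_class(fixture_library):
    return fixture_library[1]


@pytest.fixture(scope="session")
def svc_model(lib):
    model, metrics = train(lib, "svc", TrainConfig(emsa_per_class=25), seed=3)
    return model, metrics


@pytest.fixture(scope="session")
def mixture_dataset(runs_by_class):
    """100 seeded mixtures with their ground-truth manifest."""
    return make_mixture_dataset(runs_by_class, n=100, seed=7)


@pytest.fixture
def small_grid():
    return WavenumberGrid(np.array([800.0, 1000.0, 1500.0, 2000.0, 3000.0]))


def toy_run(grid, temps, spectra_values, tg=None):
    spectra = [Spectrum(v, t) for v, t in zip(spectra_values, temps)]
    return TgaFtirRun(
        grid=grid,
        temperatures=np.asarray(temps, dtype=float),
        spectra=spectra,
        tg=tg,
    )
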