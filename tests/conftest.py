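import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from quadlock import synthetic_data as sd

EXTERNAL_DIR = Path(__file__).resolve().parent.parent / "data" / "external"


@pytest.fixture(scope="session")
def at26_fixture():
    """Clean single-model intra-locked fixture plus its truth record."""
    models, truth = sd.build_ideal_g4(sd.fixture_at26_like())
    return models[0], truth


@pytest.fixture(scope="session")
def at26_ensemble():
    """Ten jittered, rigidly reoriented models of the intra-locked fixture."""
    models, truth = sd.build_ideal_g4(
        sd.fixture_at26_like(), n_models=10, jitter_sd=0.1, seed=11
    )
    return models, truth


@pytest.fixture(scope="session")
def parallel3_fixture():
    models, truth = sd.build_ideal_g4(sd.fixture_parallel(3))
    return models[0], truth
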