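import numpy as np
import pytest

from squiggleid import PoreModel, synthesize_pore_model


@pytest.fixture(scope="session")
def k2_model() -> PoreModel:
    """Tiny complete 2-mer model with distinct hand-set levels."""
    bases = "ACGT"
    levels = {
        a + b: 10.0 * (1 + i) + 2.5 * j
        for i, a in enumerate(bases)
        for j, b in enumerate(bases)
    }
    return PoreModel(k=2, levels=levels, name="k2-test")


@pytest.fixture(scope="session")
def k5_model() -> PoreModel:
    return synthesize_pore_model(k=5, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
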