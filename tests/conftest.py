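import numpy as np
import pytest

from bimotif import BmfModel, EnergyTable, SpacerParams


def random_model(rng: np.random.Generator, k: int, scale: float | None = None) -> BmfModel:
    """A random small model with moderate energies (weights O(1))."""
    n = 4**k
    return BmfModel(
        core_a=EnergyTable(k, rng.normal(4.0, 1.5, n)),
        core_b=EnergyTable(k, rng.normal(4.0, 1.5, n)),
        spacer=SpacerParams.from_natural(
            r=rng.uniform(0.5, 5.0),
            p=rng.uniform(0.05, 0.9),
            scale=rng.uniform(1.0, 5000.0) if scale is None else scale,
        ),
    )


def random_seq(rng: np.random.Generator, L: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=L))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_model():
    """k=3 model with all energies equal (flat motif), moderate spacer."""
    return BmfModel(
        core_a=EnergyTable(3, np.full(64, 3.0)),
        core_b=EnergyTable(3, np.full(64, 3.0)),
        spacer=SpacerParams.from_natural(r=2.0, p=0.3, scale=100.0),
    )
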