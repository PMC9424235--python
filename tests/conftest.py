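import numpy as np
import pytest

from allokin import fixtures


@pytest.fixture(scope="session")
def fx():
    return fixtures()


@pytest.fixture(scope="session")
def bromo(fx):
    return fx.bromoguanine


@pytest.fixture(scope="session")
def deaza(fx):
    return fx.deazaguanine


def perturbed_starts(params, names, factors=(3.0, 1.0 / 3.0)):
    """Starting sets with every parameter jointly scaled by each factor."""
    return [
        {nm: getattr(params, nm) * f for nm in names}
        for f in factors
    ]
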