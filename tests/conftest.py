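import numpy as np
import pytest

import pollendiv as pv
from pollendiv.pollen import CharacterMatrix


@pytest.fixture(scope="session")
def cherry():
    """Two tips, both 10 Myr from the root."""
    return pv.read_tree("(A:10,B:10);")


@pytest.fixture(scope="session")
def quartet():
    """Balanced ultrametric 4-tip tree."""
    return pv.read_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def sim_replicate_50():
    """One 50-tip BiSSE replicate reused by likelihood-level tests."""
    cfg = pv.SimConfig(
        params=pv.SSEParameters.bisse(0.1, 0.2, 0.03, 0.03, 0.01, 0.01),
        stop=("n_tips", 50),
        seed=42,
    )
    return pv.simulate_bisse_tree(cfg)


@pytest.fixture(scope="session")
def sim_chars_50(sim_replicate_50):
    return CharacterMatrix(
        "PA1", {l: str(s) for l, s in sim_replicate_50.tip_states.items()}
    )


def random_yule_tree(n_tips: int, rng: np.random.Generator, lam: float = 0.2):
    """Small random ultrametric tree via the package's own simulator."""
    cfg = pv.SimConfig(
        params=pv.SSEParameters.bisse(lam, lam, 0.0, 0.0, 0.0, 0.0),
        stop=("n_tips", n_tips),
        seed=int(rng.integers(1, 2**31 - 1)),
        min_surviving_tips=2,
    )
    return pv.simulate_bisse_tree(cfg).tree
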