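import numpy as np
import pytest

from perturbgrn import GeneNetwork, PerturbationDataset, simulate_knockdown_study


@pytest.fixture
def chain_net() -> GeneNetwork:
    """2-gene chain: gene 0 represses itself and activates gene 1."""
    return GeneNetwork(np.array([[-1.0, 0.0], [1.0, -1.0]]), ["G0", "G1"])


@pytest.fixture
def chain_dataset(chain_net) -> PerturbationDataset:
    """Noiseless single-knockdown data from the 2-gene chain (P = -I)."""
    P = -np.eye(2)
    Y = np.array([[-1.0, 0.0], [-1.0, -1.0]])
    return PerturbationDataset(Y, P, ["G0", "G1"], ["kd0", "kd1"])


@pytest.fixture(scope="session")
def study15():
    """15-gene knockdown study at moderate noise (snr=7), 3 replicates."""
    return simulate_knockdown_study(15, 3.0, 3, snr=7.0, seed=2)


@pytest.fixture(scope="session")
def study15_clean():
    """Same design, noiseless."""
    return simulate_knockdown_study(15, 3.0, 3, snr=float("inf"), seed=2)
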