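import numpy as np
import pytest

from hyperdisc import ItemBank, ModelParams
from hyperdisc.recovery import simulate_choices


@pytest.fixture(scope="session")
def bank():
    return ItemBank.kirby27()


@pytest.fixture(scope="session")
def simulated_datasets(bank):
    """20 datasets simulated from parameters spread over the fit bounds."""
    rng = np.random.default_rng(20240117)
    out = []
    for i in range(20):
        k = float(np.exp(rng.uniform(np.log(1e-4), np.log(0.25))))
        beta = float(np.exp(rng.uniform(np.log(1e-3), np.log(10.0))))
        out.append(
            (
                ModelParams(k=k, beta=beta),
                simulate_choices(bank, ModelParams(k=k, beta=beta), seed=5000 + i,
                                 participant_id=f"sim{i:02d}"),
            )
        )
    return out
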