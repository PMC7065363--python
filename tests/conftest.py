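import numpy as np
import pytest

from methylosip.labelling import CallParameters, call_experiment
from methylosip.simulate import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def strong_signal_experiment():
    """The fixed strong-signal recovery fixture: 200 taxa, 20 labelled at
    50-fold median enrichment, 3 replicates, 20k reads per fraction."""
    return simulate_experiment(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def strong_signal_calls(strong_signal_experiment):
    experiment, _ = strong_signal_experiment
    return call_experiment(
        experiment.abundance,
        experiment.samples,
        CallParameters(floor=0.001, k=10),
        control_treatment="unplanted",
    )


def random_profile_arrays(rng: np.random.Generator, n: int):
    """Random four-fraction abundance quadruples spanning the decision
    boundaries (mix of magnitudes around the 0.1% floor and k-fold ratios)."""
    scale = 10.0 ** rng.uniform(-4, 0, size=(n, 4))
    raw = rng.uniform(0, 1, size=(n, 4)) * scale
    # sprinkle exact zeros and ties to hit the boundary semantics
    raw[rng.uniform(size=(n, 4)) < 0.05] = 0.0
    tie = rng.uniform(size=n) < 0.1
    raw[tie, 3] = raw[tie, 2]
    return np.clip(raw, 0.0, 1.0)
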