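import numpy as np
import pytest

import oscnet as on


@pytest.fixture(scope="session")
def star_network() -> on.Network:
    """11-node star: one hub (degree 10) and ten leaves (degree 1)."""
    A = np.zeros((11, 11), dtype=int)
    A[0, 1:] = 1
    A[1:, 0] = 1
    return on.Network(A)


@pytest.fixture(scope="session")
def star_run(star_network):
    """Deterministic noise-free star-graph run at the hub-lag conditions:
    identical 10 Hz oscillators, operating-point coupling, 10 ms delays.  30 s so that the
    leaf-leaf phase differences (zero by symmetry) decay to numerical
    silence inside the retained window."""
    delays = on.build_delay_matrix(star_network, "constant", 0.010)
    cfg = on.SimulationConfig(
        S=on.coupling_from_cycles(1.5), delays=delays, seed=42, noise_sd=0.0,
        omega_sd_hz=0.0, n_samples=30_000,
    )
    return on.simulate_stuart_landau(star_network, cfg)


@pytest.fixture(scope="session")
def scalefree_net() -> on.Network:
    return on.generate_scale_free_catanzaro(78, 2.2, seed=7)


@pytest.fixture(scope="session")
def scalefree_run(scalefree_net):
    """One noisy run at the intermediate-synchronization operating point."""
    delays = on.build_delay_matrix(scalefree_net, "constant", 0.010)
    cfg = on.SimulationConfig(
        S=on.coupling_from_cycles(1.5), delays=delays, seed=11
    )
    return on.simulate_stuart_landau(scalefree_net, cfg)
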