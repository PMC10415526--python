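import numpy as np
import pytest

from betasw import CouplingEdge, CouplingSpec, generate_roi_timeseries


@pytest.fixture(scope="session")
def coupled_pair_roi():
    """Two ROIs with a strong lagged coupling (0->1, gain 0.8, 20 ms)."""
    spec = CouplingSpec(n_rois=2, edges=(CouplingEdge(0, 1, 0.8, 20.0),),
                        noise_sd=0.1)
    return generate_roi_timeseries(spec, duration_s=120.0, rate_hz=250.0,
                                   seed=7)


@pytest.fixture(scope="session")
def uncoupled_pair_roi():
    spec = CouplingSpec(n_rois=2, noise_sd=0.1)
    return generate_roi_timeseries(spec, duration_s=120.0, rate_hz=250.0,
                                   seed=7)


def random_dense_graph(n: int, rng: np.random.Generator) -> np.ndarray:
    """Fully connected symmetric zero-diagonal weights, uniform (0, 1)."""
    A = np.triu(rng.random((n, n)), 1)
    return A + A.T
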