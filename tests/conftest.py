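import numpy as np
import pytest

import ehhsim as e


@pytest.fixture(scope="session")
def hh_model():
    return e.build_original_hh()


@pytest.fixture(scope="session")
def io_cell():
    return e.build_io_cell()


@pytest.fixture(scope="session")
def key():
    return e.make_key(42)


def random_io_network(n_cells, seed, symmetric=True):
    """Small olive network with random gaussian connectivity."""
    return e.build_io_network(
        n_cells,
        {"dist": "gaussian", "key_seed": seed, "mu": 0.5, "sigma": 0.15,
         "symmetric": symmetric},
    )


def hh_rate_oracles():
    """Direct transcriptions of the six classic squid-axon rate equations.

    Each returns the analytic limit at its removable singularity so the
    oracle is defined on every grid point.
    """
    def alpha_n(v):
        x = v + 10.0
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(np.abs(x) < 1e-12, 0.1, 0.01 * x / (np.exp(x / 10.0) - 1.0))

    def beta_n(v):
        return 0.125 * np.exp(v / 80.0)

    def alpha_m(v):
        x = v + 25.0
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(np.abs(x) < 1e-12, 1.0, 0.1 * x / (np.exp(x / 10.0) - 1.0))

    def beta_m(v):
        return 4.0 * np.exp(v / 18.0)

    def alpha_h(v):
        return 0.07 * np.exp(v / 20.0)

    def beta_h(v):
        return 1.0 / (np.exp((v + 30.0) / 10.0) + 1.0)

    return {
        ("K", "n"): (alpha_n, beta_n),
        ("Na", "m"): (alpha_m, beta_m),
        ("Na", "h"): (alpha_h, beta_h),
    }
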