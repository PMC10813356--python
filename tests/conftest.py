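import numpy as np
import pytest

from immunoflux.network import build_default_network


@pytest.fixture(scope="session")
def network():
    return build_default_network()


@pytest.fixture(scope="session")
def pbmc_free(network):
    """A representative PBMC-like free-flux assignment."""
    from immunoflux.synthetic import DEFAULT_FLUX_MEDIANS

    return np.array(
        [DEFAULT_FLUX_MEDIANS["PBMC"][f] for f in network.free_flux_ids]
    )


@pytest.fixture(scope="session")
def pbmc_fluxes(network, pbmc_free):
    return network.embed(pbmc_free)
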