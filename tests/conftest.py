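import pytest

from polychron import SimParams, create_network


@pytest.fixture
def tiny_params():
    """A small network suitable for hand-computable checks."""
    return SimParams(n_neurons=16, n_axon_arrays=1, modules_per_array=8)


@pytest.fixture
def tiny_net(tiny_params):
    return create_network(tiny_params)


def configure_module(net, idx, input_addr, outputs, delays):
    """Directly configure one axon module (test plumbing)."""
    net.input_addrs[idx] = input_addr
    net.out_addrs[idx] = list(outputs)
    net.delays[idx] = list(delays)
    net.programming_index = max(net.programming_index, idx + 1)
    net.invalidate_routing()
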