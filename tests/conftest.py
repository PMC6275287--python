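import numpy as np
import pytest

import somasim as ss


@pytest.fixture
def hh_tree():
    return ss.make_fixture("hh_neuron")


@pytest.fixture
def leak_tree():
    """Single leak-only compartment with a 10 ms membrane time constant."""
    tree = ss.ModelTree()
    tree.add_compartment("cell", A=0.01, Cm=10.0)
    tree.add_channel("cell", "Leak", gbar=1.0, E=-50.0)
    tree.compartments["cell"].V = -60.0
    return tree


@pytest.fixture
def pyloric_tree():
    return ss.make_fixture("pyloric_network")
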