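import numpy as np
import pytest

from spinetraffic.engine import compile_network
from spinetraffic.network import ReactionChannel
from spinetraffic.protocols import make_protocol, run_protocol


class ToySystem:
    """Minimal stand-in for ReactionSystem: explicit species and channels."""

    def __init__(self, species: list[str], channels: list[ReactionChannel],
                 initial: list[int]):
        self.species_names = [(s, "toy") for s in species]
        self._index = {name: k for k, name in enumerate(species)}
        self.channels = channels
        self._initial = np.array(initial, dtype=np.int64)
        self._compiled = None

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def idx(self, species: str, comp_id: str = "toy") -> int:
        return self._index[species]

    def initial_state(self) -> np.ndarray:
        return self._initial.copy()

    def compiled(self):
        if self._compiled is None:
            self._compiled = compile_network(self)
        return self._compiled


@pytest.fixture(scope="session")
def toy_system_factory():
    return ToySystem


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced 2-spine model (200 receptors, 60 s) used for fast checks."""
    return make_protocol("fixture_small")


@pytest.fixture(scope="session")
def small_system(small_protocol):
    return small_protocol.build_system()


@pytest.fixture(scope="session")
def small_trajs(small_protocol):
    return run_protocol(small_protocol)
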