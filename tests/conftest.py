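import dataclasses

import numpy as np
import pytest

from riverdci import RiverNetwork, build_topology


@pytest.fixture
def binary7_net() -> RiverNetwork:
    """7-reach complete binary tree, unit lengths, all passabilities 0.5."""
    net = build_topology("binary", 7)
    a = np.full(7, 0.5)
    a[0] = np.nan
    return dataclasses.replace(net, alpha_up=a.copy(), alpha_down=a.copy())


@pytest.fixture
def random_net():
    """Factory for random valid networks with independent lengths/alphas."""

    def make(
        rng: np.random.Generator,
        n: int | None = None,
        topology: str | None = None,
        alpha_low: float = 0.05,
    ) -> RiverNetwork:
        if n is None:
            n = int(rng.integers(2, 13))
        if topology is None:
            topology = rng.choice(["linear", "binary"])
        net = build_topology(topology, n)
        a_up = rng.uniform(alpha_low, 1.0, n)
        a_down = rng.uniform(alpha_low, 1.0, n)
        a_up[0] = a_down[0] = np.nan
        return dataclasses.replace(
            net,
            lengths=rng.uniform(0.5, 1.0, n),
            alpha_up=a_up,
            alpha_down=a_down,
        )

    return make
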