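from __future__ import annotations

import numpy as np
import pytest

from chmnet import synthetic


@pytest.fixture
def trans5():
    """Five tiny transactions used throughout the ARM examples."""
    return [frozenset(t) for t in ("ab", "abc", "ac", "bc", "a")]


@pytest.fixture
def random_transactions():
    """Factory for random transaction lists over a small herb alphabet."""

    def make(seed, n_transactions=200, n_items=12, max_size=6):
        rng = np.random.default_rng(seed)
        items = [f"h{i:02d}" for i in range(n_items)]
        out = []
        for _ in range(n_transactions):
            size = int(rng.integers(1, max_size + 1))
            out.append(frozenset(rng.choice(items, size=size, replace=False)))
        return out

    return make


@pytest.fixture(scope="session")
def demo_spec():
    """The planted six-community fixture at a reduced transaction count."""
    return synthetic.default_network_spec(seed=11, n_prescriptions=5000)


@pytest.fixture(scope="session")
def demo_prescriptions(demo_spec):
    return synthetic.generate_prescriptions(demo_spec)
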