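import numpy as np
import pytest

from chromaxent import (
    BinnedChromosome,
    ContactMap,
    ModelBank,
    NeighborhoodScheme,
    SyntheticConfig,
    generate_states,
    plant_bank,
    simulate_contacts,
)


@pytest.fixture
def scheme4() -> NeighborhoodScheme:
    return NeighborhoodScheme(4)


@pytest.fixture
def toy_states() -> BinnedChromosome:
    """30 bins: a down-state block in the middle of an up genome."""
    s = np.ones(30, dtype=np.int8)
    s[12:18] = -1
    return BinnedChromosome("toy", 10_000, s)


def toy_map(entries, n_bins=30, bin_size=10_000, name="toy") -> ContactMap:
    if entries:
        i, j, v = map(np.asarray, zip(*entries))
    else:
        i = j = v = np.zeros(0)
    return ContactMap(name, bin_size, n_bins, i, j, v)


@pytest.fixture(scope="session")
def small_synthetic():
    """A modest planted-model dataset shared by forward/inverse unit tests."""
    cfg = SyntheticConfig(n_bins=4000, d_max=6, window_size=4, depth=50.0, seed=7)
    rng = np.random.default_rng(cfg.seed)
    states = generate_states(cfg, rng)
    bank = plant_bank(cfg)
    cmap = simulate_contacts(states, bank, cfg, rng)
    return cfg, states, bank, cmap
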