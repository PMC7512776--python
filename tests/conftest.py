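import pytest

from entrank import SynthSpec, WeightedNetwork, random_network, toy_network


@pytest.fixture
def toy() -> WeightedNetwork:
    return toy_network()


def small_random_networks(count: int, max_n: int = 12, directed: bool = True,
                          seed0: int = 100):
    """Deterministic batch of small random networks spanning both
    reciprocity regimes (the fully reciprocal toy network cannot
    distinguish in- from out-neighbor conventions)."""
    nets = []
    for k in range(count):
        n = 4 + (k % (max_n - 3))
        spec = SynthSpec(
            n=n,
            density=0.15 + 0.07 * (k % 10),
            reciprocity=(k % 3) / 2.0,  # 0, 0.5, 1.0
            weight_dist=("uniform-integer", "geometric", "lognormal")[k % 3],
            directed=directed,
            rng_seed=seed0 + k,
        )
        nets.append(random_network(spec))
    return nets
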