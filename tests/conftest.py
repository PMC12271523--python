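import numpy as np
import pytest

from longax.fixtures import demo_atlas, demo_population_spec, generate_population
from longax.morpho import Morphology, MorphNode, SectionType


@pytest.fixture(scope="session")
def atlas():
    return demo_atlas()


@pytest.fixture(scope="session")
def demo_population(atlas):
    """59 labeled axons of the standard 5-cluster demo."""
    spec = demo_population_spec()
    morphs, labels, truth = generate_population(spec, atlas, seed=7)
    return morphs, labels, truth


def random_binary_tree(rng: np.random.Generator, n_leaves: int = 6,
                       scale: float = 100.0) -> Morphology:
    """Random axonal binary tree grown by splitting a random tip."""
    nodes = [
        MorphNode(1, None, rng.random(3) * scale, 2.0, SectionType.soma),
        MorphNode(2, 1, rng.random(3) * scale, 1.0, SectionType.axon),
    ]
    tips = [2]
    next_id = 3
    while len(tips) < n_leaves:
        tip = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            nodes.append(
                MorphNode(next_id, tip,
                          nodes[tip - 1].xyz + rng.normal(0, scale / 4, 3),
                          1.0, SectionType.axon)
            )
            tips.append(next_id)
            next_id += 1
        # occasionally extend a tip with polyline points
        if rng.random() < 0.5 and tips:
            t = tips.pop(int(rng.integers(len(tips))))
            nodes.append(
                MorphNode(next_id, t,
                          nodes[t - 1].xyz + rng.normal(0, scale / 4, 3),
                          1.0, SectionType.axon)
            )
            tips.append(next_id)
            next_id += 1
    return Morphology(nodes, neuron_id="rand")
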