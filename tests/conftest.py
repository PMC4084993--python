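import numpy as np
import pytest

import decophylo as dp


@pytest.fixture
def margotrema():
    return dp.load_margotrema_table()


@pytest.fixture
def three_tip_tree():
    return dp.DatedTree.from_newick("((x:1,y:1):1,z:2);")


@pytest.fixture
def two_area_space():
    return dp.build_state_space(["A", "B"], 2)


def random_instance(rng, max_tips=4, max_areas=3):
    """A random small DEC instance (tree, tip ranges, space, params)."""
    n_areas = int(rng.integers(2, max_areas + 1))
    areas = [chr(65 + i) for i in range(n_areas)]
    space = dp.build_state_space(areas, 2)
    n_tips = int(rng.integers(3, max_tips + 1))
    tree = dp.simulate_host_tree(1.0, n_tips, rng)
    d, e = rng.uniform(0.02, 0.6, 2)
    if rng.uniform() < 0.3:
        mult = rng.uniform(0.2, 3.0, (n_areas, n_areas))
        epochs = dp.EpochConfig(
            [tree.root_age * 0.4, 0.0], [mult, np.ones((n_areas, n_areas))]
        )
    else:
        epochs = None
    params = dp.DECParams(d=float(d), e=float(e), epochs=epochs)
    tip_ranges = {
        lab: space.labels(int(rng.integers(1, space.n_states)))
        for lab in tree.tip_labels
    }
    return tree, tip_ranges, space, params
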