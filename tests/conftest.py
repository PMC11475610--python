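import numpy as np
import pytest

from histovote.synthetic import generate_predictions, scenario_presets


@pytest.fixture(scope="session")
def trio_fitness_set():
    """500-sample prediction matrices for the complementary trio preset."""
    trio = scenario_presets()["complementary_trio"]
    matrices, truth = generate_predictions(500, trio, seed=11)
    return matrices, truth


@pytest.fixture(scope="session")
def tiny_image_tree(tmp_path_factory):
    """A small balanced synthetic image tree, indexed."""
    from histovote.synthetic import ImageScenario, generate_images

    root = tmp_path_factory.mktemp("images")
    scenario = ImageScenario(counts=(5,) * 8, image_size=48, seed=3)
    index = generate_images(scenario, root)
    return root, index


def simplex_grid_oracle(matrices, truth, step=0.01):
    """Exhaustive accuracy search over the weight simplex at a fixed step."""
    from histovote.ensemble import fitness_accuracy

    m = len(matrices)
    n_steps = round(1 / step)
    best = -1.0
    if m == 2:
        for i in range(n_steps + 1):
            best = max(best, fitness_accuracy(matrices, [i * step, 1 - i * step], truth))
    elif m == 3:
        for i in range(n_steps + 1):
            for j in range(n_steps + 1 - i):
                w = np.array([i, j, n_steps - i - j]) * step
                best = max(best, fitness_accuracy(matrices, w, truth))
    else:
        raise ValueError("grid oracle supports 2 or 3 models")
    return best
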