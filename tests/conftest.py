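import numpy as np
import pytest

from plantcloud import LabeledPointCloud, PlantSpec, gen_plant


@pytest.fixture(scope="session")
def dicot_plant() -> LabeledPointCloud:
    """A mid-size labeled dicot plant shared across tests."""
    return gen_plant(PlantSpec(morphology="dicot", n_leaves=6,
                               n_points=12_000, seed=11))


@pytest.fixture(scope="session")
def monocot_plant() -> LabeledPointCloud:
    return gen_plant(PlantSpec(morphology="monocot", n_leaves=5,
                               n_points=12_000, seed=12))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_cloud(rng, n, labeled=False) -> LabeledPointCloud:
    coords = rng.normal(size=(n, 3)) * 10
    if not labeled:
        return LabeledPointCloud(coords=coords)
    sem = rng.integers(0, 2, n)
    ins = np.where(sem == 1, rng.integers(0, 3, n), -1)
    return LabeledPointCloud(coords=coords, sem=sem, ins=ins, n_classes=2)
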