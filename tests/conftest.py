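import numpy as np
import pytest

from paleoneuro import (
    LabyrinthShapeParams,
    LandmarkConfiguration,
    generate_population,
    load_example_table,
)


@pytest.fixture(scope="session")
def table1_ds():
    return load_example_table("table1")


@pytest.fixture(scope="session")
def table3_ds():
    return load_example_table("table3")


@pytest.fixture(scope="session")
def table4_ds():
    return load_example_table("table4")


@pytest.fixture(scope="session")
def table5_ds():
    return load_example_table("table5")


@pytest.fixture(scope="session")
def table6_ds():
    return load_example_table("table6")


@pytest.fixture(scope="session")
def two_cluster_population():
    """Two labyrinth clusters separated along the height/width axis, with
    landmark noise well below the between-group effect (>= 5x)."""
    groups = [
        (LabyrinthShapeParams(height_width_ratio=0.75, noise_sd=0.01),
         "longirostrine", 10),
        (LabyrinthShapeParams(height_width_ratio=1.25, noise_sd=0.01),
         "brevirostrine", 10),
    ]
    return generate_population(groups, seed=42)


def random_rigid_motion(rng: np.random.Generator):
    """A random proper rotation, positive scale, and translation."""
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    scale = rng.uniform(0.3, 3.0)
    shift = rng.normal(scale=20.0, size=3)
    return q, scale, shift


def apply_rigid_motion(config: LandmarkConfiguration, rng: np.random.Generator):
    q, scale, shift = random_rigid_motion(rng)
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        coordinates=config.coordinates @ q * scale + shift,
        curve_ids=config.curve_ids,
        is_semilandmark=config.is_semilandmark,
    )
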