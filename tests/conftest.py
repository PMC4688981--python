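import numpy as np
import pytest

from morphatlas import (
    ExperimentConfig,
    LabelVolume,
    SyntheticConfig,
    generate_database,
    run_full_experiment,
)


def make_volume(voxels, spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    return LabelVolume(np.asarray(voxels, dtype=np.uint8), spacing)


def blob_volume(shape=(12, 12, 12), lo=3, hi=9) -> LabelVolume:
    vox = np.zeros(shape, np.uint8)
    vox[lo:hi, lo:hi, lo:hi] = 1
    return LabelVolume(vox)


@pytest.fixture
def blob():
    return blob_volume()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom settings: 32^3 grid, protractions fitting its extent."""
    return SyntheticConfig(
        n_atlases=5,
        grid_shape=(32, 32, 32),
        spacing_mm=(2.0, 2.0, 2.0),
        protraction_range_mm=(20.0, 42.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_db(small_config):
    return generate_database(small_config)


@pytest.fixture(scope="session")
def full_experiment():
    """The default-condition experiment: 12 phantoms at 48^3/2 mm, k=2..8,
    selected and random arms with shared propagations, fixed seed."""
    config = SyntheticConfig(seed=0)
    db = generate_database(config)
    result = run_full_experiment(
        db,
        synthetic_config=config,
        experiment_config=ExperimentConfig(seed=0),
    )
    return config, db, result
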