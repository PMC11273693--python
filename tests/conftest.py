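import numpy as np
import pytest

from svct.geometry import FanBeamGeometry
from svct.phantom import PhantomSpec, make_dataset, PhantomDataset
from svct.pipeline import TrainConfig


@pytest.fixture(scope="session")
def desk_geometry():
    """Reduced-scale scanner: 180 detectors, 180/60/20 views."""
    return FanBeamGeometry(n_detectors=180, n_views_standard=180,
                           n_views_intermediate=60, n_views_sparse=20)


@pytest.fixture(scope="session")
def tiny_geometry():
    """Very small scanner for fast operator and pipeline tests."""
    return FanBeamGeometry(n_detectors=48, n_views_standard=48,
                           n_views_intermediate=12, n_views_sparse=4)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_geometry, tmp_path_factory):
    """Eight-phantom paired dataset at 32 px (shared across pipeline tests)."""
    path = tmp_path_factory.mktemp("data") / "tiny.h5"
    spec = PhantomSpec(image_size=32, seed=11)
    make_dataset(6, 2, spec, tiny_geometry, path)
    return PhantomDataset(path)


@pytest.fixture(scope="session")
def tiny_train_config(tiny_geometry):
    """Seconds-scale two-phase training configuration on 32 px images."""
    return TrainConfig(geometry=tiny_geometry, image_size=32, depth=1,
                       base_width=4, n_primitives=4, critic_widths=(4, 8),
                       epochs=2, batch_size=2, max_steps=6, gan_epochs=1,
                       max_gen_steps=1, critic_steps_per_gen=2, seed=0,
                       scale_preset="desk", val_fraction=0.34)
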