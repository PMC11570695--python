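import numpy as np
import pytest

from glucopipe.pipeline import RunConfig, run_pipeline
from glucopipe.synthetic_imaging import (
    DEFAULT_CAMERAS,
    GeneratorConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """Four classes x 6 images at 64x64, low noise: fast train/IO fixture."""
    root = tmp_path_factory.mktemp("tiny_dataset")
    cfg = GeneratorConfig(
        concentrations=(50, 100, 150, 200),
        lightings=("natural", "artificial"),
        locations=(1,),
        cameras=(DEFAULT_CAMERAS[0],),
        replicates=3,
        image_size=(64, 64),
        noise_sigma=1.0,
        master_seed=123,
    )
    generate_dataset(cfg, root)
    return root


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One complete small-profile pipeline run at a fixed seed."""
    out = tmp_path_factory.mktemp("small_run")
    summary = run_pipeline(RunConfig.small_profile(seed=0), out)
    return summary


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
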