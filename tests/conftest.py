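import numpy as np
import pytest
from scipy import ndimage

from viewscape.grids import ElevationGrid, GridSpec


def smooth_random_terrain(seed: int, n: int = 64, amp: float = 8.0,
                          cellsize: float = 1.0) -> ElevationGrid:
    """Correlated random terrain (Gaussian-filtered white noise)."""
    rng = np.random.default_rng(seed)
    z = ndimage.gaussian_filter(rng.normal(0.0, amp, (n, n)), 3)
    return ElevationGrid(GridSpec(0.0, 0.0, cellsize, n, n), z)


@pytest.fixture
def flat_grid():
    """41x41 flat terrain at z=0, 1 m cells."""
    return ElevationGrid(GridSpec(0.0, 0.0, 1.0, 41, 41), np.zeros((41, 41)))


@pytest.fixture(scope="session")
def tiny_scene_outputs(tmp_path_factory):
    """One pipeline run on a small self-similar scene, shared by tests."""
    from viewscape.pipeline import PipelineConfig, run_pipeline
    from viewscape.synthetic import scaled_scene

    out = tmp_path_factory.mktemp("tiny_pipeline")
    scene = scaled_scene(0.3, n_photos=120, seed=424)
    cfg = PipelineConfig(out_dir=str(out), sample_fraction=0.2, sample_seed=9)
    cfg.scene = scene
    manifest = run_pipeline(cfg)
    return cfg, manifest, out
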