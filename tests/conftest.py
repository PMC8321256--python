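import numpy as np
import pytest

from veglatent.compositing import fill_gaps, monthly_median, pixel_matrix
from veglatent.indices import compute_stack
from veglatent.simulate import SimConfig, default_profiles, simulate_scenes


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        grid_size=32,
        scenes_per_month=2,
        cloud_fraction=0.1,
        seed=11,
        profiles=default_profiles(points_scale=0.05),
    )


@pytest.fixture(scope="session")
def small_scenes(small_config):
    return simulate_scenes(small_config)


@pytest.fixture(scope="session")
def small_composite(small_scenes):
    scenes, _ = small_scenes
    stacks = [compute_stack(s) for s in scenes]
    comp, dropped = fill_gaps(monthly_median(stacks))
    return comp, dropped


@pytest.fixture(scope="session")
def small_matrix(small_composite):
    comp, dropped = small_composite
    return pixel_matrix(comp, exclude=dropped)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_band_pixels(rng, n):
    """n random valid reflectance pixels as a dict of arrays in (0.01, 0.99)."""
    return {role: rng.uniform(0.01, 0.99, size=n) for role in ("B", "G", "R", "RE1", "RE3", "N")}
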