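import numpy as np
import pytest
from hypothesis import settings

from ovaspec import calibrate_cube, segment_roi, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SMALL_SHAPE = (24, 24)


@pytest.fixture(scope="session")
def small_design():
    return synthetic.StorageDesign(eggs_per_day=2, seed=0)


@pytest.fixture(scope="session")
def small_dataset(small_design):
    """20 eggs at 24x24: raw cubes, references, planted masks, truths."""
    seqs = np.random.SeedSequence(small_design.seed).spawn(small_design.n_samples + 1)
    white, dark = synthetic.make_reference_cubes(SMALL_SHAPE, np.random.default_rng(seqs[0]))
    eggs = list(synthetic.iter_eggs(small_design, SMALL_SHAPE))
    return {"eggs": eggs, "white": white, "dark": dark}


@pytest.fixture(scope="session")
def small_calibrated(small_dataset):
    """Calibrated cubes plus planted masks for the small dataset."""
    return [
        (calibrate_cube(e.cube, small_dataset["white"], small_dataset["dark"]), e.mask, e.truth)
        for e in small_dataset["eggs"]
    ]
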