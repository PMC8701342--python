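import numpy as np
import pytest

from copyamp.coverage import BinnedTrack, DepthTrack
from copyamp.plasmid import PlasmidSpec
from copyamp.regions import RegionMask
from copyamp.simulate import EventSet, GenomeLayout, NoiseModel


@pytest.fixture
def small_layout():
    return GenomeLayout([("chrI", 20_000), ("chrII", 15_000), ("chrIV", 50_000)])


@pytest.fixture
def det_noise():
    """Deterministic (noise-disabled) model for exact identity tests."""
    return NoiseModel(mean_depth=30.0, dispersion=10.0, seed=0, deterministic=True)


@pytest.fixture
def plasmid_spec():
    """8 kb plasmid with a 1.6 kb block shared with the genome."""
    return PlasmidSpec("plasmid", 8000, RegionMask([("plasmid", 1600, 3200)]))


@pytest.fixture
def flat_profile():
    """Normalized euploid profile: 100 bins of 1 kb, all at 1.0."""
    starts = np.arange(100) * 1000
    return BinnedTrack(
        "chrI", starts, starts + 1000, np.ones(100), 1000, genome_mean=30.0
    )


def make_profile(values, sequence="chrI", bin_size=1000, genome_mean=30.0):
    values = np.asarray(values, dtype=float)
    starts = np.arange(values.size) * bin_size
    return BinnedTrack(
        sequence, starts, starts + bin_size, values, bin_size, genome_mean=genome_mean
    )


@pytest.fixture
def profile_factory():
    return make_profile
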