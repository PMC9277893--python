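import numpy as np
import pytest

from clscreen.syndata import ArchetypeSpec, FluorModel, ScreenDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def noiseless_archetypes():
    """Control trio without plate/replicate noise (deterministic decay)."""
    return {
        "short_lived": ArchetypeSpec("short_lived", tau=2.0, plate_sd=0.0, rep_sd=0.0),
        "average": ArchetypeSpec("average", tau=4.0, plate_sd=0.0, rep_sd=0.0),
        "long_lived": ArchetypeSpec("long_lived", tau=8.0, plate_sd=0.0, rep_sd=0.0),
    }


@pytest.fixture
def small_design():
    """One small plate, light event load — for fast unit tests."""
    return ScreenDesign(plates=1, wells_per_plate=8, events_per_sample=2_000, seed=11)


@pytest.fixture
def fluor():
    return FluorModel()
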