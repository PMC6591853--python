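import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dermengraft as dg
from dermengraft.profiles import normalize_counts
from dermengraft.simulate import StudyDesign

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (18 subjects, full 13-day grid)."""
    return dg.simulate_study(seed=7)


@pytest.fixture(scope="session")
def default_series(default_study):
    study = default_study
    abund = {
        "slst": normalize_counts(study.slst_counts),
        "genus": normalize_counts(study.genus_counts),
    }
    series = dg.engraftment_timecourse(abund, study.metadata, study.solutions)
    return study, abund, series


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (short day grid) for fast I/O and pipeline tests."""
    design = StudyDesign(sampling_days=(0, 1, 2, 3, 5, 8), reads_per_sample=2000)
    return dg.simulate_study(design=design, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def archetypes():
    return dg.default_archetypes()


def random_profiles(rng, n, k, scale=100.0):
    return pd.DataFrame(rng.dirichlet(np.full(k, 0.7), size=n) * scale)
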