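import numpy as np
import pytest
from hypothesis import settings

from nirlipid import regress, synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def diet_profiles():
    return synth.default_diet_profiles()


@pytest.fixture(scope="session")
def study():
    """A full synthetic calibration study: 100 lobes, 5 diets, default
    noise, preprocessed to SNV sample spectra."""
    spectra, truth = synth.simulate_study(n_per_diet=20, seed=1)
    return regress.CalibrationSet.from_spectra(spectra, truth), truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_calibration():
    """A small, fast calibration set (30 lobes) for oracle-equivalence
    and API tests that do not need high accuracy."""
    spectra, truth = synth.simulate_study(
        n_per_diet=6, seed=7, lobe_shape=(8, 8)
    )
    return regress.CalibrationSet.from_spectra(spectra, truth)
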