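import numpy as np
import pytest

import gelspec as gs
from gelspec.circuit import default_frequency_grid


@pytest.fixture
def band_grid() -> np.ndarray:
    """50-point log grid over the 2-300 kHz measurement band."""
    return default_frequency_grid(50)


@pytest.fixture
def simple_spectrum() -> gs.ImpedanceSpectrum:
    return gs.ImpedanceSpectrum(
        frequencies=np.array([2000.0, 6000.0, 300000.0]),
        resistance=np.array([100.0, 80.0, 10.0]),
        reactance=np.array([-50.0, -40.0, -5.0]),
        sample_id="egg1",
    )


@pytest.fixture
def spectrum_csv(tmp_path, simple_spectrum):
    path = tmp_path / "egg1.csv"
    gs.write_spectrum(simple_spectrum, path)
    return path


@pytest.fixture
def tiny_cohort_spec() -> gs.CohortSpec:
    """Down-scaled cohort for fast unit tests (full-size runs live in the
    acceptance suite)."""
    return gs.CohortSpec(n_gelled_train=4, n_non_gelled_train=4,
                         n_gelled_test=6, n_non_gelled_test=6,
                         n_frequencies=20, seed=7)
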