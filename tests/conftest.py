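import numpy as np
import pandas as pd
import pytest

from nirfly.spectra_io import SpectrumSet
from nirfly.synthetic_data import SyntheticConfig, generate_population, \
    generate_wolbachia_population
from nirfly.pipeline import run_all_studies


def make_set(values, wavelengths=None, units="absorbance", **meta_cols):
    """Build a SpectrumSet from a 2-D array with auto-generated metadata."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    if wavelengths is None:
        wavelengths = 400.0 + np.arange(p)
    meta = {"sample_id": [f"s{i}" for i in range(n)]}
    for col, vals in meta_cols.items():
        meta[col] = list(vals)
    return SpectrumSet(wavelengths, values, pd.DataFrame(meta), units=units)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def full_study_results():
    """The four study protocols run end to end at the default design.

    Full scale (2520 calibration spectra for the species model, 45 flies per
    cell) at one fixed seed; shared across tests because it takes ~1 minute.
    """
    pop = generate_population(seed=42)
    wol = generate_wolbachia_population(seed=42)
    return run_all_studies(pop, wol)
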