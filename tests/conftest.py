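import numpy as np
import pytest

from nirmap.io_formats import SpectraSet, WavelengthAxis
from nirmap.synthetic import PhantomSpec, generate_dataset


@pytest.fixture(scope="session")
def default_axis():
    return WavelengthAxis.default()


@pytest.fixture(scope="session")
def small_spectra(default_axis):
    """Seeded random 12-spectrum set on the instrument axis (4 groups x 3)."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.2, 1.5, size=(12, len(default_axis)))
    ids = [f"s{i}" for i in range(12)]
    groups = [f"g{i // 3}" for i in range(12)]
    return SpectraSet(values, default_axis, ids, groups)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Study-design phantom with scatter and noise switched off."""
    spec = PhantomSpec(gain_sd=0, offset_sd=0, slope_sd=0, noise_sd=0)
    return generate_dataset(spec, seed=5)


@pytest.fixture(scope="session")
def default_dataset():
    """Study-design phantom at the default noise/scatter conditions."""
    return generate_dataset(PhantomSpec(), seed=7)
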