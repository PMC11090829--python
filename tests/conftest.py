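import numpy as np
import pytest

from orgfid import BinScheme, cohort_spec, fit_bin_scheme, gen_cohort


@pytest.fixture(scope="session")
def normal_cohort():
    """Default normal-tissue ST cohort (the bin-scheme reference)."""
    return gen_cohort(cohort_spec("normal", seed=1), "ST", "normal-ST")


@pytest.fixture(scope="session")
def normal_scheme(normal_cohort):
    return fit_bin_scheme(normal_cohort, reference_label="normal-ST")


@pytest.fixture()
def symmetric_scheme():
    return BinScheme(q25=-1.0, q50=0.0, q75=1.0, reference_label="synthetic")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
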