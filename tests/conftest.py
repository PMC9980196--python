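import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def dispensing(*rows):
    """Build a dispensing DataFrame from (patient, atc, date) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "atc", "date"])


def ect(*rows):
    return pd.DataFrame(rows, columns=["patient_id", "date"])


@pytest.fixture
def make_dispensing():
    return dispensing


@pytest.fixture
def make_ect():
    return ect


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small synthetic cohort for read-only tests."""
    from trdprs import SynthConfig, generate_cohort

    cfg = SynthConfig(n_cases_trd=80, n_nontrd=120, n_snps=300, seed=7)
    return generate_cohort(cfg)
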