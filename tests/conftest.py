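import numpy as np
import pytest

from piolcalc.cohort import CohortSpec, mean_eye, sample_cohort
from piolcalc.design import synth_design_table
from piolcalc.eye import EyeBiometry


@pytest.fixture(scope="session")
def design_table():
    """Surrogate 58-step design table (defaults)."""
    return synth_design_table()


@pytest.fixture(scope="session")
def table1_mean_eye():
    """Eye with the reference-population mean biometry."""
    return mean_eye()


@pytest.fixture(scope="session")
def clinical_eye():
    """Schematic-eye cornea used in the worked clinical example (AQD 3.00 mm)."""
    return EyeBiometry(rc_a=7.77, rc_p=6.40, cct=0.50, aqd=3.00, lt=4.0)


@pytest.fixture(scope="session")
def random_eyes():
    """100 seeded eyes from the default cohort generator."""
    return sample_cohort(CohortSpec(n_eyes=100, seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
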