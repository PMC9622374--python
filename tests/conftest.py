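import numpy as np
import pytest

from oformula.biometry import BiometryRecord
from oformula.elp import DEFAULT_SYNTHETIC_COEFFICIENTS
from oformula.synth import CohortParams, make_design_table, sample_cohort


@pytest.fixture(scope="session")
def mean_record():
    """A synthetic eye at the population mean of every biometric field."""
    return BiometryRecord(
        al_display=24.31, cct=0.545, aqd=2.69, lt=4.68, ata_depth=3.25,
        le_depth=4.14, nuclear_grade=2.2, r_ant_steep=7.61, r_ant_flat=7.72,
        r_post_steep=6.26, r_post_flat=6.52, e_ant=0.52, e_post=0.67,
        eye_id="mean",
    )


@pytest.fixture(scope="session")
def design():
    return make_design_table()


@pytest.fixture(scope="session")
def coefficients():
    return DEFAULT_SYNTHETIC_COEFFICIENTS


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(CohortParams(n=25, seed=11))
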