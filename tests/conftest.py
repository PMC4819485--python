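import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from audioscreen import (
    Audiogram,
    InclusionCriteria,
    PatientRecord,
    load_default_table,
    load_grading_scales,
)

# Synthetic reconstruction of the published worked example: a 65-year-old
# female screening candidate whose acute 4PTA is 53.75 dB HL and whose
# contralateral-ear comparison yields five qualifying three-frequency
# windows with a maximum mean difference of 46.67 dB at 0.5-2 kHz.
ACUTE_THRESHOLDS = {0.125: 40, 0.25: 45, 0.5: 50, 1: 50, 2: 55, 3: 55, 4: 60, 6: 50, 8: 45}
CONTRA_THRESHOLDS = {0.125: 10, 0.25: 10, 0.5: 10, 1: 5, 2: 0, 3: 20, 4: 30, 6: 40, 8: 40}


@pytest.fixture(scope="session")
def scales():
    return load_grading_scales()


@pytest.fixture(scope="session")
def iso_table():
    return load_default_table()


@pytest.fixture(scope="session")
def default_criteria():
    return InclusionCriteria(min_severity_db=50.0, min_window_mean_difference_db=30.0)


@pytest.fixture
def worked_example_record():
    return PatientRecord(
        acute=Audiogram(ACUTE_THRESHOLDS, ear="affected", role="acute"),
        id="worked-example",
        age=65,
        sex="female",
        baseline_contralateral=Audiogram(
            CONTRA_THRESHOLDS, ear="contralateral", role="baseline_contralateral"
        ),
    )
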