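import pytest

from edplot import Direction, OutcomeRecord, Quality, StudyMetadata
from edplot.io import housing_example


@pytest.fixture(scope="session")
def housing():
    """The packaged synthetic warmth/energy-efficiency review."""
    return housing_example()


@pytest.fixture
def tiny_dataset():
    """Well-formed 2-study, 1-domain dataset."""
    records = [
        OutcomeRecord("S1", "sleep", "sleep quality", Direction.POSITIVE),
        OutcomeRecord("S1", "sleep", "sleep duration", Direction.POSITIVE),
        OutcomeRecord("S2", "sleep", "sleep quality", Direction.NEGATIVE),
    ]
    studies = [
        StudyMetadata("S1", "RCT", 120, Quality.HIGH),
        StudyMetadata("S2", "cohort", 40, Quality.LOW),
    ]
    return records, studies
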