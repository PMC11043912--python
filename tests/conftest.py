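import pytest

from mtlnova import (
    PRINTED_COUNTS,
    AnalysisConfig,
    default_thresholds,
    fixture_printed_counts,
    run_study,
)
from mtlnova.databank import filter_classifiable


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


@pytest.fixture(scope="session")
def fixture_bank():
    """Deterministic databank realizing the published contingency counts."""
    return fixture_printed_counts(PRINTED_COUNTS)


@pytest.fixture(scope="session")
def fixture_classifiable(fixture_bank):
    return filter_classifiable(fixture_bank).databank


@pytest.fixture(scope="session")
def fixture_report(fixture_bank):
    """Full study report on the printed-counts fixture (computed once)."""
    return run_study(fixture_bank, AnalysisConfig())
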