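import pytest

from crowdcbr import datasets
from crowdcbr.cbr_reasoner import CaseBase


@pytest.fixture(scope="session")
def survey():
    """The packaged 100-record survey sample, labelled for the depression task."""
    return datasets.load_survey("E_DEP").categorize()


@pytest.fixture(scope="session")
def cooccurrence_table():
    return datasets.load_cooccurrence()


@pytest.fixture(scope="session")
def association_levels():
    return datasets.load_association_levels()


@pytest.fixture(scope="session")
def table2_kb():
    """KB taken from the published association levels, features renamed
    to survey columns (depression task)."""
    return datasets.association_level_kb("E_DEP")


@pytest.fixture(scope="session")
def survey_case_base(survey):
    return CaseBase.fit(survey)
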