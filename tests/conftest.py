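import pytest

from moxatox import datasets
from moxatox.lethality import MortalityTable


@pytest.fixture
def study_mortality() -> MortalityTable:
    """The five-group (A-E) acute-toxicity quantal design."""
    return datasets.mortality_table()


@pytest.fixture
def uniform_design() -> MortalityTable:
    """Geometric dose ladder 10/100/1000 with mortality 0, 0.5, 1."""
    return MortalityTable.from_records([(10, 10, 0), (100, 10, 5), (1000, 10, 10)])
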