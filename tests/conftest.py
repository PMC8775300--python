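import pytest

from periomr import SummaryRecord, SummaryTable, load_table1_fixture


@pytest.fixture(scope="session")
def fixture_table() -> SummaryTable:
    return load_table1_fixture()


@pytest.fixture
def small_table() -> SummaryTable:
    trait = "toy exposure"
    records = [
        SummaryRecord("rs1", "a", 0.02, 0.003, 1e-10, other_allele="g", eaf=0.3, trait=trait),
        SummaryRecord("rs2", "t", -0.015, 0.004, 2e-9, other_allele="c", eaf=0.45, trait=trait),
        SummaryRecord("rs3", "c", 0.03, 0.005, 5e-12, other_allele="a", eaf=0.1, trait=trait),
    ]
    return SummaryTable(records=records, trait=trait)
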