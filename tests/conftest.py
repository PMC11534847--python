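import logging

import pytest

from mlpbpk import (
    load_default_physiology,
    load_drug_table,
    default_drug_table_path,
    load_benchmark_table,
)

logging.getLogger("mlpbpk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def body():
    return load_default_physiology()


@pytest.fixture(scope="session")
def ml_records():
    return load_drug_table(default_drug_table_path(), "ml")


@pytest.fixture(scope="session")
def invitro_records():
    return load_drug_table(default_drug_table_path(), "invitro")


@pytest.fixture(scope="session")
def benchmark_table():
    return load_benchmark_table()


@pytest.fixture(scope="session")
def drug_by_name(ml_records):
    return {r.name: r for r in ml_records}
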