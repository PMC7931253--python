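import pytest

from foodex import FoodClass, canonical_name, load_table2, load_table4


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def table4():
    return load_table4()


@pytest.fixture(scope="session")
def dishes(table2):
    return [row for row in table2 if row.record.food_class is FoodClass.dish]


@pytest.fixture(scope="session")
def sweets(table2):
    return [row for row in table2 if row.record.food_class is FoodClass.sweet]


@pytest.fixture(scope="session")
def table2_by_name(table2):
    return {canonical_name(row.record.name): row for row in table2}


@pytest.fixture(scope="session")
def table4_by_name(table4):
    return {canonical_name(row.name): row for row in table4}


@pytest.fixture(scope="session")
def record(table2_by_name):
    def _get(name):
        return table2_by_name[canonical_name(name)].record

    return _get
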