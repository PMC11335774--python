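import pytest

from lexstat import builtin_fixture, db_from_spec


@pytest.fixture(scope="session")
def table1_db():
    """The three analyses of the noun form silmäsi."""
    return db_from_spec(builtin_fixture("table1_silmasi"))


@pytest.fixture(scope="session")
def table3_db():
    """Five readings of the form voi (verb voida / interjection / noun)."""
    return db_from_spec(builtin_fixture("table3_voi"))


@pytest.fixture(scope="session")
def table4_db():
    """The six most frequent forms of the noun voi ('butter')."""
    return db_from_spec(builtin_fixture("table4_voi_forms"))


@pytest.fixture(scope="session")
def table5_db():
    """Ten noisy lemma/word-class readings of the form voit."""
    return db_from_spec(builtin_fixture("table5_voit"))
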