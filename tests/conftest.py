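import pytest

from haplopurge.alignment_metrics import filter_eligible
from haplopurge.fixtures import (
    FixtureSpec,
    make_alignment_table,
    make_busco_catalog,
    make_fixture,
)


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def planted(default_spec):
    """Default planted-haplotig fixture: contigs, truth, table, catalog."""
    contigs, truth = make_fixture(default_spec)
    table = filter_eligible(make_alignment_table(contigs, truth, default_spec))
    catalog = make_busco_catalog(contigs, truth, default_spec)
    return contigs, truth, table, catalog
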