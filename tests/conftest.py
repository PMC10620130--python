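import pytest

from gistcin.segment_io import GenomeBuild, b37
from gistcin.synthetic_data import load_fixture


@pytest.fixture(scope="session")
def build():
    return b37()


@pytest.fixture(scope="session")
def tiny_build():
    """A one-chromosome 100 Mb toy genome for closed-form score checks."""
    return GenomeBuild(name="toy", chromosomes=(("1", 100_000_000),))


@pytest.fixture(scope="session")
def cohort_fixture():
    """The bundled 21-sample cohort CIN count table."""
    return load_fixture("cohort_cin")


@pytest.fixture(scope="session")
def chromothripsis_fixture():
    return load_fixture("chromothripsis")
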