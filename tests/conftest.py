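import pytest

from adcea import paper_fixture


@pytest.fixture(scope="session")
def base_spec():
    """The bundled base-case model parameterization."""
    return paper_fixture()


# Printed state times (2 d.p.) used to cross-check economics arithmetic.
PRINTED_TIMES = {
    "ChEI alone": {"alive": 5.66, "community": 4.57},
    "ChEI + memantine": {"alive": 5.66, "community": 5.54},
}
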