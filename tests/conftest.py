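import io

import pytest
from hypothesis import HealthCheck, settings

from strandfit import Oligomer, P4_SEQ, P10_SEQ, RES_SEQ, read_topology

settings.register_profile(
    "ci",
    database=None,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def res():
    return Oligomer("res", RES_SEQ)


@pytest.fixture
def p4():
    return Oligomer("p4", P4_SEQ)


@pytest.fixture
def p10():
    return Oligomer("p10", P10_SEQ)


def make_topology(*oligomers: Oligomer):
    """Topology over the given strands with 5'->3' global indexing."""
    from strandfit import topology_from_oligomers

    return topology_from_oligomers(oligomers)


@pytest.fixture
def two_acgt_topology():
    """Two 4-mers named a and b, both ACGT; globals a=0..3, b=4..7."""
    return make_topology(Oligomer("a", "ACGT"), Oligomer("b", "ACGT"))


def topology_text(*oligomers: Oligomer) -> str:
    """Canonical topology file text for the given strands."""
    import io as _io

    from strandfit import write_topology

    buf = _io.StringIO()
    write_topology(make_topology(*oligomers), buf)
    return buf.getvalue()


def parse_topology(text: str, names=None):
    return read_topology(io.StringIO(text), names=names)
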