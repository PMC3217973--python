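import numpy as np
import pytest

from spliceid import ProteinRecord


def make_record(seq, id="p1", label="unknown", domains=()):
    return ProteinRecord(id=id, sequence=seq, label=label, domains=frozenset(domains))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def record_factory():
    return make_record
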