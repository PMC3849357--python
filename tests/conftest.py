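import numpy as np
import pytest
from hypothesis import settings

from allonet.datatypes import Alignment, SeqRecord

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def small_alignment():
    return Alignment(
        [
            SeqRecord("a", "ACDEF"),
            SeqRecord("b", "ACDEF"),
            SeqRecord("c", "ACDEG"),
            SeqRecord("d", "KCDEG"),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_alignment(rng):
    from allonet.datatypes import AMINO_ACIDS

    aas = np.array(list(AMINO_ACIDS))

    def _make(ids, length):
        return Alignment(
            [
                SeqRecord(i, "".join(aas[rng.integers(0, 20, size=length)]))
                for i in ids
            ]
        )

    return _make
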