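import pytest

from ctdegron.phylo import ScoringScheme
from ctdegron.seqio import ProteinRecord, SequenceFamily


@pytest.fixture
def unit_scheme():
    """Match +1 / mismatch -1, gap open 1 / extend 1."""
    return ScoringScheme.simple()


@pytest.fixture
def small_family():
    return SequenceFamily([
        ProteinRecord("s1", "MKTAYIAKQR"),
        ProteinRecord("s2", "MKTAYIVKQR"),
        ProteinRecord("s3", "MKTWYIAKQR"),
    ])


@pytest.fixture
def dup_family():
    """Records 2 and 4 duplicate record 1."""
    return SequenceFamily([
        ProteinRecord("r1", "MKTAYIAKQR"),
        ProteinRecord("r2", "MKTAYIAKQR"),
        ProteinRecord("r3", "MKTWYIAKQR"),
        ProteinRecord("r4", "MKTAYIAKQR"),
        ProteinRecord("r5", "MKVAYIAKQR"),
    ])
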