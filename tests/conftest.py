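import numpy as np
import pytest

from ribostall import (
    CodonCountTrack,
    TranscriptModel,
    TranscriptSet,
)


def make_cds(internal_codons, stop="TAA"):
    """Build a CDS string: ATG + the given internal codons + a stop."""
    return "ATG" + "".join(internal_codons) + stop


@pytest.fixture
def toy_transcript():
    """6-codon gene: ATG AAA AAA AAA TGG TAA (hand-arithmetic toy)."""
    return TranscriptModel("g1", make_cds(["AAA", "AAA", "AAA", "TGG"]))


@pytest.fixture
def toy_set(toy_transcript):
    return TranscriptSet([toy_transcript])


def make_track(transcript, counts):
    arr = np.zeros(transcript.n_codons, dtype=np.int64)
    for pos, n in counts.items():
        arr[pos] = n
    return CodonCountTrack(transcript.transcript_id, arr)
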