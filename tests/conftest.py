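"""Shared fixtures: small hand-constructed transcripts and read sets."""

from __future__ import annotations

import numpy as np
import pytest

from scrleak.records import FootprintRead, TranscriptRecord


def make_transcript(
    tid: str = "tx",
    utr5: int = 20,
    n_sense_codons: int = 40,
    stop_codon: str = "UGA",
    second_stop_distance: int | None = 90,
    utr3: int = 150,
    filler: str = "C",
    rng: np.random.Generator | None = None,
) -> TranscriptRecord:
    """A structurally valid transcript made of non-stop filler codons.

    ``filler='C'`` gives a fully deterministic sequence (CCC codons are
    sense), which makes window positions easy to enumerate by hand.
    """
    cds_body = "AUG" + filler * (3 * (n_sense_codons - 1))
    stop_start = utr5 + len(cds_body)
    if second_stop_distance is None:
        tail = filler * utr3
    else:
        assert second_stop_distance % 3 == 0
        tail = filler * second_stop_distance + "UAA" + filler * (utr3 - second_stop_distance - 3)
    seq = filler * utr5 + cds_body + stop_codon + tail
    return TranscriptRecord(
        id=tid, sequence=seq, cds_start=utr5, stop_start=stop_start, stop_codon=stop_codon
    )


@pytest.fixture
def transcript() -> TranscriptRecord:
    return make_transcript()


def reads_at(tid: str, starts: list[int], length: int = 28) -> list[FootprintRead]:
    return [FootprintRead(transcript_id=tid, start=s, length=length) for s in starts]
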