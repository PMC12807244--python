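"""Ribosome density profiles from footprint read tables.

The density profile of a transcript is the per-nucleotide count of footprints
covering each position (full-footprint coverage, not P-site-collapsed
counts).  The downstream rate estimator works on window sums of this profile,
so footprint geometry is absorbed by the window definitions.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .records import DensityProfile, FootprintRead, ScrLeakError

#: 1-based position of the ribosomal P-site within a footprint.
PSITE_OFFSET = 13


class ReadOutOfBoundsError(ScrLeakError):
    """A footprint extends outside its transcript."""


def build_density_profile(
    reads: Iterable[FootprintRead],
    transcript_length: int,
    transcript_id: str | None = None,
) -> DensityProfile:
    """Accumulate footprint coverage into a per-nucleotide count vector.

    ``counts[p]`` equals the number of reads whose half-open interval
    ``[start, start + length)`` contains ``p``.  Reads extending outside
    ``[0, transcript_length)`` raise :class:`ReadOutOfBoundsError` naming the
    offending read.
    """
    diff = np.zeros(transcript_length + 1, dtype=np.int64)
    tid = transcript_id
    for read in reads:
        if tid is None:
            tid = read.transcript_id
        if read.start + read.length > transcript_length:
            raise ReadOutOfBoundsError(
                f"read (start={read.start}, length={read.length}) on "
                f"{read.transcript_id} extends past transcript end ({transcript_length} nt)"
            )
        diff[read.start] += 1
        diff[read.start + read.length] -= 1
    counts = np.cumsum(diff[:-1])
    return DensityProfile(transcript_id=tid or "", counts=counts)


def build_density_profile_from_starts(
    starts: np.ndarray,
    lengths: np.ndarray,
    transcript_length: int,
    transcript_id: str = "",
) -> DensityProfile:
    """Vectorised variant of :func:`build_density_profile` for array input."""
    starts = np.asarray(starts, dtype=np.int64)
    lengths = np.asarray(lengths, dtype=np.int64)
    if starts.size and (starts.min() < 0 or (starts + lengths).max() > transcript_length):
        raise ReadOutOfBoundsError(f"reads on {transcript_id or '<anonymous>'} extend outside the transcript")
    diff = np.zeros(transcript_length + 1, dtype=np.int64)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + lengths, -1)
    return DensityProfile(transcript_id=transcript_id, counts=np.cumsum(diff[:-1]))


def psite_position(read: FootprintRead) -> int:
    """0-based transcript offset of the ribosomal P-site of a footprint.

    The P-site occupies the 13th nucleotide of the protected fragment
    (1-based), i.e. offset ``start + 12``.
    """
    if read.length < PSITE_OFFSET:
        raise ScrLeakError(
            f"read of length {read.length} is too short to carry a P-site "
            f"(needs >= {PSITE_OFFSET} nt)"
        )
    return read.start + PSITE_OFFSET - 1


def asite_position(read: FootprintRead) -> int:
    """0-based offset of the A-site: one codon downstream of the P-site."""
    return psite_position(read) + 3
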