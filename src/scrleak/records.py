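"""Core record types shared by every pipeline stage.

All coordinates are 0-based, half-open, in transcript space.  Sequences are
normalised to the RNA alphabet ``ACGU`` on construction (``T`` is accepted as
a synonym for ``U``).  The flanking-position labels used in reports
(``-49..-1`` upstream of the stop codon, ``+1..+18`` downstream) are a pure
presentation convention; see :mod:`scrleak.context` for the mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RNA_ALPHABET = "ACGU"
NUC_INDEX = {c: i for i, c in enumerate(RNA_ALPHABET)}
STOP_CODONS = ("UAA", "UAG", "UGA")

#: sense codons (all 64 minus the three stops), used by the simulator
SENSE_CODONS = tuple(
    a + b + c
    for a in RNA_ALPHABET
    for b in RNA_ALPHABET
    for c in RNA_ALPHABET
    if a + b + c not in STOP_CODONS
)


class ScrLeakError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(ScrLeakError):
    """An input record violates a structural invariant."""


def normalize_sequence(seq: str, *, name: str = "sequence") -> str:
    """Uppercase a nucleotide string and map T to U.

    Raises :class:`ValidationError` on symbols outside ``ACGUT`` (case
    insensitive).
    """
    s = seq.upper().replace("T", "U")
    bad = set(s) - set(RNA_ALPHABET)
    if bad:
        raise ValidationError(f"{name} contains invalid symbols: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence together with its CDS geometry.

    Parameters
    ----------
    id : str
        Transcript identifier.
    sequence : str
        Full transcript sequence (5'UTR + CDS + 3'UTR), RNA alphabet.
    cds_start : int
        0-based offset of the first CDS nucleotide (the A of AUG).
    stop_start : int
        0-based offset of the first nucleotide of the annotated stop codon.
    stop_codon : str
        One of UAA / UAG / UGA; must match the sequence at ``stop_start``.
    """

    id: str
    sequence: str
    cds_start: int
    stop_start: int
    stop_codon: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence, name=f"transcript {self.id}"))
        object.__setattr__(self, "stop_codon", normalize_sequence(self.stop_codon, name="stop_codon"))
        if self.stop_codon not in STOP_CODONS:
            raise ValidationError(f"transcript {self.id}: unknown stop codon {self.stop_codon!r}")
        if not (0 <= self.cds_start <= self.stop_start):
            raise ValidationError(f"transcript {self.id}: cds_start/stop_start out of order")
        if self.stop_start + 3 > len(self.sequence):
            raise ValidationError(f"transcript {self.id}: stop codon extends past the sequence end")
        observed = self.sequence[self.stop_start : self.stop_start + 3]
        if observed != self.stop_codon:
            raise ValidationError(
                f"transcript {self.id}: annotated stop codon {self.stop_codon} "
                f"does not match sequence {observed} at position {self.stop_start}"
            )
        if (self.stop_start - self.cds_start) % 3 != 0:
            raise ValidationError(f"transcript {self.id}: stop codon is out of frame with cds_start")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        """CDS length in nt, stop codon included."""
        return self.stop_start + 3 - self.cds_start

    @property
    def utr3_length(self) -> int:
        return len(self.sequence) - (self.stop_start + 3)


@dataclass(frozen=True)
class FootprintRead:
    """One ribosome-protected fragment in transcript coordinates."""

    transcript_id: str
    start: int
    length: int

    MIN_LENGTH = 25
    MAX_LENGTH = 35

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"read on {self.transcript_id}: negative start {self.start}")
        if not (self.MIN_LENGTH <= self.length <= self.MAX_LENGTH):
            raise ValidationError(
                f"read on {self.transcript_id}: length {self.length} outside "
                f"[{self.MIN_LENGTH}, {self.MAX_LENGTH}]"
            )

    @property
    def end(self) -> int:
        """One past the last covered position (half-open)."""
        return self.start + self.length


@dataclass
class DensityProfile:
    """Per-nucleotide footprint coverage for one transcript.

    ``counts[p]`` is the number of footprints whose interval covers position
    ``p``; the total mass therefore equals the summed footprint lengths.
    """

    transcript_id: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValidationError("profile counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValidationError("profile counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.counts)
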