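"""Stop-codon readthrough (SCR) detection and rate estimation.

The leak rate of a transcript is

    rho = delta_ext / delta_CD

where ``delta_CD`` is the footprint coverage summed over the 30-nt window
flanking the stop codon (the 14 nt immediately before it plus the 16 nt
immediately after it, stop codon excluded) and ``delta_ext`` is the coverage
summed over the 30-nt window spanning offsets +29..+58 downstream of the
stop (offset +1 being the first nucleotide after the stop codon).  The gap
between the two windows keeps footprints of terminating ribosomes (28-29 nt
long) out of the extension window.

Candidate events are filtered on extension coverage, a minimum leak rate,
and the distance to the next in-frame stop codon, then labelled into the
rate sets TS1 / TS2 (moderate / high leak) against the TS0 control pool.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

from .records import DensityProfile, FootprintRead, ScrLeakError, STOP_CODONS, TranscriptRecord

# Window geometry (nt).
CD_UPSTREAM = 14
CD_DOWNSTREAM = 16
EXT_OFFSET_START = 29   # 1-based offset of the first extension-window nt
EXT_OFFSET_END = 58     # 1-based offset of the last extension-window nt


class WindowError(ScrLeakError):
    """A rate-estimation window falls outside the transcript."""


class UndefinedRateError(ScrLeakError):
    """delta_CD is zero, so the leak rate is undefined."""


@dataclass
class DetectionConfig:
    """Thresholds of the candidate-selection and set-labelling steps."""

    min_coverage_fraction: float = 0.90
    min_reads: int = 2
    #: interpret ``min_reads`` per covered position instead of in total
    min_reads_per_position: bool = False
    min_rho: float = 0.005
    min_next_stop_distance: int = 18
    ts1_rho: float = 3e-4
    ts2_rho: float = 20e-4
    cd_upstream: int = CD_UPSTREAM
    cd_downstream: int = CD_DOWNSTREAM
    ext_offset_start: int = EXT_OFFSET_START
    ext_offset_end: int = EXT_OFFSET_END


@dataclass
class ScrEvent:
    """One candidate readthrough event with its filter outcome."""

    transcript_id: str
    stop_codon: str
    delta_cd: float = math.nan
    delta_ext: float = math.nan
    rho: float = math.nan
    next_stop_distance: int | None = None
    extension_coverage_fraction: float = math.nan
    extension_read_count: int = 0
    passes_filters: bool = False
    reasons: tuple[str, ...] = ()
    set_label: str = "candidate-excluded"


def find_next_inframe_stop(transcript: TranscriptRecord) -> int | None:
    """Distance (nt) from the first nucleotide after the annotated stop codon
    to the first nucleotide of the next in-frame stop codon.

    Returns 0 when the codon immediately following the annotated stop is
    itself a stop, and ``None`` when no downstream in-frame stop exists
    within the transcript.
    """
    seq = transcript.sequence
    pos = transcript.stop_start + 3
    while pos + 3 <= len(seq):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos - (transcript.stop_start + 3)
        pos += 3
    return None


def compute_delta_cd(
    profile: DensityProfile,
    stop_start: int,
    upstream: int = CD_UPSTREAM,
    downstream: int = CD_DOWNSTREAM,
) -> int:
    """Coverage summed over the CDS-end window (stop codon excluded)."""
    lo = stop_start - upstream
    hi = stop_start + 3 + downstream
    if lo < 0 or hi > len(profile.counts):
        raise WindowError(
            f"delta_CD window [{lo}, {hi}) outside transcript "
            f"{profile.transcript_id} (length {len(profile.counts)})"
        )
    counts = profile.counts
    return int(counts[lo:stop_start].sum() + counts[stop_start + 3 : hi].sum())


def compute_delta_ext(
    profile: DensityProfile,
    stop_start: int,
    offset_start: int = EXT_OFFSET_START,
    offset_end: int = EXT_OFFSET_END,
) -> int:
    """Coverage summed over the extension window (offsets +29..+58).

    Offsets are 1-based and counted from the first nucleotide after the stop
    codon, so the window covers transcript positions
    ``stop_start + 3 + offset_start - 1 .. stop_start + 3 + offset_end - 1``.
    """
    lo = stop_start + 3 + offset_start - 1
    hi = stop_start + 3 + offset_end
    if lo < 0 or hi > len(profile.counts):
        raise WindowError(
            f"delta_ext window [{lo}, {hi}) outside transcript "
            f"{profile.transcript_id} (length {len(profile.counts)})"
        )
    return int(profile.counts[lo:hi].sum())


def compute_scr_rate(delta_cd: float, delta_ext: float) -> float:
    """Eq. rho = delta_ext / delta_cd; undefined when delta_cd is zero."""
    if delta_cd <= 0:
        raise UndefinedRateError("delta_CD is zero; SCR rate undefined")
    return delta_ext / delta_cd


def extension_region(transcript: TranscriptRecord, next_stop_distance: int) -> tuple[int, int]:
    """Half-open interval from the nucleotide after the annotated stop to the
    nucleotide before the next in-frame stop."""
    lo = transcript.stop_start + 3
    return lo, lo + next_stop_distance


def extension_support(
    profile: DensityProfile,
    reads: Sequence[FootprintRead],
    region: tuple[int, int],
    min_reads_per_position: int = 1,
) -> tuple[float, int]:
    """Coverage fraction of the extension region and the number of distinct
    footprints overlapping it."""
    lo, hi = region
    if hi <= lo:
        return 0.0, 0
    window = profile.counts[lo:hi]
    fraction = float((window >= min_reads_per_position).mean())
    n_reads = sum(1 for r in reads if r.start < hi and r.end > lo)
    return fraction, n_reads


def apply_filters(event: ScrEvent, config: DetectionConfig | None = None) -> tuple[bool, tuple[str, ...]]:
    """Candidate-selection criteria.

    An event passes iff the extension region is covered at >= the configured
    fraction with the configured read support, rho exceeds the minimum rate
    (strictly), a downstream in-frame stop exists, and it lies at least the
    minimum distance away.
    """
    cfg = config or DetectionConfig()
    reasons: list[str] = []
    if event.next_stop_distance is None:
        reasons.append("no downstream in-frame stop")
    elif event.next_stop_distance < cfg.min_next_stop_distance:
        reasons.append("next-stop distance")
    if not (event.rho > cfg.min_rho):  # also fails on NaN
        reasons.append("rate")
    if not (event.extension_coverage_fraction >= cfg.min_coverage_fraction):
        reasons.append("coverage")
    if not cfg.min_reads_per_position and event.extension_read_count < cfg.min_reads:
        reasons.append("read support")
    return (not reasons), tuple(reasons)


def rate_set_membership(rho: float, ts1_rho: float = 3e-4, ts2_rho: float = 20e-4) -> frozenset[str]:
    """Rate-set membership of a leak rate: TS2 is a subset of TS1."""
    members = set()
    if rho > ts1_rho:
        members.add("TS1")
    if rho > ts2_rho:
        members.add("TS2")
    return frozenset(members)


def label_rate_sets(events: Iterable[ScrEvent], config: DetectionConfig | None = None) -> list[ScrEvent]:
    """Assign each event its highest rate-set label.

    Events passing all filters are labelled TS2 or TS1 by their rate.
    Transcripts without any extension signal (delta_ext == 0) form the TS0
    control pool; everything else is a rejected candidate.
    """
    cfg = config or DetectionConfig()
    out = []
    for ev in events:
        members = rate_set_membership(ev.rho, cfg.ts1_rho, cfg.ts2_rho) if ev.passes_filters else frozenset()
        if "TS2" in members:
            label = "TS2"
        elif "TS1" in members:
            label = "TS1"
        elif ev.delta_ext == 0 or (not math.isnan(ev.rho) and ev.rho == 0.0):
            label = "TS0"
        else:
            label = "candidate-excluded"
        out.append(replace(ev, set_label=label))
    return out


def detect_event(
    transcript: TranscriptRecord,
    profile: DensityProfile,
    reads: Sequence[FootprintRead] = (),
    config: DetectionConfig | None = None,
) -> ScrEvent:
    """Estimate the leak rate for one transcript and apply the filters."""
    cfg = config or DetectionConfig()
    event = ScrEvent(transcript_id=transcript.id, stop_codon=transcript.stop_codon)
    event.next_stop_distance = find_next_inframe_stop(transcript)
    try:
        event.delta_cd = compute_delta_cd(profile, transcript.stop_start, cfg.cd_upstream, cfg.cd_downstream)
        event.delta_ext = compute_delta_ext(
            profile, transcript.stop_start, cfg.ext_offset_start, cfg.ext_offset_end
        )
    except WindowError as exc:
        event.passes_filters = False
        event.reasons = (f"window: {exc}",)
        return event
    try:
        event.rho = compute_scr_rate(event.delta_cd, event.delta_ext)
    except UndefinedRateError:
        event.rho = math.nan
    if event.next_stop_distance is not None:
        region = extension_region(transcript, event.next_stop_distance)
        min_per_pos = cfg.min_reads if cfg.min_reads_per_position else 1
        event.extension_coverage_fraction, event.extension_read_count = extension_support(
            profile, reads, region, min_per_pos
        )
    event.passes_filters, event.reasons = apply_filters(event, cfg)
    return event


def detect_events(
    transcripts: Sequence[TranscriptRecord],
    reads_by_transcript: dict[str, Sequence[FootprintRead]],
    profiles: dict[str, DensityProfile],
    config: DetectionConfig | None = None,
) -> list[ScrEvent]:
    """Run detection over a transcript collection and label the rate sets."""
    cfg = config or DetectionConfig()
    events = [
        detect_event(t, profiles[t.id], reads_by_transcript.get(t.id, ()), cfg)
        for t in transcripts
        if t.id in profiles
    ]
    return label_rate_sets(events, cfg)
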