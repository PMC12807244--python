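"""Readers and writers for the pipeline's tabular formats.

Sequences travel as FASTA; everything else is TSV.  All coordinate columns
are 0-based, half-open, in transcript space (column headers say so);
flanking-position labels (-49..+18) appear only in report columns explicitly
flagged as labels.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detection import DetectionConfig, ScrEvent
from .records import DensityProfile, FootprintRead, TranscriptRecord, ValidationError
from .synthetic import GroundTruth, SimulationConfig

ANNOTATION_COLUMNS = ["transcript_id", "cds_start", "stop_codon_start", "stop_codon"]
READ_COLUMNS = ["transcript_id", "start", "length"]
EVENT_COLUMNS = [
    "transcript_id",
    "stop_codon",
    "delta_cd",
    "delta_ext",
    "rho",
    "next_stop_distance",
    "coverage_fraction",
    "read_count",
    "passes_filters",
    "reasons",
    "set_label",
]


def write_transcripts(
    transcripts: list[TranscriptRecord], fasta_path: str | Path, annotation_path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        [(t.id, t.cds_start, t.stop_start, t.stop_codon) for t in transcripts],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(annotation_path, sep="\t", index=False)


def read_transcripts(fasta_path: str | Path, annotation_path: str | Path) -> list[TranscriptRecord]:
    """Load and validate transcripts; raises naming the offending record."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = pd.read_csv(annotation_path, sep="\t")
    missing = set(ann.transcript_id) - set(seqs)
    if missing:
        raise ValidationError(f"annotation references sequences absent from FASTA: {sorted(missing)}")
    out = []
    for row in ann.itertuples(index=False):
        out.append(
            TranscriptRecord(
                id=row.transcript_id,
                sequence=seqs[row.transcript_id],
                cds_start=int(row.cds_start),
                stop_start=int(row.stop_codon_start),
                stop_codon=str(row.stop_codon),
            )
        )
    return out


def write_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False, columns=READ_COLUMNS)


def read_reads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"read table missing columns {sorted(missing)}")
    return df


def reads_to_records(df: pd.DataFrame) -> dict[str, list[FootprintRead]]:
    out: dict[str, list[FootprintRead]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.transcript_id, []).append(
            FootprintRead(transcript_id=row.transcript_id, start=int(row.start), length=int(row.length))
        )
    return out


def events_to_frame(events: list[ScrEvent]) -> pd.DataFrame:
    rows = [
        (
            e.transcript_id,
            e.stop_codon,
            e.delta_cd,
            e.delta_ext,
            e.rho,
            -1 if e.next_stop_distance is None else e.next_stop_distance,
            e.extension_coverage_fraction,
            e.extension_read_count,
            e.passes_filters,
            ";".join(e.reasons),
            e.set_label,
        )
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: list[ScrEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    truth.per_transcript.to_csv(path, sep="\t", index=False)


def write_profile_bedgraph(profile: DensityProfile, path: str | Path, mode: str = "w") -> None:
    """bedGraph-style export (transcript_id, start, end, count; 0-based
    half-open), run-length compressed."""
    counts = profile.counts
    with open(path, mode) as fh:
        if counts.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(counts)) + 1
        edges = np.concatenate(([0], boundaries, [counts.size]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            fh.write(f"{profile.transcript_id}\t{lo}\t{hi}\t{counts[lo]}\n")


def write_model(model, path: str | Path) -> None:
    """Tabular model file: header lines with metadata, then one coefficient
    per row (feature label, value)."""
    with open(path, "w") as fh:
        fh.write(f"# stop_codon: {model.stop_codon}\n")
        fh.write(f"# selected_positions: {','.join(map(str, model.selected_positions))}\n")
        fh.write(f"# training_size: {model.training_size}\n")
        fh.write(f"# svd_truncation: {model.truncation!r}\n")
        fh.write("feature\tcoefficient\n")
        fh.write(f"intercept\t{float(model.w[0])!r}\n")
        for j, lbl in enumerate(model.selected_positions):
            fh.write(f"pos{lbl}_u\t{float(model.w[2 * j + 1])!r}\n")
            fh.write(f"pos{lbl}_v\t{float(model.w[2 * j + 2])!r}\n")


def read_model(path: str | Path):
    from .model import LeakModel

    meta: dict[str, str] = {}
    coeffs: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, _, value = line[2:].partition(": ")
                meta[key] = value
            elif line and not line.startswith("feature"):
                coeffs.append(float(line.split("\t")[1]))
    positions = [int(x) for x in meta["selected_positions"].split(",") if x]
    return LeakModel(
        w=np.asarray(coeffs),
        selected_positions=positions,
        singular_values=np.array([]),
        training_size=int(meta.get("training_size", 0)),
        stop_codon=meta.get("stop_codon", ""),
        truncation=float(meta.get("svd_truncation", 1e-10)),
    )


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds, windows and seeds of the end-to-end pipeline."""

    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    pseudocount: float = 0.5
    svd_truncation: float = 1e-10
    top_k: int | None = None
    n_test_negatives: int = 50
    test_fraction: float = 0.25
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # JSON object keys are strings; keep footprint lengths round-trippable
        d["simulation"]["footprint_lengths"] = {
            str(k): v for k, v in self.simulation.footprint_lengths.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.get("simulation", {}))
        if "footprint_lengths" in sim:
            sim["footprint_lengths"] = {int(k): v for k, v in sim["footprint_lengths"].items()}
        for tup_key in ("cds_length_range", "utr5_length_range", "utr3_length_range", "base_composition"):
            if tup_key in sim and isinstance(sim[tup_key], list):
                sim[tup_key] = tuple(sim[tup_key])
        if "planted_bias" in sim:
            sim["planted_bias"] = [tuple(t) for t in sim["planted_bias"]]
        det = dict(d.get("detection", {}))
        kwargs = {k: v for k, v in d.items() if k not in ("simulation", "detection")}
        return cls(simulation=SimulationConfig(**sim), detection=DetectionConfig(**det), **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
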