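"""Synthetic transcripts, footprint reads, and regression training sets.

The generator emulates the statistical regime the analysis assumes:
transcripts with a 5'UTR / CDS / 3'UTR structure, an annotated stop codon
and an in-frame downstream second stop at a controllable distance;
footprints of 28-29 nt whose 5' starts are Poisson-distributed at a CDS
density level and at rho times that level in the extension; and stop-codon
contexts with planted per-position nucleotide biases tied to a known leak
rate.  The coverage profile is flat within each region (no stop-proximal
taper or pause is modelled), since the rate estimator only uses window sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import SCC_UPSTREAM, label_to_index
from .model import encode_context
from .records import (
    NUC_INDEX,
    RNA_ALPHABET,
    SENSE_CODONS,
    STOP_CODONS,
    ScrLeakError,
    TranscriptRecord,
)

_STOP_TRIPLES = {tuple(NUC_INDEX[c] for c in codon) for codon in STOP_CODONS}

#: minimum 3'UTR room past the second stop so every extension read fits
_UTR3_TAIL = 32


class ConfigError(ScrLeakError):
    """The simulation configuration is infeasible."""


@dataclass
class SimulationConfig:
    """Parameters of the transcript / read simulator.

    ``true_rho`` is the leak rate of readthrough transcripts; a fraction
    ``scr_fraction`` of transcripts leak at that rate, the rest at zero.
    ``planted_bias`` lists (position_label, nucleotide, excess) triples:
    with probability ``excess`` the context position of a leaking transcript
    is forced to the given nucleotide (mixture replacement), which shifts
    its empirical frequency by exactly ``excess * (1 - base_freq)``.
    """

    seed: int = 0
    n_transcripts: int = 100
    cds_length_range: tuple[int, int] = (150, 300)
    utr5_length_range: tuple[int, int] = (20, 50)
    utr3_length_range: tuple[int, int] = (150, 250)
    stop_codon: str = "UGA"  # UGA / UAA / UAG / mixed
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cds_density: float = 5.0
    true_rho: float = 0.05
    scr_fraction: float = 1.0
    second_stop_distance: int | str = 90  # nt, multiple of 3, or "random"
    footprint_lengths: dict[int, float] = field(default_factory=lambda: {28: 0.5, 29: 0.5})
    planted_bias: list[tuple[int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.size != 4 or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ConfigError("base_composition must be 4 nonnegative probabilities summing to 1")
        if self.true_rho < 0:
            raise ConfigError("true_rho must be >= 0")
        if self.cds_density < 0:
            raise ConfigError("cds_density must be >= 0")
        if not 0 <= self.scr_fraction <= 1:
            raise ConfigError("scr_fraction must be in [0, 1]")
        if self.stop_codon not in (*STOP_CODONS, "mixed"):
            raise ConfigError(f"unknown stop codon {self.stop_codon!r}")
        if isinstance(self.second_stop_distance, str):
            if self.second_stop_distance != "random":
                raise ConfigError("second_stop_distance must be an int or 'random'")
        elif self.second_stop_distance % 3 != 0 or self.second_stop_distance < 0:
            raise ConfigError("second_stop_distance must be a nonnegative multiple of 3")
        if abs(sum(self.footprint_lengths.values()) - 1.0) > 1e-9:
            raise ConfigError("footprint_lengths weights must sum to 1")
        for pos, nuc, excess in self.planted_bias:
            label_to_index(pos)  # raises outside the 70-nt window
            if nuc not in RNA_ALPHABET:
                raise ConfigError(f"planted nucleotide {nuc!r} not in {RNA_ALPHABET}")
            if not 0 <= excess <= 1:
                raise ConfigError("planted excess must be in [0, 1]")
        if isinstance(self.second_stop_distance, int):
            if self.second_stop_distance + _UTR3_TAIL > self.utr3_length_range[0]:
                raise ConfigError(
                    "utr3_length_range too short for the requested second-stop "
                    f"distance (need >= {self.second_stop_distance + _UTR3_TAIL} nt)"
                )


@dataclass
class GroundTruth:
    """Per-transcript truth of a simulation, plus planted model coefficients
    when a regression training set was generated."""

    per_transcript: pd.DataFrame
    true_w: np.ndarray | None = None
    causal_positions: list[int] | None = None

    def rho_of(self, transcript_id: str) -> float:
        row = self.per_transcript.loc[self.per_transcript.transcript_id == transcript_id]
        return float(row.true_rho.iloc[0])


def _draw_nucleotides(rng: np.random.Generator, n: int, comp: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=n, p=comp)


def _redraw_frame_stops(rng: np.random.Generator, nts: np.ndarray, comp: np.ndarray) -> np.ndarray:
    """Redraw frame-0 codons of a flat nucleotide array until none is a stop."""
    m = nts.size // 3
    codons = nts[: 3 * m].reshape(m, 3)
    while True:
        is_stop = np.array([tuple(c) in _STOP_TRIPLES for c in codons])
        if not is_stop.any():
            break
        codons[is_stop] = rng.choice(4, size=(int(is_stop.sum()), 3), p=comp)
    return nts


def _indices_to_seq(nts: np.ndarray) -> str:
    return "".join(RNA_ALPHABET[i] for i in nts)


def _plant_and_repair(
    seq: list[str],
    stop_start: int,
    second_stop_start: int,
    cds_start: int,
    planted_bias: list[tuple[int, str, float]],
    rng: np.random.Generator,
) -> set[int]:
    """Apply mixture-replacement biases at context positions, then repair any
    in-frame stop codon the planting created (inside the CDS or before the
    intended second stop) without touching planted positions."""
    planted: set[int] = set()
    for label, nuc, excess in planted_bias:
        offset = label_to_index(label) - SCC_UPSTREAM  # nt relative to stop_start
        pos = stop_start + offset
        if rng.random() < excess:
            seq[pos] = nuc
            planted.add(pos)
    # rescan the two frame-0 regions that must stay stop-free
    regions = [
        range(cds_start + 3, stop_start, 3),
        range(stop_start + 3, second_stop_start, 3),
    ]
    for region in regions:
        for cpos in region:
            if "".join(seq[cpos : cpos + 3]) in STOP_CODONS:
                for off in range(3):
                    if cpos + off not in planted:
                        # C never occurs in a stop codon, so this always repairs
                        seq[cpos + off] = "C"
                        break
                else:
                    raise ConfigError(
                        f"planted bias forces a premature stop codon at position {cpos}"
                    )
    return planted


def generate_transcripts(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Generate transcripts with valid ORFs and known per-transcript truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    comp = np.asarray(config.base_composition, dtype=float)
    transcripts: list[TranscriptRecord] = []
    truth_rows = []
    for i in range(config.n_transcripts):
        utr5_len = int(rng.integers(config.utr5_length_range[0], config.utr5_length_range[1] + 1))
        cds_len = int(rng.integers(config.cds_length_range[0], config.cds_length_range[1] + 1))
        cds_len = max(9, cds_len - cds_len % 3)
        utr3_len = int(rng.integers(config.utr3_length_range[0], config.utr3_length_range[1] + 1))
        if config.second_stop_distance == "random":
            max_d = (utr3_len - _UTR3_TAIL) // 3
            if max_d < 0:
                raise ConfigError("utr3_length_range too short for any second stop")
            d = 3 * int(rng.integers(0, max_d + 1))
        else:
            d = int(config.second_stop_distance)
        stop_codon = (
            str(rng.choice(STOP_CODONS)) if config.stop_codon == "mixed" else config.stop_codon
        )
        second_stop = str(rng.choice(STOP_CODONS))

        utr5 = _draw_nucleotides(rng, utr5_len, comp)
        body = _redraw_frame_stops(rng, _draw_nucleotides(rng, cds_len - 6, comp), comp)
        ext = _redraw_frame_stops(rng, _draw_nucleotides(rng, d, comp), comp)
        tail = _draw_nucleotides(rng, utr3_len - d - 3, comp)

        cds_start = utr5_len
        stop_start = utr5_len + cds_len - 3
        second_stop_start = stop_start + 3 + d
        seq = list(
            _indices_to_seq(utr5)
            + "AUG"
            + _indices_to_seq(body)
            + stop_codon
            + _indices_to_seq(ext)
            + second_stop
            + _indices_to_seq(tail)
        )
        rho = config.true_rho if rng.random() < config.scr_fraction else 0.0
        if rho > 0 and config.planted_bias:
            _plant_and_repair(seq, stop_start, second_stop_start, cds_start, config.planted_bias, rng)
        tid = f"tx{i:05d}"
        transcripts.append(
            TranscriptRecord(
                id=tid,
                sequence="".join(seq),
                cds_start=cds_start,
                stop_start=stop_start,
                stop_codon=stop_codon,
            )
        )
        truth_rows.append((tid, rho, d))
    truth = GroundTruth(
        per_transcript=pd.DataFrame(truth_rows, columns=["transcript_id", "true_rho", "second_stop_distance"])
    )
    return transcripts, truth


def sample_read_arrays(
    transcript: TranscriptRecord,
    rho: float,
    second_stop_distance: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Footprint (starts, lengths) arrays for one transcript.

    5'-start counts are Poisson per nucleotide: at ``cds_density`` over the
    CDS (stop codon included), at ``rho * cds_density`` over the extension
    (between annotated and second stop), and zero elsewhere.
    """
    n = len(transcript.sequence)
    rates = np.zeros(n)
    rates[transcript.cds_start : transcript.stop_start + 3] = config.cds_density
    ext_lo = transcript.stop_start + 3
    rates[ext_lo : ext_lo + second_stop_distance] = rho * config.cds_density
    counts = rng.poisson(rates)
    starts = np.repeat(np.arange(n), counts)
    lens = np.array(sorted(config.footprint_lengths))
    weights = np.array([config.footprint_lengths[l] for l in lens], dtype=float)
    lengths = rng.choice(lens, size=starts.size, p=weights)
    keep = starts + lengths <= n
    return starts[keep], lengths[keep]


def generate_reads(
    transcripts: list[TranscriptRecord],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Footprint read table (transcript_id, start, length) for a cohort."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    info = truth.per_transcript.set_index("transcript_id")
    frames = []
    for t in transcripts:
        row = info.loc[t.id]
        starts, lengths = sample_read_arrays(
            t, float(row.true_rho), int(row.second_stop_distance), config, rng
        )
        frames.append(pd.DataFrame({"transcript_id": t.id, "start": starts, "length": lengths}))
    if not frames:
        return pd.DataFrame(columns=["transcript_id", "start", "length"])
    return pd.concat(frames, ignore_index=True)


def _random_contexts(
    rng: np.random.Generator,
    n: int,
    stop_codon: str,
    comp: np.ndarray,
) -> list[str]:
    out = []
    for _ in range(n):
        nts = rng.choice(4, size=70, p=comp)
        ctx = list(_indices_to_seq(nts))
        ctx[SCC_UPSTREAM : SCC_UPSTREAM + 3] = list(stop_codon)
        out.append("".join(ctx))
    return out


def generate_regression_set(
    n: int,
    positions: list[int],
    true_w: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
    stop_codon: str = "UGA",
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[list[str], np.ndarray, GroundTruth]:
    """Training pairs (context, rate) from a known linear model.

    Rates follow y = w . v(context) + Gaussian noise, with v the bipolar
    encoding of the selected positions (intercept first).
    """
    true_w = np.asarray(true_w, dtype=float)
    if true_w.size != 2 * len(positions) + 1:
        raise ConfigError(
            f"true_w has {true_w.size} entries; expected {2 * len(positions) + 1} "
            f"for {len(positions)} positions"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = np.asarray(base_composition, dtype=float)
    contexts = _random_contexts(rng, n, stop_codon, comp)
    V = np.array([encode_context(c, positions) for c in contexts])
    y = V @ true_w + rng.normal(0.0, noise_sd, size=n)
    truth = GroundTruth(
        per_transcript=pd.DataFrame({"transcript_id": [f"ctx{i:05d}" for i in range(n)], "true_rho": y,
                                     "second_stop_distance": -1}),
        true_w=true_w,
        causal_positions=list(positions),
    )
    return contexts, y, truth


def generate_scr_benchmark(
    seed: int,
    stop_codon: str = "UGA",
    n_train: int = 400,
    n_test_pos: int = 200,
    n_test_neg: int = 50,
    n_control: int = 400,
    causal_positions: tuple[int, ...] = (-47, -12, -2, -1, 1, 9),
    effect: float = 0.05,
    baseline: float = -0.05,
    noise_sd: float = 0.005,
) -> dict:
    """A readthrough-prediction benchmark with known causal positions.

    Contexts are unbiased uniform draws scored by a known linear model,
    y = a0 + sum b_i x_i + noise, with a0 = ``baseline`` and a per-position
    contribution of ``effect`` for the nucleotide A (the (1, 1) code).
    A context is a readthrough ("positive") when its score is positive, a
    control otherwise, so the positive class is enriched for A at the causal
    positions purely by selection -- the way readthrough transcript sets are
    enriched in real cohorts.  Half the causal positions sit outside the 6+6
    flanking window, so models restricted to it miss real signal.

    Returns a dict with train / test sets, a control-context set for
    divergence estimation, and the ground truth.
    """
    rng = np.random.default_rng(seed)
    comp = np.full(4, 0.25)
    positions = sorted(causal_positions, key=label_to_index)
    true_w = np.empty(2 * len(positions) + 1)
    true_w[0] = baseline
    true_w[1:] = effect / 2.0

    def draw(n_needed: int, positive: bool) -> list[tuple[str, float]]:
        out: list[tuple[str, float]] = []
        while len(out) < n_needed:
            for ctx in _random_contexts(rng, 64, stop_codon, comp):
                rate = float(encode_context(ctx, positions) @ true_w + rng.normal(0.0, noise_sd))
                if (rate > 0) == positive:
                    out.append((ctx, rate))
                    if len(out) == n_needed:
                        break
        return out

    train = draw(n_train, True)
    test_pos = [c for c, _ in draw(n_test_pos, True)]
    test_neg = [c for c, _ in draw(n_test_neg, False)]
    control = [c for c, _ in draw(n_control, False)]
    truth = GroundTruth(
        per_transcript=pd.DataFrame(
            {"transcript_id": [f"pos{i:05d}" for i in range(n_train)],
             "true_rho": [r for _, r in train],
             "second_stop_distance": -1}
        ),
        true_w=true_w,
        causal_positions=positions,
    )
    return {
        "stop_codon": stop_codon,
        "train_contexts": [c for c, _ in train],
        "train_rates": np.array([r for _, r in train]),
        "test_positives": test_pos,
        "test_negatives": test_neg,
        "control_contexts": control,
        "truth": truth,
    }
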