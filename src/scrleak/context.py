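"""Stop-codon-context statistics.

The stop codon context (SCC) is the 70-nt window made of the 49 nt upstream
of the stop codon, the 3 stop-codon nucleotides, and the 18 nt downstream.
Internally contexts are indexed 0..69 with the stop codon at slots 49..51;
reports use flanking labels -49..-1 (upstream) and +1..+18 (downstream).

Statistics provided:

* per-position nucleotide frequencies and the positional Kullback-Leibler
  divergence D(r) of a transcript set against a control set,
* the pairwise divergence D(r, s) between two context positions, which is
  the mutual information of the two alignment columns,
* a per-position Fisher exact test of GC versus AU usage,
* GC3 (wobble G/C fraction) profiles along the CDS, and
* leak-rate histograms stratified by the nucleotide adjacent to the stop.

All divergences are in nats.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .records import NUC_INDEX, RNA_ALPHABET, ScrLeakError, TranscriptRecord, normalize_sequence

SCC_UPSTREAM = 49
SCC_DOWNSTREAM = 18
SCC_LENGTH = SCC_UPSTREAM + 3 + SCC_DOWNSTREAM  # 70
STOP_SLOTS = (SCC_UPSTREAM, SCC_UPSTREAM + 1, SCC_UPSTREAM + 2)

#: default Jeffreys pseudocount per nucleotide per position
DEFAULT_PSEUDOCOUNT = 0.5


def label_to_index(label: int) -> int:
    """Map a flanking-position label (-49..-1, +1..+18) to 0..69."""
    if -SCC_UPSTREAM <= label <= -1:
        return SCC_UPSTREAM + label
    if 1 <= label <= SCC_DOWNSTREAM:
        return SCC_UPSTREAM + 2 + label
    raise ValueError(f"position label {label} outside the context window")


def index_to_label(index: int) -> int:
    """Inverse of :func:`label_to_index`; stop-codon slots have no label."""
    if 0 <= index < SCC_UPSTREAM:
        return index - SCC_UPSTREAM
    if SCC_UPSTREAM + 3 <= index < SCC_LENGTH:
        return index - (SCC_UPSTREAM + 2)
    raise ValueError(f"index {index} is a stop-codon slot or outside the window")


def non_stop_labels() -> list[int]:
    """The 67 informative position labels, 5' to 3'."""
    return list(range(-SCC_UPSTREAM, 0)) + list(range(1, SCC_DOWNSTREAM + 1))


def extract_scc(transcript: TranscriptRecord) -> str | None:
    """The 70-nt context of a transcript, or None when a flank is missing."""
    lo = transcript.stop_start - SCC_UPSTREAM
    hi = transcript.stop_start + 3 + SCC_DOWNSTREAM
    if lo < 0 or hi > len(transcript.sequence):
        return None
    return transcript.sequence[lo:hi]


def _as_index_matrix(contexts: Sequence[str]) -> np.ndarray:
    if not contexts:
        raise ScrLeakError("empty context set")
    width = len(contexts[0])
    mat = np.empty((len(contexts), width), dtype=np.int8)
    for i, ctx in enumerate(contexts):
        ctx = normalize_sequence(ctx, name="context")
        if len(ctx) != width:
            raise ScrLeakError(f"context {i} has length {len(ctx)}, expected {width}")
        mat[i] = [NUC_INDEX[c] for c in ctx]
    return mat


def nucleotide_counts(contexts: Sequence[str]) -> np.ndarray:
    """4 x W per-position occurrence counts (rows ordered A, C, G, U)."""
    mat = _as_index_matrix(contexts)
    counts = np.zeros((4, mat.shape[1]), dtype=np.int64)
    for n in range(4):
        counts[n] = (mat == n).sum(axis=0)
    return counts


def position_frequencies(contexts: Sequence[str], pseudocount: float = 0.0) -> np.ndarray:
    """Column-stochastic 4 x W frequency table p_i(r)."""
    counts = nucleotide_counts(contexts).astype(float) + pseudocount
    return counts / counts.sum(axis=0, keepdims=True)


def kl_divergence_profile(p_set: np.ndarray, p_ref: np.ndarray) -> np.ndarray:
    """Positional divergence D(r) = sum_i p_i(r) log(p_i(r) / p*_i(r)).

    Terms with p_i(r) = 0 contribute 0.  A position where the set uses a
    nucleotide the reference never does yields +inf; apply a pseudocount
    when building the tables to avoid this.
    """
    p_set = np.asarray(p_set, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    if p_set.shape != p_ref.shape:
        raise ScrLeakError("frequency tables have mismatched shapes")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p_set > 0, p_set * np.log(p_set / p_ref), 0.0)
    return terms.sum(axis=0)


def divergence_from_counts(
    counts_set: np.ndarray,
    counts_ref: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """D(r) from raw count tables, with pseudocount regularisation."""
    cs = np.asarray(counts_set, dtype=float) + pseudocount
    cr = np.asarray(counts_ref, dtype=float) + pseudocount
    return kl_divergence_profile(cs / cs.sum(axis=0), cr / cr.sum(axis=0))


class ContextMatrix:
    """Aligned stop-codon contexts for one transcript set."""

    def __init__(self, contexts: Sequence[str], set_label: str = "", stop_codon: str = ""):
        self.contexts = [normalize_sequence(c, name="context") for c in contexts]
        self.set_label = set_label
        self.stop_codon = normalize_sequence(stop_codon) if stop_codon else ""
        for i, ctx in enumerate(self.contexts):
            if len(ctx) != SCC_LENGTH:
                raise ScrLeakError(f"context {i} has length {len(ctx)}, expected {SCC_LENGTH}")
            if self.stop_codon and ctx[SCC_UPSTREAM : SCC_UPSTREAM + 3] != self.stop_codon:
                raise ScrLeakError(
                    f"context {i} carries {ctx[SCC_UPSTREAM:SCC_UPSTREAM + 3]} at the stop slot, "
                    f"expected {self.stop_codon}"
                )
        self.counts = nucleotide_counts(self.contexts) if self.contexts else np.zeros((4, SCC_LENGTH), int)

    def __len__(self) -> int:
        return len(self.contexts)

    def frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        c = self.counts.astype(float) + pseudocount
        return c / c.sum(axis=0, keepdims=True)


def pairwise_divergence(contexts: Sequence[str], labels: Sequence[int] | None = None) -> pd.DataFrame:
    """Pairwise divergence D(r, s) for every unordered pair of non-stop
    positions (2211 pairs for the full 67-position window).

    D(r, s) = sum_{i,j} p_ij(r,s) log(p_ij(r,s) / (p_i(r) p_j(s))) is the
    mutual information of the two columns; joint zeros contribute nothing,
    so no pseudocount is needed.
    """
    mat = _as_index_matrix(contexts)
    if mat.shape[0] < 2:
        raise ScrLeakError("pairwise divergence needs at least 2 contexts")
    if labels is None:
        labels = non_stop_labels()
    idx = [label_to_index(lbl) for lbl in labels]
    n = mat.shape[0]
    rows = []
    for a in range(len(idx)):
        col_a = mat[:, idx[a]]
        for b in range(a + 1, len(idx)):
            joint = np.bincount(col_a * 4 + mat[:, idx[b]], minlength=16).reshape(4, 4) / n
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(joint > 0, joint * np.log(joint / np.outer(pi, pj)), 0.0)
            rows.append((labels[a], labels[b], float(terms.sum())))
    return pd.DataFrame(rows, columns=["r", "s", "divergence"])


def mutual_information(joint: np.ndarray) -> float:
    """Mutual information (nats) of a joint probability table."""
    joint = np.asarray(joint, dtype=float)
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(joint > 0, joint * np.log(joint / np.outer(pi, pj)), 0.0)
    return float(terms.sum())


def fisher_gc_au(counts_set: np.ndarray, counts_ref: np.ndarray) -> np.ndarray:
    """Two-sided Fisher exact p-value per position for GC vs AU usage.

    The 2x2 table at each position is [[GC_set, AU_set], [GC_ref, AU_ref]].
    Positions with an all-zero margin return p = 1 by convention.
    """
    counts_set = np.asarray(counts_set)
    counts_ref = np.asarray(counts_ref)
    gc = [NUC_INDEX["G"], NUC_INDEX["C"]]
    au = [NUC_INDEX["A"], NUC_INDEX["U"]]
    width = counts_set.shape[1]
    pvals = np.ones(width)
    for r in range(width):
        table = np.array(
            [
                [counts_set[gc, r].sum(), counts_set[au, r].sum()],
                [counts_ref[gc, r].sum(), counts_ref[au, r].sum()],
            ]
        )
        if table.sum(axis=0).min() == 0 and table.sum() > 0:
            # one column empty in both groups: no association testable
            pvals[r] = 1.0
        elif table.sum() == 0:
            pvals[r] = 1.0
        else:
            pvals[r] = fisher_exact(table, alternative="two-sided")[1]
    return pvals


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values (optional multiple-testing correction)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def gc3_profile(
    transcripts: Iterable[TranscriptRecord],
    align: str = "start",
    n_codons: int | None = None,
) -> pd.DataFrame:
    """Fraction of transcripts with G or C at the third codon position,
    per codon index.  The stop codon is excluded.

    ``align='start'`` indexes codons 0, 1, ... from the CDS start;
    ``align='end'`` indexes them -1, -2, ... from the last sense codon.
    """
    if align not in ("start", "end"):
        raise ScrLeakError(f"unknown alignment {align!r}")
    gc_hits: dict[int, int] = {}
    totals: dict[int, int] = {}
    for t in transcripts:
        cds = t.sequence[t.cds_start : t.stop_start]  # sense codons only
        n = len(cds) // 3
        for k in range(n):
            idx = k if align == "start" else k - n
            if n_codons is not None:
                if align == "start" and idx >= n_codons:
                    break
                if align == "end" and idx < -n_codons:
                    continue
            third = cds[3 * k + 2]
            totals[idx] = totals.get(idx, 0) + 1
            if third in "GC":
                gc_hits[idx] = gc_hits.get(idx, 0) + 1
    rows = [
        (idx, totals[idx], gc_hits.get(idx, 0) / totals[idx])
        for idx in sorted(totals)
    ]
    return pd.DataFrame(rows, columns=["codon_index", "n_transcripts", "gc3_fraction"])


def stratify_by_adjacent(
    rhos: Sequence[float],
    contexts: Sequence[str],
    bins: np.ndarray | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Leak-rate histograms conditioned on the nucleotide at the -1 and +1
    positions flanking the stop codon.

    Returns one row per (side, nucleotide, bin) with the event count in that
    bin; per side, the counts sum to the number of events.
    """
    if len(rhos) != len(contexts):
        raise ScrLeakError("rhos and contexts must have equal length")
    rhos = np.asarray(rhos, dtype=float)
    if bins is None:
        upper = max(float(rhos.max()) if rhos.size else 0.1, 1e-3)
        bins = np.linspace(0.0, upper, 21)
    bins = np.asarray(bins, dtype=float)
    sides = {"-1": label_to_index(-1), "+1": label_to_index(1)}
    rows = []
    for side, idx in sides.items():
        flank = np.array([normalize_sequence(c)[idx] for c in contexts]) if contexts else np.array([])
        for nuc in RNA_ALPHABET:
            vals = rhos[flank == nuc] if flank.size else np.array([])
            hist, _ = np.histogram(vals, bins=bins)
            for b, cnt in enumerate(hist):
                rows.append((side, nuc, bins[b], bins[b + 1], int(cnt)))
    return pd.DataFrame(rows, columns=["side", "nucleotide", "bin_left", "bin_right", "count"])


def divergence_table(
    contexts_by_set: dict[str, Sequence[str]],
    reference_set: str = "TS0",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-position report: frequencies per set, D(r) per non-reference set,
    and the Fisher GC/AU p-value of the highest-rate set vs the reference.

    The reference distribution p*_i is position-specific, computed from the
    control set at the same position r.
    """
    if reference_set not in contexts_by_set:
        raise ScrLeakError(f"reference set {reference_set!r} missing")
    counts = {name: nucleotide_counts(list(ctxs)) for name, ctxs in contexts_by_set.items()}
    ref_counts = counts[reference_set]
    width = ref_counts.shape[1]
    data: dict[str, list] = {"position_label": [], "slot": []}
    for i in range(width):
        data["slot"].append(i)
        try:
            data["position_label"].append(str(index_to_label(i)) if index_to_label(i) < 0 else f"+{index_to_label(i)}")
        except ValueError:
            data["position_label"].append(f"stop{i - SCC_UPSTREAM + 1}")
    frame = pd.DataFrame(data)
    for name, cnt in counts.items():
        freqs = (cnt + pseudocount) / (cnt + pseudocount).sum(axis=0, keepdims=True)
        for n, nuc in enumerate(RNA_ALPHABET):
            frame[f"p_{nuc}_{name}"] = freqs[n]
        if name != reference_set:
            frame[f"D_{name}"] = divergence_from_counts(cnt, ref_counts, pseudocount)
            frame[f"fisher_p_{name}"] = fisher_gc_au(cnt, ref_counts)
    return frame
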