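"""End-to-end orchestration: simulate -> detect -> divergence -> fit -> evaluate.

Each stage writes its table under the output directory and the run manifest
records the configuration, seed, and per-stage record counts, so reruns with
identical config and inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .context import divergence_table, extract_scc, gc3_profile, stratify_by_adjacent
from .detection import detect_events
from .io import (
    PipelineConfig,
    events_to_frame,
    reads_to_records,
    write_events,
    write_model,
    write_reads,
    write_transcripts,
    write_truth,
)
from .model import evaluate, fit_leak_model, model_variants
from .profiles import build_density_profile_from_starts
from .records import STOP_CODONS
from .synthetic import generate_reads, generate_transcripts

logger = logging.getLogger("scrleak")


def build_profiles(transcripts, reads_df: pd.DataFrame) -> dict:
    """Density profiles for every transcript in the cohort."""
    profiles = {}
    grouped = dict(tuple(reads_df.groupby("transcript_id"))) if len(reads_df) else {}
    for t in transcripts:
        sub = grouped.get(t.id)
        if sub is None:
            starts = np.array([], dtype=int)
            lengths = np.array([], dtype=int)
        else:
            starts = sub["start"].to_numpy()
            lengths = sub["length"].to_numpy()
        profiles[t.id] = build_density_profile_from_starts(starts, lengths, len(t.sequence), t.id)
    return profiles


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full pipeline on simulated data; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}

    # --- simulate -------------------------------------------------------
    transcripts, truth = generate_transcripts(config.simulation, rng)
    reads = generate_reads(transcripts, truth, config.simulation, rng)
    write_transcripts(transcripts, outdir / "transcripts.fasta", outdir / "annotation.tsv")
    write_reads(reads, outdir / "reads.tsv")
    write_truth(truth, outdir / "truth.tsv")
    manifest["stages"]["simulate"] = {"transcripts": len(transcripts), "reads": int(len(reads))}
    if len(reads) == 0:
        logger.warning("empty read table: downstream stages will see zero events")

    # --- detect ---------------------------------------------------------
    profiles = build_profiles(transcripts, reads)
    reads_by_tx = reads_to_records(reads)
    events = detect_events(transcripts, reads_by_tx, profiles, config.detection)
    write_events(events, outdir / "events.tsv")
    events_df = events_to_frame(events)
    n_pass = int(events_df.passes_filters.sum())
    manifest["stages"]["detect"] = {
        "candidates": len(events),
        "passing": n_pass,
        "labels": {k: int(v) for k, v in events_df.set_label.value_counts().sort_index().items()},
    }

    # --- divergence / context statistics -------------------------------
    contexts = {t.id: extract_scc(t) for t in transcripts}
    by_tx = {t.id: t for t in transcripts}
    div_frames = []
    strat_frames = []
    for codon in STOP_CODONS:
        sub = events_df[events_df.stop_codon == codon]
        sets = {}
        for label, min_label in (("TS0", None), ("TS1", ("TS1", "TS2")), ("TS2", ("TS2",))):
            if min_label is None:
                ids = sub.loc[sub.set_label == "TS0", "transcript_id"]
            else:
                ids = sub.loc[sub.set_label.isin(min_label), "transcript_id"]
            ctxs = [contexts[i] for i in ids if contexts[i] is not None]
            if ctxs:
                sets[label] = ctxs
        if "TS0" in sets and len(sets) > 1:
            table = divergence_table(sets, reference_set="TS0", pseudocount=config.pseudocount)
            table.insert(0, "stop_codon", codon)
            div_frames.append(table)
        passing = sub[sub.passes_filters]
        ctx_rho = [
            (contexts[r.transcript_id], r.rho)
            for r in passing.itertuples(index=False)
            if contexts[r.transcript_id] is not None
        ]
        if ctx_rho:
            strat = stratify_by_adjacent([r for _, r in ctx_rho], [c for c, _ in ctx_rho])
            strat.insert(0, "stop_codon", codon)
            strat_frames.append(strat)
    if div_frames:
        pd.concat(div_frames, ignore_index=True).to_csv(outdir / "divergence.tsv", sep="\t", index=False)
    if strat_frames:
        pd.concat(strat_frames, ignore_index=True).to_csv(outdir / "adjacent_rates.tsv", sep="\t", index=False)
    gc3 = gc3_profile(transcripts, align="end", n_codons=40)
    gc3.to_csv(outdir / "gc3.tsv", sep="\t", index=False)
    manifest["stages"]["divergence"] = {"codons_analysed": len(div_frames)}

    # --- fit & evaluate, per stop codon --------------------------------
    eval_rows = []
    for codon in STOP_CODONS:
        sub = events_df[(events_df.stop_codon == codon) & events_df.passes_filters]
        pos_items = [
            (r.transcript_id, contexts[r.transcript_id], r.rho)
            for r in sub.itertuples(index=False)
            if contexts[r.transcript_id] is not None
        ]
        neg_ids = events_df.loc[
            (events_df.stop_codon == codon) & (events_df.set_label == "TS0"), "transcript_id"
        ]
        negatives = [contexts[i] for i in neg_ids if contexts[i] is not None]
        n_test = max(1, int(round(config.test_fraction * len(pos_items))))
        if len(pos_items) - n_test < 3 or len(negatives) < 2:
            logger.warning("stop codon %s: too few events to fit a model", codon)
            continue
        order = rng.permutation(len(pos_items))
        test_idx = set(order[:n_test].tolist())
        train = [pos_items[i] for i in range(len(pos_items)) if i not in test_idx]
        test_pos = [pos_items[i][1] for i in sorted(test_idx)]
        test_neg = negatives[: config.n_test_negatives]
        train_ctx = [c for _, c, _ in train]
        train_rho = np.array([r for _, _, r in train])
        div = divergence_table(
            {"TS0": negatives, "SCR": train_ctx}, reference_set="TS0", pseudocount=config.pseudocount
        )["D_SCR"].to_numpy()
        variants = model_variants(codon, divergence=div, k=config.top_k)
        for name, positions in variants.items():
            model = fit_leak_model(train_ctx, train_rho, positions, codon, config.svd_truncation)
            result = evaluate(model, test_pos, test_neg)
            if name == "topk":
                write_model(model, outdir / f"model_{codon}.tsv")
            eval_rows.append(
                (codon, name, len(positions), len(train), len(test_pos), len(test_neg),
                 result.fp_fraction, result.fn_fraction)
            )
    if eval_rows:
        pd.DataFrame(
            eval_rows,
            columns=["stop_codon", "variant", "n_positions", "n_train", "n_test_pos",
                     "n_test_neg", "fp_fraction", "fn_fraction"],
        ).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
    manifest["stages"]["model"] = {"evaluations": len(eval_rows)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
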