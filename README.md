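# scrleak

Detection and modelling of **stop-codon readthrough (SCR)** from
ribosome-profiling (Ribo-seq) footprint data, in transcript coordinates.

When a ribosome fails to terminate at the annotated stop codon, it continues
translating the 3′UTR until the next in-frame stop, producing a C-terminally
extended protein. In Ribo-seq data this leaves a footprint-density signature
between the annotated stop codon and the next in-frame stop. `scrleak` is a
library and CLI for researchers who want to quantify that leak from
transcript-space footprint tables, characterise the sequence context that
drives it, and predict it from sequence alone.

## What it computes

**Leak rate.** For each transcript the per-nucleotide footprint-coverage
profile is summed over two 30-nt windows and the SCR rate is their ratio:

    rho = delta_ext / delta_CD

where `delta_CD` covers the 14 nt before plus the 16 nt after the stop codon
(stop excluded) and `delta_ext` covers downstream offsets +29..+58, far
enough that no footprint of a terminating ribosome (28–29 nt, P-site at
footprint position 13) can reach it. Candidate events must have ≥ 90 % of
the extension covered with ≥ 2 reads, `rho > 0.005`, and a next in-frame
stop at least 18 nt away. Events are labelled TS1 (`rho > 3×10⁻⁴`) and
TS2 (`rho > 2×10⁻³`) against the TS0 control pool (no extension signal).

**Context statistics.** Around each stop codon a 70-nt stop-codon context
(49 nt upstream, stop, 18 nt downstream) is extracted. Per position *r* the
Kullback–Leibler divergence

    D(r) = Σ_i p_i(r) log( p_i(r) / p*_i(r) )

measures how a readthrough set's nucleotide usage departs from the control
set's usage at the same position (nats). The pairwise analogue `D(r, s)` is
the mutual information between two context positions (2211 eligible pairs);
a per-position Fisher exact test compares GC vs AU usage, and GC3 profiles
track wobble-position G/C content along the CDS.

**Leak-rate model.** Each selected context position is encoded as a bipolar
pair (A→(1,1), C→(−1,1), U→(1,−1), G→(−1,−1)) and the linear model
`y = a0 + Σ b_i x_i` is fitted per stop codon by minimum-L2-norm least
squares via the SVD of the design matrix. Position sets: the 6+6 flanking
positions, the 29 positions contiguous to the stop, or the top-k positions
ranked by D(r). Performance is reported as false-positive / false-negative
fractions (a sequence is called readthrough when the predicted rate is
strictly positive).

A synthetic-data module generates transcripts with a controllable second
in-frame stop, Poisson-distributed footprints at a CDS density level and at
`rho` times that level in the extension, planted context biases, and
regression benchmarks with known coefficients — so every stage can be tested
against ground truth.

## Worked example

```python
from scrleak.synthetic import SimulationConfig, generate_transcripts, generate_reads
from scrleak.pipeline import build_profiles
from scrleak.detection import detect_events
from scrleak.io import reads_to_records

cfg = SimulationConfig(seed=11, n_transcripts=6, true_rho=0.05, cds_density=10.0)
transcripts, truth = generate_transcripts(cfg)
reads = generate_reads(transcripts, truth, cfg)
profiles = build_profiles(transcripts, reads)
events = detect_events(transcripts, reads_to_records(reads), profiles)
for e in events:
    print(e.transcript_id, e.delta_cd, e.delta_ext, round(e.rho, 4), e.set_label)
```

Output:

```
tx00000 7153 417 0.0583 TS2
tx00001 7207 361 0.0501 TS2
tx00002 7407 249 0.0336 TS2
tx00003 7190 406 0.0565 TS2
tx00004 7007 345 0.0492 TS2
tx00005 7118 497 0.0698 TS2
```

Six transcripts simulated with a true leak rate of 0.05 all yield rate
estimates near 0.05 (the window-sum estimator over-reads by roughly 17–19 %
under a flat-coverage simulation; see `docs/methods.md`), pass the filters,
and land in the high-rate set TS2.

The same pipeline is available from the shell:

```bash
scrleak simulate --seed 11 --n-transcripts 100 --out out/
scrleak detect --fasta out/transcripts.fasta --annotation out/annotation.tsv \
               --reads out/reads.tsv --out out/events.tsv
scrleak run --out out/full   # simulate → detect → divergence → fit → evaluate
```

## Layout

- `src/scrleak/synthetic.py` — transcript / read / benchmark generators
- `src/scrleak/profiles.py` — footprint coverage profiles, P-site geometry
- `src/scrleak/detection.py` — leak-rate windows, filters, rate sets
- `src/scrleak/context.py` — contexts, D(r), D(r,s), Fisher GC/AU, GC3
- `src/scrleak/model.py` — encoding, position selection, SVD fit, evaluation
- `src/scrleak/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
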