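# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `scrleak`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinates and alphabets

All internal coordinates are 0-based, half-open, in transcript space;
sequences are normalised to RNA (`T` → `U`) on input. Reports use the
flanking-position convention −49..−1 / +1..+18 around the stop codon; the
three stop slots carry no flanking label (internal indices 49–51 of the
70-nt context). Downstream window offsets are 1-based from the first
nucleotide after the stop codon, so the extension window +29..+58 spans
transcript positions `stop_start+31 .. stop_start+60`.

## Leak-rate estimation

The density profile is full-footprint coverage (each footprint increments
every position it spans), not P-site-collapsed counts. The estimator
`rho = delta_ext / delta_CD` uses two 30-nt window sums:

| window | span | role |
|---|---|---|
| `delta_CD` | 14 nt before stop + 16 nt after (stop excluded) | terminal CDS density |
| `delta_ext` | offsets +29..+58 after the stop | extension density |

The gap (+17..+28) guarantees that a 28–29-nt footprint whose 5′ end lies
in the CDS (up to the last stop-codon base) cannot reach the extension
window, which is what keeps the numerator free of termination footprints.

Filters (all configurable in `DetectionConfig`): extension coverage ≥ 0.90,
≥ 2 distinct footprints overlapping the extension in total (a per-position
variant is available), `rho > 0.005` strictly, next in-frame stop ≥ 18 nt
away and required to exist. Rate-set thresholds are TS1: `rho > 3×10⁻⁴`,
TS2: `rho > 2×10⁻³`. Note the TS1 threshold lies below the candidate
threshold 0.005, so with default settings every passing event is also TS2;
both thresholds are kept as independent knobs rather than reconciled,
since each is meaningful on its own (the candidate filter guards detection
reliability, the TS thresholds stratify rate magnitude).

### Estimator bias under the flat-flux simulation

The simulator draws footprint 5′ starts as independent Poisson counts per
position: at rate `cds_density` from the CDS start through the last
stop-codon base, at `true_rho × cds_density` between the stops, and zero
elsewhere. Coverage is then flat in each region's interior but tapers where
the start-rate changes: positions +1..+16 after the stop receive coverage
only from the shrinking set of CDS starts still overlapping them. Summing
expected coverage over the windows (footprint length 28/29, equal weights)
gives

    E[delta_CD] ≈ (719 + 136·rho) · cds_density,
    E[delta_ext] ≈ 855 · rho · cds_density,

so the estimator over-reads by a factor ≈ 855/719 ≈ 1.19 at small rho
(1.17 at rho = 0.1). This is a property of the window geometry itself, not
of the code; the recovery checks therefore assert agreement within 20 %,
and the cohort sizes used there (3000 / 600 / 400 transcripts at CDS
densities 100 / 50 / 50) were chosen from this closed form so that
Monte-Carlo noise in the mean (≲ 0.4 %) is small against the margin.
In real Ribo-seq data the taper is reshaped by termination pausing, which
the simulator deliberately does not model — the flat-flux regime isolates
the window arithmetic from pause-modelling choices.

## Synthetic data

`SimulationConfig` defaults: 100 transcripts, CDS 150–300 nt, 5′UTR
20–50 nt, 3′UTR 150–250 nt, stop codon UGA (or `"mixed"`), uniform base
composition, CDS density 5 starts/nt, `true_rho` 0.05 with all transcripts
leaking (`scr_fraction = 1`), second stop 90 nt downstream (≥ 60 nt keeps
the extension window inside the extension), footprint lengths 28/29 at
equal weight. CDS and inter-stop regions are drawn codon-wise with in-frame
stop codons redrawn, so a valid ORF holds by construction.

Planted context biases use mixture replacement: with probability `excess`
the position is forced to the given nucleotide, moving its frequency from
p₀ to `excess + (1 − excess)·p₀` — an analytically known shift (for a
+0.25 excess on a 0.25 background the frequency lands at 0.4375). If a
planting creates an in-frame stop, one non-planted base of that codon is
set to C (no stop codon contains C); a planting that itself spells a stop
codon is rejected as infeasible.

What the generator does **not** emulate: termination pausing and codon-level
dwell-time variation, sequencing error, non-uniform library biases, isoform
mixtures, and double/triple readthrough extensions. Passing tests therefore
demonstrate the correctness of the window arithmetic, the divergence
statistics and the fitting machinery under the stated statistical regime —
not robustness to those real-data artefacts.

## Divergence statistics

Logarithms are natural (nats). Positional divergence uses a Jeffreys
pseudocount of ½ per nucleotide per position (disable by passing 0), which
keeps D(r) finite when the reference set lacks a nucleotide; the reference
distribution p*ᵢ(r) is position-specific, taken from the control set at the
same position. Pairwise divergence D(r, s) is computed from raw joint
frequencies with the 0·log 0 = 0 convention — it equals the mutual
information of the two columns and is finite without regularisation. It is
restricted to the 67 non-stop positions (2211 unordered pairs). Fisher
GC-vs-AU tests are two-sided on the 2×2 table [GC, AU] × [set, reference];
no multiple-testing correction is applied by default (a Benjamini–Hochberg
helper is provided). Note the plug-in mutual-information estimate has an
upward sampling bias of order (4−1)²/(2n) nats, which matters when
comparing small sets.

## Regression model

Encoding: A→(1,1), C→(−1,1), U→(1,−1), G→(−1,−1), intercept slot first;
the design matrix has one column per sequence. The fit is minimum-L2-norm
least squares via SVD of the transposed design; singular values below
1e-10 × s_max are truncated (standard pseudoinverse practice), which makes
rank-deficient designs well-defined. Position selection takes the k largest
D(r) values with ties broken toward the smaller absolute flanking label
(upstream first on exact ties), returned 5′→3′. Default k per stop codon:
UGA 18, UAA 13, UAG 25. The model uses single positions only; pair terms
are not included in the default feature map. The "29 contiguous positions"
variant is split 15 upstream / 14 downstream by default (the split is a
configuration knob; nothing forces this choice and results should be
checked against alternatives). Per-stop-codon models are always fitted
separately, never pooled. A predicted rate of exactly 0 counts as "no
readthrough predicted", so it is never a false positive.

## The prediction benchmark

`generate_scr_benchmark` scores uniform random contexts with a known linear
model (default: six causal positions −47, −12, −2, −1, +1, +9, each
contributing ±0.05 for A vs G, intercept −0.05, Gaussian noise 0.005) and
defines the readthrough class by score > 0. Class-conditional nucleotide
enrichment at the causal positions then arises purely by selection, the way
readthrough transcript sets are enriched in real cohorts, and the training
rates are the (positive) scores themselves. This was preferred over
planting biases into a designated positive class because training on
all-positive rates makes under-specified models collapse toward
constant-positive predictors, flattening the false-negative contrast the
benchmark is meant to probe. Half the causal positions lie outside the 6+6
flanking window, so the flanking model misses real signal (high false
positives), while divergence-guided selection recovers all causal positions
and attains the lowest error. With training size fixed, the 29-position
model is not guaranteed to beat the selected-position model — the benchmark
asserts superiority of selection only on average over seeds.

## Degenerate inputs and conventions

Zero `delta_CD` makes the rate undefined: the event is rejected, never
NaN-propagated. Absent downstream stops are a valid outcome of the scan and
exclude the transcript from candidacy. Transcripts with < 49 nt upstream or
< 18 nt downstream flank are skipped for context extraction. Fisher tables
with an empty margin return p = 1. Empty read tables produce all-zero
profiles and a completed pipeline run with zero events.

## Known limitations

- The window-ratio estimator's ≈ 17–19 % upward bias under flat flux means
  absolute rate calibration should not be over-interpreted; comparisons
  between transcripts processed identically are unaffected.
- Context statistics treat positions independently apart from the pairwise
  mutual-information table; no haplotype/motif model is fitted.
- The linear model predicts signed rates and is evaluated only by the sign;
  calibration of predicted magnitudes is out of scope, as are regularised
  variants and interaction features.
- Only the first extension (annotated stop → next in-frame stop) is
  analysed; subsequent readthrough events are ignored.
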