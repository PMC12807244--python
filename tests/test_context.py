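"""Context extraction, divergence statistics, Fisher tests, GC3 profiles."""

import math
from itertools import product

import numpy as np
import pytest
from scipy.stats import hypergeom

from scrleak.context import (
    SCC_LENGTH,
    ContextMatrix,
    benjamini_hochberg,
    divergence_from_counts,
    divergence_table,
    extract_scc,
    fisher_gc_au,
    gc3_profile,
    index_to_label,
    kl_divergence_profile,
    label_to_index,
    mutual_information,
    non_stop_labels,
    nucleotide_counts,
    pairwise_divergence,
    position_frequencies,
    stratify_by_adjacent,
)
from scrleak.records import ScrLeakError, TranscriptRecord

from conftest import make_transcript


def make_context(stop="UGA", fill="A"):
    return fill * 49 + stop + fill * 18


class TestLabels:
    def test_round_trip_over_all_non_stop_positions(self):
        labels = non_stop_labels()
        assert len(labels) == 67
        for lbl in labels:
            assert index_to_label(label_to_index(lbl)) == lbl

    def test_flanking_labels_map_to_stop_neighbours(self):
        assert label_to_index(-1) == 48
        assert label_to_index(1) == 52
        with pytest.raises(ValueError):
            label_to_index(0)


class TestExtraction:
    def test_extracted_context_has_length_seventy(self):
        ctx = extract_scc(make_transcript())
        assert ctx is not None and len(ctx) == SCC_LENGTH

    def test_context_matches_hand_sliced_substring(self):
        t = make_transcript()
        ctx = extract_scc(t)
        assert ctx == t.sequence[t.stop_start - 49 : t.stop_start + 21]
        assert ctx[49:52] == t.stop_codon

    def test_short_upstream_flank_is_skipped(self):
        # 48 nt of transcript upstream of the stop codon is not enough
        seq = "AUG" + "C" * 42 + "UGA" + "C" * 40
        t = TranscriptRecord("t", seq, 0, 45, "UGA")
        assert extract_scc(t) is None


class TestFrequencies:
    def test_single_symbol_contexts(self):
        freqs = position_frequencies([make_context(fill="A")] * 5)
        # all-A outside the stop codon
        for lbl in non_stop_labels():
            assert freqs[0, label_to_index(lbl)] == 1.0

    def test_two_contexts_differing_at_one_position(self):
        a = make_context(fill="A")
        b = a[:10] + "C" + a[11:]
        freqs = position_frequencies([a, b])
        assert freqs[:, 10] == pytest.approx([0.5, 0.5, 0.0, 0.0])
        assert freqs.sum(axis=0) == pytest.approx(np.ones(70))

    def test_uniform_sampling_recovers_base_composition(self):
        rng = np.random.default_rng(5)
        n = 4000
        contexts = ["".join(rng.choice(list("ACGU"), size=70)) for _ in range(n)]
        freqs = position_frequencies(contexts)
        se = math.sqrt(0.25 * 0.75 / n)
        assert np.abs(freqs - 0.25).max() < 4 * se

    def test_empty_set_fails(self):
        with pytest.raises(ScrLeakError):
            position_frequencies([])


class TestPositionalDivergence:
    def test_identical_distributions_give_zero(self):
        p = np.array([[0.1], [0.2], [0.3], [0.4]])
        assert kl_divergence_profile(p, p) == pytest.approx([0.0])

    def test_degenerate_vs_uniform_is_log_four(self):
        p_set = np.array([[1.0], [0.0], [0.0], [0.0]])
        p_ref = np.full((4, 1), 0.25)
        assert kl_divergence_profile(p_set, p_ref)[0] == pytest.approx(math.log(4.0))

    def test_matches_term_by_term_summation(self):
        rng = np.random.default_rng(3)
        p_set = rng.dirichlet(np.ones(4), size=7).T
        p_ref = rng.dirichlet(np.ones(4), size=7).T
        expected = [
            sum(p_set[i, r] * math.log(p_set[i, r] / p_ref[i, r]) for i in range(4))
            for r in range(7)
        ]
        assert kl_divergence_profile(p_set, p_ref) == pytest.approx(expected)

    def test_pseudocount_keeps_divergence_finite(self):
        set_contexts = [make_context(fill="A")] * 10
        ref_contexts = [make_context(fill="C")] * 10
        d = divergence_from_counts(nucleotide_counts(set_contexts), nucleotide_counts(ref_contexts))
        assert np.isfinite(d).all() and (d >= 0).all()


class TestPairwiseDivergence:
    def test_one_value_per_eligible_pair(self):
        contexts = [make_context(fill=f) for f in "ACGU"]
        table = pairwise_divergence(contexts)
        assert len(table) == 2211  # C(67, 2)
        assert (table.divergence >= -1e-12).all()

    def test_perfectly_coupled_pair_is_log_four(self):
        # 4 context types with matched symbols at two positions
        base = make_context(fill="A")
        contexts = []
        for nuc in "ACGU":
            ctx = list(base)
            ctx[label_to_index(-10)] = nuc
            ctx[label_to_index(5)] = nuc
            contexts.extend(["".join(ctx)] * 3)
        table = pairwise_divergence(contexts)
        row = table[(table.r == -10) & (table.s == 5)]
        assert row.divergence.iloc[0] == pytest.approx(math.log(4.0))

    def test_independent_positions_have_near_zero_divergence(self):
        rng = np.random.default_rng(9)
        contexts = []
        for _ in range(2000):
            ctx = list(make_context(fill="A"))
            ctx[label_to_index(-3)] = "ACGU"[rng.integers(4)]
            ctx[label_to_index(7)] = "ACGU"[rng.integers(4)]
            contexts.append("".join(ctx))
        table = pairwise_divergence(contexts, labels=[-3, 7])
        # sampling bias of the MI estimate is (4-1)(4-1) / (2n)
        assert table.divergence.iloc[0] < 0.02

    def test_matches_mutual_information_oracle(self):
        rng = np.random.default_rng(17)
        contexts = []
        for _ in range(60):
            ctx = list(make_context(fill="A"))
            ctx[label_to_index(-2)] = "ACGU"[rng.integers(4)]
            ctx[label_to_index(3)] = "ACGU"[rng.integers(4) if rng.random() < 0.5 else 0]
            contexts.append("".join(ctx))
        table = pairwise_divergence(contexts, labels=[-2, 3])
        # independent brute-force MI from the joint distribution
        joint = np.zeros((4, 4))
        for ctx in contexts:
            i = "ACGU".index(ctx[label_to_index(-2)])
            j = "ACGU".index(ctx[label_to_index(3)])
            joint[i, j] += 1
        joint /= joint.sum()
        oracle = 0.0
        pi, pj = joint.sum(axis=1), joint.sum(axis=0)
        for i, j in product(range(4), range(4)):
            if joint[i, j] > 0:
                oracle += joint[i, j] * math.log(joint[i, j] / (pi[i] * pj[j]))
        assert table.divergence.iloc[0] == pytest.approx(oracle)
        assert mutual_information(joint) == pytest.approx(oracle)

    def test_symmetry_in_position_order(self):
        rng = np.random.default_rng(23)
        contexts = []
        for _ in range(40):
            ctx = list(make_context(fill="A"))
            for lbl in (-5, 8):
                ctx[label_to_index(lbl)] = "ACGU"[rng.integers(4)]
            contexts.append("".join(ctx))
        d_fwd = pairwise_divergence(contexts, labels=[-5, 8]).divergence.iloc[0]
        d_rev = pairwise_divergence(contexts, labels=[8, -5]).divergence.iloc[0]
        assert d_fwd == pytest.approx(d_rev)


class TestFisher:
    def test_identical_proportions_give_unity(self):
        counts_set = np.array([[25], [25], [25], [25]])
        counts_ref = np.array([[250], [250], [250], [250]])
        assert fisher_gc_au(counts_set, counts_ref)[0] == pytest.approx(1.0)

    def test_extreme_table_matches_hypergeometric_enumeration(self):
        # set: 10 GC, 0 AU; ref: 0 GC, 10 AU
        counts_set = np.array([[0], [5], [5], [0]])
        counts_ref = np.array([[5], [0], [0], [5]])
        p = fisher_gc_au(counts_set, counts_ref)[0]
        # two-sided Fisher p by exhaustive tail summation over the
        # hypergeometric distribution of the [GC_set] cell
        rv = hypergeom(20, 10, 10)
        observed = rv.pmf(10)
        oracle = sum(rv.pmf(k) for k in range(11) if rv.pmf(k) <= observed * (1 + 1e-9))
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_balanced_table_is_unity(self):
        counts_set = np.array([[5], [0], [5], [0]])  # 5 GC, 5 AU
        counts_ref = np.array([[5], [0], [5], [0]])
        assert fisher_gc_au(counts_set, counts_ref)[0] == pytest.approx(1.0)

    def test_empty_margin_convention(self):
        zero = np.zeros((4, 1), dtype=int)
        assert fisher_gc_au(zero, zero)[0] == 1.0

    def test_benjamini_hochberg_is_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.5, 0.9])
        q = benjamini_hochberg(p)
        assert ((0 <= q) & (q <= 1)).all()
        assert (q >= p - 1e-12).all()


class TestGC3:
    def test_all_gc_ending_codons(self):
        seq = "AUG" + "AAC" * 10 + "UGA" + "C" * 70
        t = TranscriptRecord("t", seq, 0, 33, "UGA")
        table = gc3_profile([t])
        assert (table.gc3_fraction == 1.0).all()

    def test_hand_computed_five_codon_cds(self):
        # third bases: G, A, C, U, G -> GC3 pattern 1,0,1,0,1
        seq = "AUG" + "AAG" + "CUA" + "GGC" + "AAU" + "UGG" + "UAA" + "C" * 70
        t = TranscriptRecord("t", seq, 0, 18, "UAA")
        table = gc3_profile([t], align="start")
        assert list(table.gc3_fraction) == [1.0, 1.0, 0.0, 1.0, 0.0, 1.0]
        # stop codon has no index of its own
        assert table.codon_index.max() == 5

    def test_end_alignment_indexes_backwards(self):
        seq = "AUG" + "AAG" + "CUA" + "UAA" + "C" * 70
        t = TranscriptRecord("t", seq, 0, 9, "UAA")
        table = gc3_profile([t], align="end").set_index("codon_index")
        assert table.loc[-1, "gc3_fraction"] == 0.0  # CUA
        assert table.loc[-2, "gc3_fraction"] == 1.0  # AAG
        assert table.loc[-3, "gc3_fraction"] == 1.0  # AUG

    def test_fractions_are_probabilities(self):
        rng = np.random.default_rng(2)
        transcripts = []
        for i in range(20):
            body = "".join(rng.choice(list("ACGU"), size=30))
            seq = "AUG" + body + "UAA" + "C" * 70
            transcripts.append(TranscriptRecord(f"t{i}", seq, 0, 33, "UAA"))
        table = gc3_profile(transcripts)
        assert ((0 <= table.gc3_fraction) & (table.gc3_fraction <= 1)).all()


class TestStratification:
    def test_shared_flank_leaves_other_histograms_empty(self):
        ctx = make_context(fill="A")
        ctx = ctx[:52] + "G" + ctx[53:]  # +1 position is G
        table = stratify_by_adjacent([0.01, 0.02, 0.03], [ctx] * 3)
        plus = table[table.side == "+1"]
        assert plus[plus.nucleotide == "G"]["count"].sum() == 3
        assert plus[plus.nucleotide != "G"]["count"].sum() == 0

    def test_counts_conserve_events(self):
        rng = np.random.default_rng(31)
        contexts, rhos = [], []
        for _ in range(50):
            ctx = list(make_context(fill="A"))
            ctx[48] = "ACGU"[rng.integers(4)]
            ctx[52] = "ACGU"[rng.integers(4)]
            contexts.append("".join(ctx))
            rhos.append(float(rng.uniform(0, 0.1)))
        table = stratify_by_adjacent(rhos, contexts)
        for side in ("-1", "+1"):
            assert table[table.side == side]["count"].sum() == 50

    def test_planted_high_rate_flank_shifts_mass(self):
        contexts, rhos = [], []
        for i in range(40):
            ctx = list(make_context(fill="A"))
            ctx[52] = "C" if i < 20 else "G"
            contexts.append("".join(ctx))
            rhos.append(0.09 if i < 20 else 0.01)
        bins = np.linspace(0, 0.1, 11)
        table = stratify_by_adjacent(rhos, contexts, bins=bins)
        plus = table[table.side == "+1"]
        c_mean_bin = np.average(
            range(10), weights=plus[plus.nucleotide == "C"]["count"]
        )
        g_mean_bin = np.average(
            range(10), weights=plus[plus.nucleotide == "G"]["count"]
        )
        assert c_mean_bin > g_mean_bin


class TestContextMatrix:
    def test_column_sums_equal_context_count(self):
        cm = ContextMatrix([make_context()] * 7, set_label="TS1", stop_codon="UGA")
        assert (cm.counts.sum(axis=0) == 7).all()

    def test_stop_slot_mismatch_is_rejected(self):
        with pytest.raises(ScrLeakError):
            ContextMatrix([make_context(stop="UAA")], stop_codon="UGA")

    def test_wrong_length_rejected(self):
        with pytest.raises(ScrLeakError):
            ContextMatrix(["ACGU" * 10])


def test_divergence_table_reports_all_positions():
    rng = np.random.default_rng(41)
    ts0 = ["".join(rng.choice(list("ACGU"), 49)) + "UGA" + "".join(rng.choice(list("ACGU"), 18)) for _ in range(60)]
    ts1 = ["".join(rng.choice(list("ACGU"), 49)) + "UGA" + "".join(rng.choice(list("ACGU"), 18)) for _ in range(60)]
    table = divergence_table({"TS0": ts0, "TS1": ts1})
    assert len(table) == 70
    assert {"D_TS1", "fisher_p_TS1", "p_A_TS0"} <= set(table.columns)
    assert (table.D_TS1 >= 0).all()
    assert table.position_label.iloc[49] == "stop1"
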