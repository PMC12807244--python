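"""Divergence-guided linear leak-rate predictor.

Each selected context position is encoded by a bipolar pair:
A -> (1, 1), C -> (-1, 1), U -> (1, -1), G -> (-1, -1).  The model

    y = a0 + sum_i b_i x_i

is fitted per stop codon by minimum-norm least squares via the singular
value decomposition of the design matrix, and a sequence is called a
readthrough candidate when the predicted leak rate is strictly positive.

Three position-set variants are provided: the 12 positions flanking the
stop (6 on each side), the 29 positions contiguous to it, and the top-k
positions ranked by positional divergence D(r).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .context import SCC_LENGTH, STOP_SLOTS, index_to_label, label_to_index, non_stop_labels
from .records import ScrLeakError, normalize_sequence

#: bipolar nucleotide codes
ENCODING: dict[str, tuple[int, int]] = {
    "A": (1, 1),
    "C": (-1, 1),
    "U": (1, -1),
    "G": (-1, -1),
}
DECODING = {v: k for k, v in ENCODING.items()}

#: default number of divergence-selected positions per stop codon
DEFAULT_TOP_K = {"UGA": 18, "UAA": 13, "UAG": 25}

#: singular values below EPS * s_max are truncated in the pseudoinverse
SVD_TRUNCATION = 1e-10


def encode_context(context: str, selected_positions: list[int] | tuple[int, ...]) -> np.ndarray:
    """Feature vector of a context: intercept slot 1 followed by the bipolar
    pair of each selected position, in the given order."""
    ctx = normalize_sequence(context, name="context")
    v = np.empty(2 * len(selected_positions) + 1)
    v[0] = 1.0
    for j, label in enumerate(selected_positions):
        nuc = ctx[label_to_index(label)]
        v[2 * j + 1], v[2 * j + 2] = ENCODING[nuc]
    return v


def decode_features(v: np.ndarray) -> str:
    """Nucleotides at the selected positions back from a feature vector."""
    pairs = np.asarray(v)[1:]
    if pairs.size % 2:
        raise ScrLeakError("feature vector has odd non-intercept length")
    return "".join(DECODING[(int(pairs[2 * j]), int(pairs[2 * j + 1]))] for j in range(pairs.size // 2))


def select_positions(divergence: np.ndarray, k: int) -> list[int]:
    """The k non-stop positions with the largest D(r).

    ``divergence`` is indexed over the full 70-slot window; stop-codon slots
    are ignored.  Ties break toward the smaller absolute position label
    (upstream before downstream on exact ties); the result is returned in
    5' to 3' order.
    """
    if k <= 0:
        raise ScrLeakError(f"k must be positive, got {k}")
    divergence = np.asarray(divergence, dtype=float)
    if divergence.size != SCC_LENGTH:
        raise ScrLeakError(f"divergence vector must have length {SCC_LENGTH}")
    labels = non_stop_labels()
    if k > len(labels):
        raise ScrLeakError(f"k={k} exceeds the {len(labels)} eligible positions")
    ranked = sorted(labels, key=lambda lbl: (-divergence[label_to_index(lbl)], abs(lbl), lbl))
    chosen = ranked[:k]
    return sorted(chosen, key=label_to_index)


def build_design(
    contexts: list[str],
    rates: np.ndarray,
    selected_positions: list[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix X (one column per sequence, intercept row of ones) and
    the rate vector y."""
    rates = np.asarray(rates, dtype=float)
    if len(contexts) != rates.size:
        raise ScrLeakError(f"{len(contexts)} contexts but {rates.size} rates")
    if not contexts:
        raise ScrLeakError("empty training set")
    X = np.column_stack([encode_context(c, selected_positions) for c in contexts])
    return X, rates


@dataclass
class LeakModel:
    """Fitted linear leak-rate model."""

    w: np.ndarray
    selected_positions: list[int]
    singular_values: np.ndarray
    training_size: int
    stop_codon: str = ""
    truncation: float = SVD_TRUNCATION

    @property
    def intercept(self) -> float:
        return float(self.w[0])

    def coefficient_pairs(self) -> dict[int, tuple[float, float]]:
        """Per-position (b1, b2) coefficient pairs keyed by position label."""
        return {
            lbl: (float(self.w[2 * j + 1]), float(self.w[2 * j + 2]))
            for j, lbl in enumerate(self.selected_positions)
        }


def fit_min_norm(
    X: np.ndarray,
    y: np.ndarray,
    selected_positions: list[int] | None = None,
    stop_codon: str = "",
    truncation: float = SVD_TRUNCATION,
) -> LeakModel:
    """Minimum-L2-norm least-squares fit of w in X^T w = y.

    Uses the SVD of X^T = U S V^T; singular values below
    ``truncation * s_max`` are treated as zero (pseudoinverse truncation),
    so rank-deficient designs yield the unique smallest-norm solution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[1] != y.size:
        raise ScrLeakError(f"non-conformable design: X {X.shape}, y {y.shape}")
    U, s, Vt = np.linalg.svd(X.T, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > truncation * s[0]
    else:
        keep = np.zeros_like(s, dtype=bool)
    coeffs = np.zeros_like(s)
    coeffs[keep] = (U.T @ y)[keep] / s[keep]
    w = Vt.T @ coeffs
    return LeakModel(
        w=w,
        selected_positions=list(selected_positions) if selected_positions is not None else [],
        singular_values=s,
        training_size=y.size,
        stop_codon=stop_codon,
        truncation=truncation,
    )


def fit_leak_model(
    contexts: list[str],
    rates: np.ndarray,
    selected_positions: list[int],
    stop_codon: str = "",
    truncation: float = SVD_TRUNCATION,
) -> LeakModel:
    """Convenience wrapper: encode, build the design, fit."""
    X, y = build_design(contexts, rates, selected_positions)
    return fit_min_norm(X, y, selected_positions, stop_codon, truncation)


def predict(model: LeakModel, context: str) -> float:
    """Predicted leak rate w . v; negative values mean 'no readthrough'."""
    v = encode_context(context, model.selected_positions)
    if v.size != model.w.size:
        raise ScrLeakError(f"feature width {v.size} does not match model width {model.w.size}")
    return float(model.w @ v)


@dataclass
class EvalResult:
    """False-positive / false-negative evaluation of a fitted model."""

    fp_count: int
    fn_count: int
    n_negatives: int
    n_positives: int

    @property
    def fp_fraction(self) -> float:
        return self.fp_count / self.n_negatives

    @property
    def fn_fraction(self) -> float:
        return self.fn_count / self.n_positives


def evaluate(model: LeakModel, positives: list[str], negatives: list[str]) -> EvalResult:
    """False positives: non-readthrough sequences with a strictly positive
    predicted rate.  False negatives: readthrough sequences with a strictly
    negative predicted rate.  A prediction of exactly 0 counts as 'no
    readthrough predicted'."""
    if not positives or not negatives:
        raise ScrLeakError("both test sets must be nonempty")
    fp = sum(1 for c in negatives if predict(model, c) > 0)
    fn = sum(1 for c in positives if predict(model, c) < 0)
    return EvalResult(fp_count=fp, fn_count=fn, n_negatives=len(negatives), n_positives=len(positives))


def model_variants(
    stop_codon: str,
    divergence: np.ndarray | None = None,
    k: int | None = None,
    contig29_upstream: int = 15,
) -> dict[str, list[int]]:
    """The three position-set variants compared in the benchmark.

    * ``flank12``: the 6 positions on each side of the stop codon.
    * ``contig29``: 29 positions contiguous to the stop; the upstream /
      downstream split is configurable (default 15 upstream, 14 downstream).
    * ``topk``: the k highest-divergence positions, k defaulting to
      18 / 13 / 25 for UGA / UAA / UAG.
    """
    variants = {
        "flank12": list(range(-6, 0)) + list(range(1, 7)),
        "contig29": list(range(-contig29_upstream, 0)) + list(range(1, 30 - contig29_upstream)),
    }
    if divergence is not None:
        kk = k if k is not None else DEFAULT_TOP_K[normalize_sequence(stop_codon)]
        variants["topk"] = select_positions(divergence, kk)
    return variants
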