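"""Alignment-free k-mer statistics over symbolic microstate sequences.

A length-n series over an m-symbol alphabet has n-k+1 overlapping k-mers out
of a word space of size m^k.  Observed counts X_w are compared against the
expectation under the sequence's own first-order Markov background model,

    p(w) = p(w_1) * prod_j T(w_{j-1}, w_j),

giving centralized counts X~_w = X_w - (n-k+1) p(w), the D2 / D2* similarity
statistics, the normalized D2* dissimilarity, and the per-word standardized
feature F_w = X~_w / sqrt((n-k+1) p(w)) used as the fine-level feature
vector.  Words are ordered lexicographically over symbol indices so feature
columns are comparable across trials.

Zero-probability words with zero counts contribute 0 wherever a 0/0 would
arise (no pseudocounts by default; Laplace smoothing is available as an
option on the model estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .types import MarkovModel, MicrostateSequence

__all__ = [
    "KmerTable",
    "CentralizedTable",
    "count_kmers",
    "estimate_markov",
    "word_probability",
    "all_word_probabilities",
    "d2",
    "centralize",
    "d2_star",
    "d2_star_norm",
    "fw_features",
    "dissimilarity_matrix",
    "word_strings",
    "KmerFeaturizer",
]


@dataclass
class KmerTable:
    """Sliding-window k-mer counts X_w over the full word space (size m^k)."""

    k: int
    m: int
    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != self.m**self.k:
            raise ValueError("counts must cover the full word space m^k")
        if self.counts.sum() != self.n - self.k + 1:
            raise ValueError("counts must sum to n - k + 1")

    @property
    def frequencies(self) -> np.ndarray:
        """f_w = X_w / (n - k + 1); sums to 1."""
        return self.counts / (self.n - self.k + 1)


@dataclass
class CentralizedTable:
    """Centralized counts X~_w = X_w - E_w with E_w = (n-k+1) p(w)."""

    k: int
    m: int
    values: np.ndarray
    expected: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.values.shape != self.expected.shape or self.values.size != self.m**self.k:
            raise ValueError("values/expected must cover the full word space m^k")


def _as_labels(sequence: MicrostateSequence | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(sequence, MicrostateSequence):
        return sequence.labels, sequence.n_states
    arr = np.asarray(sequence, dtype=np.int64)
    return arr, int(arr.max()) + 1


def word_strings(m: int, k: int) -> list[str]:
    """All m^k words in the canonical lexicographic order, as symbol strings."""
    return ["".join(str(s) for s in w) for w in product(range(m), repeat=k)]


def count_kmers(sequence: MicrostateSequence | np.ndarray, k: int,
                m: int | None = None) -> KmerTable:
    """Count every overlapping k-mer of the sequence (n - k + 1 windows).

    The word w = (w_1 .. w_k) maps to index sum_j w_j * m^(k-j), i.e.
    lexicographic order.
    """
    labels, m_inferred = _as_labels(sequence)
    m = m_inferred if m is None else m
    n = labels.size
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= n (got k={k}, n={n})")
    codes = labels[: n - k + 1].copy()
    for j in range(1, k):
        codes = codes * m + labels[j : n - k + 1 + j]
    counts = np.bincount(codes, minlength=m**k)
    return KmerTable(k=k, m=m, counts=counts, n=n)


def estimate_markov(sequence: MicrostateSequence | np.ndarray,
                    m: int | None = None, pseudocount: float = 0.0) -> MarkovModel:
    """Maximum-likelihood first-order Markov model of a sequence.

    The initial distribution is the empirical symbol frequency over all n
    samples; the transition matrix row-normalizes the bigram counts.  Rows of
    symbols that never precede anything are left all-zero (``zero_rows`` on
    the model).  A positive ``pseudocount`` applies Laplace smoothing to both
    estimates (off by default).
    """
    labels, m_inferred = _as_labels(sequence)
    m = m_inferred if m is None else m
    if labels.size < 2:
        raise ValueError("need at least 2 samples to estimate transitions")
    initial = np.bincount(labels, minlength=m).astype(float) + pseudocount
    initial /= initial.sum()
    bigrams = np.zeros((m, m))
    np.add.at(bigrams, (labels[:-1], labels[1:]), 1.0)
    bigrams += pseudocount
    row_sums = bigrams.sum(axis=1, keepdims=True)
    transition = np.divide(bigrams, row_sums, out=np.zeros_like(bigrams),
                           where=row_sums > 0)
    return MarkovModel(initial, transition)


def word_probability(model: MarkovModel, word) -> float:
    """p(w) = p(w_1) * prod_{j>=2} T(w_{j-1}, w_j); 0 if any factor is 0."""
    symbols = [int(c) for c in word] if isinstance(word, str) else list(word)
    if not symbols:
        raise ValueError("word must be non-empty")
    if min(symbols) < 0 or max(symbols) >= model.n_states:
        raise ValueError("word symbol outside the model alphabet")
    p = model.initial[symbols[0]]
    for a, b in zip(symbols[:-1], symbols[1:]):
        if p == 0:
            return 0.0
        p *= model.transition[a, b]
    return float(p)


def all_word_probabilities(model: MarkovModel, k: int) -> np.ndarray:
    """p(w) for every word of length k, in lexicographic order (sums to 1)."""
    if k < 1:
        raise ValueError("k must be positive")
    m = model.n_states
    probs = model.initial.copy()  # length m^1, last symbol = index % m
    for _ in range(1, k):
        probs = (probs[:, None] * model.transition[np.arange(probs.size) % m]).ravel()
    return probs


def d2(table_x: KmerTable, table_y: KmerTable) -> float:
    """D2 similarity: inner product of the two count vectors."""
    if table_x.k != table_y.k or table_x.m != table_y.m:
        raise ValueError("tables must share k and alphabet size")
    return float(table_x.counts @ table_y.counts)


def centralize(table: KmerTable, model: MarkovModel) -> CentralizedTable:
    """Subtract the Markov-expected counts: X~_w = X_w - (n-k+1) p(w)."""
    if model.n_states != table.m:
        raise ValueError("model alphabet does not match the table")
    expected = (table.n - table.k + 1) * all_word_probabilities(model, table.k)
    return CentralizedTable(
        k=table.k, m=table.m,
        values=table.counts - expected, expected=expected, n=table.n,
    )


def _standardized(ct: CentralizedTable) -> np.ndarray:
    """X~_w / sqrt(E_w) with the 0/0 := 0 convention; errors on X_w>0, E_w=0."""
    bad = (ct.expected == 0) & (ct.values != 0)
    if np.any(bad):
        raise ValueError(
            "word with zero Markov probability but nonzero count: "
            "degenerate background model"
        )
    out = np.zeros_like(ct.values)
    nz = ct.expected > 0
    out[nz] = ct.values[nz] / np.sqrt(ct.expected[nz])
    return out


def d2_star(cx: CentralizedTable, cy: CentralizedTable) -> float:
    """D2* similarity: sum_w X~_w Y~_w / sqrt(E_w^X E_w^Y).

    Word terms where both the numerator and the denominator vanish contribute
    0 (the 0/0 := 0 convention); a vanishing expectation with a nonzero count
    is a degenerate-model error.
    """
    if cx.k != cy.k or cx.m != cy.m:
        raise ValueError("tables must share k and alphabet size")
    return float(_standardized(cx) @ _standardized(cy))


def d2_star_norm(cx: CentralizedTable, cy: CentralizedTable) -> float:
    """Normalized D2* dissimilarity: 1 - D2*(X,Y)/sqrt(D2*(X,X) D2*(Y,Y)).

    Symmetric, 0 for identical inputs, and bounded in [0, 2] by
    Cauchy-Schwarz.  A zero self-norm (a sequence whose counts match its
    Markov expectation exactly) leaves the normalization undefined.
    """
    sx = _standardized(cx)
    sy = _standardized(cy)
    if cx.k != cy.k or cx.m != cy.m:
        raise ValueError("tables must share k and alphabet size")
    nx = float(sx @ sx)
    ny = float(sy @ sy)
    if nx == 0 or ny == 0:
        raise ValueError("zero self-norm: sequence is exactly Markov-typical")
    return 1.0 - float(sx @ sy) / np.sqrt(nx * ny)


def fw_features(sequence: MicrostateSequence | np.ndarray, k: int,
                m: int | None = None) -> np.ndarray:
    """Fine-level feature vector F_w = X~_w / sqrt((n-k+1) p(w)), length m^k.

    The background model is the sequence's own first-order Markov estimate;
    words with zero probability and zero count get F_w = 0.
    """
    if k < 2:
        raise ValueError("k must be at least 2 for a first-order background model")
    table = count_kmers(sequence, k, m=m)
    model = estimate_markov(sequence, m=table.m)
    return _standardized(centralize(table, model))


def dissimilarity_matrix(sequences, k: int, m: int | None = None) -> np.ndarray:
    """Square matrix of pairwise normalized-D2* dissimilarities."""
    tables = [count_kmers(s, k, m=m) for s in sequences]
    ms = {t.m for t in tables}
    if len(ms) > 1:
        if m is None:
            m_common = max(ms)
            tables = [count_kmers(s, k, m=m_common) for s in sequences]
        else:
            raise ValueError("sequences disagree on alphabet size")
    cts = [centralize(t, estimate_markov(s, m=t.m))
           for s, t in zip(sequences, tables)]
    n = len(cts)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = d2_star_norm(cts[i], cts[j])
    return out


class KmerFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer yielding the m^k fine-level feature vector per sequence.

    Parameters
    ----------
    k : k-mer length (default 5, the best-performing length upstream of the
        fused feature set).
    n_states : alphabet size; inferred from the data in ``fit`` when None.
    """

    def __init__(self, k: int = 5, n_states: int | None = None):
        self.k = k
        self.n_states = n_states

    def fit(self, X, y=None):
        if self.n_states is not None:
            self.n_states_ = self.n_states
        else:
            self.n_states_ = max(_as_labels(s)[1] for s in X)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_states_"):
            raise AttributeError("featurizer is not fitted")
        return np.vstack([fw_features(s, self.k, m=self.n_states_) for s in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(
            [f"fw_{w}" for w in word_strings(self.n_states_, self.k)], dtype=object
        )
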