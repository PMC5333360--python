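"""Position weight matrices, log-odds scoring and exact score-distribution p-values.

A PWM is a k x 4 matrix of per-position nucleotide probabilities (columns
ordered A, C, G, T).  Scanning scores a window w of length k as the log-odds

    s(w) = sum_i log2( p_i(w_i) / bg(w_i) )   [bits]

against a zero-order background model.  The tail probability
P(s(W) >= s) for a random background word W is computed exactly (up to a
stated discretization) by dynamic-programming convolution of the
per-position score distributions, so binding sites can be called at a
calibrated significance level (default alpha = 0.005).

Discretization and conservativeness
-----------------------------------
Per-position log-odds entries are floored to an integer grid of width
``granularity`` bits (default 1e-3).  The scanner scores windows on that
same grid, so the DP distribution is *exact* for scanner scores.  Relative
to the continuous score, a word's gridded score can be low by at most
(k-1) grid units more than another word's, so site p-values are looked up
at (gridded score - (k-1) units); this guarantees that no reported p-value
is ever smaller than the exact continuous-score p-value, at the price of a
conservative bias bounded by 2k grid units of score (~0.03 bits for k=14
at the default granularity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G under column order ACGT

__all__ = [
    "PWM",
    "BackgroundModel",
    "ScoredSite",
    "ScoreDistribution",
    "log_odds",
    "score_distribution",
    "threshold_for_alpha",
]


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order background: probabilities for A, C, G, T."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background must have exactly 4 frequencies (A,C,G,T)")
        if not np.all(f > 0):
            raise ValueError("background frequencies must all be > 0")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError(f"background frequencies must sum to 1, got {f.sum()!r}")
        object.__setattr__(self, "freqs", tuple(float(x) for x in f))

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_sequences(cls, sequences) -> "BackgroundModel":
        """Estimate frequencies from sequences (dict or iterable of str); N ignored."""
        counts = np.zeros(4, dtype=np.int64)
        seqs = sequences.values() if hasattr(sequences, "values") else sequences
        for seq in seqs:
            codes = encode_sequence(seq)
            counts += np.bincount(codes[codes < 4], minlength=4)
        total = counts.sum()
        if total == 0:
            raise ValueError("cannot estimate background from empty sequences")
        # one pseudo-observation per base avoids zero frequencies on tiny inputs
        freqs = (counts + 1) / (total + 4)
        return cls(tuple(freqs))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.freqs)


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide probability matrix (k x 4, columns A,C,G,T).

    ``probs`` is stored after pseudocounting: ``(p + c) / (1 + 4c)`` per row
    with per-cell pseudocount ``c`` (default 0.01), so every entry is
    strictly positive and usable in log-odds.
    """

    probs: np.ndarray
    name: str = "pwm"
    pseudocount: float = field(default=0.01)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PWM probs must be a k x 4 matrix")
        if not 1 <= p.shape[0] <= 30:
            raise ValueError(f"PWM length must be in [1, 30], got {p.shape[0]}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        rowsums = p.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            raise ValueError("PWM rows must each sum to 1 before pseudocounting")
        p = (p + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        if np.any(p <= 0):
            raise ValueError(
                "PWM has zero-probability cells; use a positive pseudocount"
            )
        if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("PWM rows do not sum to 1 after pseudocounting")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @classmethod
    def from_counts(cls, counts, name: str = "pwm", pseudocount: float = 0.01) -> "PWM":
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        rowsums = c.sum(axis=1, keepdims=True)
        if np.any(rowsums == 0):
            raise ValueError("PWM count rows must not be all zero")
        return cls(c / rowsums, name=name, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in np.argmax(self.probs, axis=1))

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, _COMPLEMENT_ORDER]
        # probs already pseudocounted; do not pseudocount again
        obj = object.__new__(PWM)
        object.__setattr__(obj, "probs", np.ascontiguousarray(rc))
        object.__setattr__(obj, "name", self.name + "_rc")
        object.__setattr__(obj, "pseudocount", self.pseudocount)
        return obj

    def information_content(self, bg: BackgroundModel | None = None) -> float:
        """Total information content in bits (relative entropy vs background)."""
        bgf = (bg or BackgroundModel.uniform()).array
        return float(np.sum(self.probs * np.log2(self.probs / bgf)))


@dataclass(frozen=True)
class ScoredSite:
    """One predicted binding site in forward-strand coordinates.

    ``start``/``end`` are 0-based half-open; ``end - start`` equals the PWM
    length.  ``score`` is the gridded log-odds in bits; ``p_value`` is the
    (conservative) tail probability of the score under the background.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def log_odds(pwm: PWM, bg: BackgroundModel) -> np.ndarray:
    """k x 4 log2-odds matrix (bits): entry[i][b] = log2(probs[i][b] / bg[b])."""
    bgf = bg.array
    if np.any(bgf <= 0):
        raise ValueError("background frequencies must be positive")
    return np.log2(pwm.probs / bgf)


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N etc.) -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(ALPHABET):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ScoreDistribution:
    """Exact distribution of gridded PWM scores under a zero-order background.

    Built by :func:`score_distribution`.  Scores live on an integer grid of
    ``granularity`` bits; ``support``/``pmf``/``tail_probs`` describe the
    attainable gridded scores.  Memory is bounded by
    ``sum_i (max_i - min_i) / granularity`` bins; construction refuses to
    build tables above 5e7 bins.
    """

    MAX_BINS = 50_000_000

    def __init__(self, int_matrix: np.ndarray, bg: BackgroundModel, granularity: float):
        self.granularity = float(granularity)
        self.int_matrix = int_matrix  # k x 4, floor(log_odds / granularity)
        self.k = int_matrix.shape[0]
        mins = int_matrix.min(axis=1)
        maxs = int_matrix.max(axis=1)
        span = int((maxs - mins).sum())
        if span + 1 > self.MAX_BINS:
            raise MemoryError(
                f"score distribution needs {span + 1} bins (> {self.MAX_BINS}); "
                "increase granularity"
            )
        bgf = bg.array
        pmf = np.zeros(span + 1)
        pmf[0] = 1.0
        hi = 0
        for i in range(self.k):
            new = np.zeros(span + 1)
            width = hi + 1
            for b in range(4):
                off = int(int_matrix[i, b] - mins[i])
                new[off : off + width] += bgf[b] * pmf[:width]
            hi += int(maxs[i] - mins[i])
            pmf = new
        self.offset = int(mins.sum())  # gridded score of bin 0
        self.pmf = pmf
        # tail[j] = P(score_int >= offset + j)
        self.tail_probs = np.cumsum(pmf[::-1])[::-1]

    # -- queries ----------------------------------------------------------
    @property
    def min_score_int(self) -> int:
        return self.offset

    @property
    def max_score_int(self) -> int:
        return self.offset + len(self.pmf) - 1

    def tail(self, score_int: int) -> float:
        """P(gridded score >= score_int), exact on the grid."""
        j = int(score_int) - self.offset
        if j <= 0:
            return 1.0
        if j >= len(self.tail_probs):
            return 0.0
        return float(self.tail_probs[j])

    def pvalue(self, score_int: int) -> float:
        """Conservative site p-value: tail at (score_int - (k-1)) grid units.

        Guarantees the reported p is never below the exact continuous-score
        tail probability (see module docstring).
        """
        return self.tail(int(score_int) - (self.k - 1))

    def tail_bits(self, score_bits: float) -> float:
        return self.tail(int(np.ceil(score_bits / self.granularity - 1e-9)))

    def attained_scores(self) -> np.ndarray:
        """Sorted gridded scores (integer units) with nonzero probability."""
        idx = np.nonzero(self.pmf > 0)[0]
        return idx + self.offset

    def score_word(self, word: str) -> int:
        """Gridded score (integer units) of a length-k word; N not allowed."""
        codes = encode_sequence(word)
        if len(codes) != self.k or np.any(codes >= 4):
            raise ValueError("word must be length k over A,C,G,T")
        return int(self.int_matrix[np.arange(self.k), codes].sum())

    def to_bits(self, score_int: int) -> float:
        return score_int * self.granularity


def score_distribution(
    pwm: PWM, bg: BackgroundModel, granularity: float = 1e-3
) -> ScoreDistribution:
    """Exact (gridded) null distribution of PWM log-odds scores under ``bg``."""
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    lo = log_odds(pwm, bg)
    int_matrix = np.floor(lo / granularity + 1e-9).astype(np.int64)
    return ScoreDistribution(int_matrix, bg, granularity)


def threshold_for_alpha(
    pwm: PWM, bg: BackgroundModel, alpha: float, granularity: float = 1e-3,
    dist: ScoreDistribution | None = None,
) -> int | None:
    """Smallest attainable gridded score whose (conservative) p-value <= alpha.

    Returns the threshold in integer grid units, or ``None`` when even the
    maximal attainable score is not significant at ``alpha`` (no-call).
    """
    if not 0 < alpha < 1:
        if alpha == 1:
            dist = dist or score_distribution(pwm, bg, granularity)
            return int(dist.attained_scores()[0])
        raise ValueError("alpha must lie in (0, 1]")
    dist = dist or score_distribution(pwm, bg, granularity)
    attained = dist.attained_scores()
    pvals = np.array([dist.pvalue(s) for s in attained])
    ok = np.nonzero(pvals <= alpha)[0]
    if len(ok) == 0:
        return None
    return int(attained[ok[0]])
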