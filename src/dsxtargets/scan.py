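"""Genome scanning: call PWM binding sites on both strands at a significance level.

Every length-k window on either strand whose gridded log-odds score reaches
the alpha-level threshold (see :mod:`dsxtargets.pwm`) is emitted as a
:class:`~dsxtargets.pwm.ScoredSite` in forward-strand coordinates.  Windows
containing N (or any non-ACGT symbol) are skipped rather than scored.
Overlapping calls, including double-strand calls at palindromic loci, are
kept as distinct sites by default; ``merge_overlaps=True`` keeps only the
best-scoring site of each run of overlapping calls per sequence.
"""

from __future__ import annotations

import numpy as np

from .pwm import (
    _COMPLEMENT_ORDER,
    PWM,
    BackgroundModel,
    ScoredSite,
    ScoreDistribution,
    encode_sequence,
    score_distribution,
    threshold_for_alpha,
)

__all__ = ["scan", "scan_scores"]

_NEG = np.int64(-(1 << 40))  # sentinel column score for N: sinks any window


def _rc_int_matrix(int_matrix: np.ndarray) -> np.ndarray:
    """Matrix scoring a window as its reverse complement under the same PWM/bg.

    rev[i][b] = fwd[k-1-i][complement(b)], so the reverse-strand score of a
    window equals the forward score of its reverse complement exactly; strand
    symmetry then holds for any background model.
    """
    return np.ascontiguousarray(int_matrix[::-1, _COMPLEMENT_ORDER])


def _window_scores(codes: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Gridded scores of all forward windows; windows with N get a huge negative."""
    k = int_matrix.shape[0]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    lut = np.concatenate([int_matrix, np.full((k, 1), _NEG, dtype=np.int64)], axis=1)
    acc = np.zeros(n, dtype=np.int64)
    for i in range(k):
        acc += lut[i][codes[i : i + n]]
    return acc


def scan_scores(
    sequence: str, pwm: PWM, bg: BackgroundModel, granularity: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, ScoreDistribution]:
    """Gridded window scores for one sequence on both strands.

    Returns ``(fwd, rev, dist)`` where ``fwd[j]``/``rev[j]`` score the window
    starting at forward coordinate ``j`` on the +/- strand respectively.
    """
    dist = score_distribution(pwm, bg, granularity)
    codes = encode_sequence(sequence)
    fwd = _window_scores(codes, dist.int_matrix)
    rev = _window_scores(codes, _rc_int_matrix(dist.int_matrix))
    return fwd, rev, dist


def scan(
    sequences: dict[str, str],
    pwm: PWM,
    bg: BackgroundModel,
    alpha: float = 0.005,
    granularity: float = 1e-3,
    merge_overlaps: bool = False,
) -> list[ScoredSite]:
    """Call significant PWM sites on both strands of every sequence.

    Reverse-strand windows are scored against the reverse-complemented
    matrix, which is equivalent to scoring the reverse complement of the
    window, and reported at their forward-strand interval.  Sequences
    shorter than k yield no sites (not an error).
    """
    dist = score_distribution(pwm, bg, granularity)
    thr = threshold_for_alpha(pwm, bg, alpha, granularity, dist=dist)
    if thr is None:
        return []
    k = pwm.length
    rc_matrix = _rc_int_matrix(dist.int_matrix)
    sites: list[ScoredSite] = []
    for seq_id in sequences:
        codes = encode_sequence(sequences[seq_id])
        seq_sites: list[ScoredSite] = []
        for strand, matrix in (("+", dist.int_matrix), ("-", rc_matrix)):
            scores = _window_scores(codes, matrix)
            hits = np.nonzero(scores >= thr)[0]
            for j in hits:
                s = int(scores[j])
                seq_sites.append(
                    ScoredSite(
                        seq_id=seq_id,
                        start=int(j),
                        end=int(j) + k,
                        strand=strand,
                        score=dist.to_bits(s),
                        p_value=dist.pvalue(s),
                    )
                )
        seq_sites.sort(key=lambda s: (s.start, s.strand))
        if merge_overlaps:
            seq_sites = _merge_overlapping(seq_sites)
        sites.extend(seq_sites)
    return sites


def _merge_overlapping(sites: list[ScoredSite]) -> list[ScoredSite]:
    """Keep the best-scoring site of each run of mutually overlapping calls."""
    merged: list[ScoredSite] = []
    run: list[ScoredSite] = []
    run_end = -1
    for site in sites:  # sorted by start
        if run and site.start < run_end:
            run.append(site)
            run_end = max(run_end, site.end)
        else:
            if run:
                merged.append(max(run, key=lambda s: (s.score, -s.start)))
            run = [site]
            run_end = site.end
    if run:
        merged.append(max(run, key=lambda s: (s.score, -s.start)))
    return merged
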