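"""Promoter windows: 5-kb upstream intervals, the non-overlap filter, site counting.

The TSS of a gene is its 5' end (GFF ``start`` on +, ``end`` on -).  The
promoter window is the L-bp interval immediately upstream of the TSS,
clipped to the sequence bounds.  A gene is eligible when neither its body
nor (by default) its upstream window intersects any *other* gene's body;
sites are counted for eligible genes only, requiring full containment in
the window, on either strand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .pwm import ScoredSite

__all__ = [
    "GeneModel",
    "PromoterWindow",
    "SiteCount",
    "upstream_window",
    "non_overlap_filter",
    "count_sites",
]


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates in GFF convention: 1-based, inclusive."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: 1-based start must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        """Transcription start site, 1-based (5' end of the gene)."""
        return self.start if self.strand == "+" else self.end

    @property
    def body(self) -> tuple[int, int]:
        """Gene body as a 0-based half-open interval."""
        return (self.start - 1, self.end)


@dataclass(frozen=True)
class PromoterWindow:
    """Upstream window, 0-based half-open; abuts the TSS on the upstream side."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    eligible: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SiteCount:
    gene_id: str
    n_sites: int


def upstream_window(gene: GeneModel, seq_length: int, L: int = 5000) -> PromoterWindow:
    """L-bp window upstream of the TSS, clipped at the sequence bounds.

    Clipped windows keep their eligibility but record the reduced length; a
    gene whose TSS sits at the sequence edge gets a zero-length window.
    """
    if L <= 0:
        raise ValueError("window length L must be > 0")
    if gene.end > seq_length:
        raise ValueError(f"{gene.gene_id}: gene extends past sequence end")
    if gene.strand == "+":
        end = gene.start - 1
        start = max(0, end - L)
    else:
        start = gene.end
        end = min(seq_length, start + L)
    return PromoterWindow(gene.gene_id, gene.seq_id, start, end)


def non_overlap_filter(
    genes: list[GeneModel],
    L: int = 5000,
    seq_lengths: dict[str, int] | None = None,
    scope: str = "body+window",
) -> dict[str, bool]:
    """Eligibility flags for the promoter non-overlap filter.

    With ``scope='body+window'`` (default) a gene is eligible iff neither its
    body nor its L-bp upstream window intersects any other gene's body; with
    ``scope='body'`` only body-body intersections disqualify.  Intervals are
    half-open and strand-agnostic.
    """
    if scope not in ("body", "body+window"):
        raise ValueError("scope must be 'body' or 'body+window'")
    dup = [g for g, c in Counter(g.gene_id for g in genes).items() if c > 1]
    if dup:
        raise ValueError(f"duplicate gene ids: {dup[:5]}")
    eligible: dict[str, bool] = {}
    by_seq: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_id, group in by_seq.items():
        starts = np.array([g.body[0] for g in group])
        ends = np.array([g.body[1] for g in group])
        seq_len = seq_lengths[seq_id] if seq_lengths else max(int(e) for e in ends) + L
        for i, g in enumerate(group):
            qs, qe = g.body
            if scope == "body+window":
                w = upstream_window(g, seq_len, L)
                qs, qe = min(qs, w.start), max(qe, w.end)
            # only *bodies* of other genes are compared against the query span
            hit = (starts < qe) & (ends > qs)
            hit[i] = False  # a gene's own body never disqualifies it
            eligible[g.gene_id] = not bool(hit.any())
    return eligible


def build_windows(
    genes: list[GeneModel],
    seq_lengths: dict[str, int],
    L: int = 5000,
    scope: str = "body+window",
) -> list[PromoterWindow]:
    """Upstream windows for all genes with eligibility flags attached."""
    flags = non_overlap_filter(genes, L=L, seq_lengths=seq_lengths, scope=scope)
    out = []
    for g in genes:
        w = upstream_window(g, seq_lengths[g.seq_id], L)
        out.append(PromoterWindow(w.gene_id, w.seq_id, w.start, w.end, flags[g.gene_id]))
    return out


def count_sites(
    windows: list[PromoterWindow], sites: list[ScoredSite]
) -> list[SiteCount]:
    """Per-gene counts of sites fully contained in eligible windows.

    A site is counted when ``window.start <= site.start`` and
    ``site.end <= window.end`` on the same sequence, either strand.
    Ineligible genes get no count record.
    """
    by_seq_start: dict[str, np.ndarray] = {}
    by_seq_end: dict[str, np.ndarray] = {}
    for seq_id in {s.seq_id for s in sites}:
        ss = sorted((s.start, s.end) for s in sites if s.seq_id == seq_id)
        by_seq_start[seq_id] = np.array([x[0] for x in ss], dtype=np.int64)
        by_seq_end[seq_id] = np.array([x[1] for x in ss], dtype=np.int64)
    out = []
    for w in windows:
        if not w.eligible:
            continue
        starts = by_seq_start.get(w.seq_id)
        if starts is None or w.length <= 0:
            out.append(SiteCount(w.gene_id, 0))
            continue
        ends = by_seq_end[w.seq_id]
        lo = int(np.searchsorted(starts, w.start, side="left"))
        hi = int(np.searchsorted(starts, w.end, side="left"))
        n = int(np.count_nonzero(ends[lo:hi] <= w.end))
        out.append(SiteCount(w.gene_id, n))
    return out
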