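"""Gene score resampling (GSR) enrichment of functional categories.

Each gene carries a score (by convention -log10 of its BH-adjusted DE
p-value, capped); a category's statistic is the mean score of its members,
and its p-value is estimated by comparing that mean against the means of
random same-size gene draws (without replacement) from the scored-gene
universe, with the add-one estimator p = (1 + #{null >= observed}) /
(n_resamples + 1).  BH adjustment runs across the categories tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust

__all__ = ["gene_scores", "gsr"]

logger = logging.getLogger(__name__)


def gene_scores(p_adj: pd.Series, cap: float = 10.0) -> pd.Series:
    """-log10(p_adj) scores, capped (default 10, i.e. a p_adj floor of 1e-10)."""
    p = p_adj.astype(float).clip(lower=10.0 ** (-cap))
    return (-np.log10(p)).clip(upper=cap).rename("score")


def gsr(
    scores: pd.Series,
    categories: dict[str, list[str]] | pd.DataFrame,
    n_resamples: int = 10_000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 200,
) -> pd.DataFrame:
    """Gene score resampling over a gene -> category map.

    ``categories`` is either {category: [genes]} or a two-column frame
    (gene, category), many-to-many.  Members without scores are dropped;
    categories outside [min_size, max_size] after dropping are excluded
    and logged.  Resampling is reproducible for a given seed.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if isinstance(categories, pd.DataFrame):
        gene_col, cat_col = categories.columns[:2]
        catmap: dict[str, list[str]] = {}
        for cat, grp in categories.groupby(cat_col):
            catmap[str(cat)] = list(grp[gene_col])
    else:
        catmap = {str(k): list(v) for k, v in categories.items()}

    universe = scores.dropna()
    values = universe.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(universe.index)}
    n_genes = len(values)
    rng = np.random.default_rng(seed)

    rows = []
    for cat in sorted(catmap):
        members = [index[g] for g in set(catmap[cat]) if g in index]
        size = len(members)
        if not min_size <= size <= max_size:
            logger.info("category %s excluded: size %d outside [%d, %d]",
                        cat, size, min_size, max_size)
            continue
        observed = float(values[members].mean())
        # null means of n_resamples random same-size draws without replacement:
        # rank a uniform key per gene per resample and take the size smallest;
        # chunked to bound the key matrix at ~64 MB
        exceed = 0
        chunk = max(1, int(8_000_000 // max(n_genes, 1)))
        done = 0
        while done < n_resamples:
            m = min(chunk, n_resamples - done)
            keys = rng.random((m, n_genes))
            picks = np.argpartition(keys, size - 1, axis=1)[:, :size]
            null_means = values[picks].mean(axis=1)
            exceed += int(np.count_nonzero(null_means >= observed - 1e-12))
            done += m
        p = (1 + exceed) / (n_resamples + 1)
        rows.append(
            {"category": cat, "size": size, "observed_mean": observed, "p": p}
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
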