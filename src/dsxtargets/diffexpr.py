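"""Count normalization and a simplified negative-binomial differential test.

The test models counts as NB with Var = mu + alpha * mu^2, estimates a
pooled per-gene dispersion by the method of moments, and forms a Wald
statistic on the log ratio of scaled group means with a delta-method
variance.  The reference distribution is Student-t with nA + nB - 2
degrees of freedom, which accounts for the uncertainty of the per-gene
dispersion estimate at the small replicate numbers this design uses; a
plain normal reference is measurably anti-conservative at n = 6 + 6.

This is deliberately not a re-implementation of DESeq2: there is no
empirical-Bayes dispersion shrinkage and no logFC moderation.  Contrast
convention is "first-named group minus second" on the log scale, so
CF-CM > 0 means female-biased.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "size_factors",
    "fpkm",
    "nb_test",
    "bh_adjust",
    "wilcoxon_ranksum",
    "replicate_qc",
    "run_contrast",
    "select_samples",
]

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (DESeq-style) per-sample scaling factors.

    Uses only genes with positive counts in every sample; each sample's
    factor is the median over those genes of count / geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = np.all(mat > 0, axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in all samples; size factors are "
            "undefined (filter samples or supply factors explicitly)"
        )
    logs = np.log(mat[allpos])
    geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - geo, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of feature length per million mapped fragments."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive length for FPKM")
    colsums = counts.sum(axis=0).astype(float)
    if (colsums == 0).any():
        bad = list(colsums.index[colsums == 0])
        raise ValueError(f"zero column sum for samples {bad}; FPKM undefined")
    kb = lengths.to_numpy(dtype=float)[:, None] / 1e3
    mill = colsums.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / (kb * mill),
        index=counts.index,
        columns=counts.columns,
    )


def nb_test(
    counts: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    factors: pd.Series | None = None,
    min_total: float = 1.0,
    dispersion: str = "common",
) -> pd.DataFrame:
    """Wald test of group A vs group B on size-factor-scaled counts.

    Per-gene method-of-moments dispersion estimates are pooled across the
    two groups; with ``dispersion='common'`` (default) their across-gene
    median is used as a single common dispersion, as in classic
    common-dispersion NB testing.  A per-gene MoM estimate collapses to
    zero for a noticeable fraction of low-count genes at typical replicate
    numbers, which inflates the Wald statistic exactly in the small-p tail
    that BH rejection depends on; the common estimate avoids that without
    any empirical-Bayes machinery.  ``dispersion='per-gene'`` keeps the raw
    per-gene estimates (floored at 1e-8).

    Returns a frame indexed by gene with columns ``log2fc`` (A vs B, with a
    0.5 pseudo-count used for the displayed fold change only), ``se`` (of the
    natural-log ratio), ``p`` and ``mean_a``/``mean_b``.  Genes whose summed
    scaled count across the contrast's samples is below ``min_total`` are
    reported with NaN p (excluded from testing and from BH); genes with
    all-zero counts in both groups get log2fc 0 and p 1.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if dispersion not in ("common", "per-gene"):
        raise ValueError("dispersion must be 'common' or 'per-gene'")
    if factors is None:
        factors = size_factors(counts[list(samples_a) + list(samples_b)])
    a = counts[samples_a].to_numpy(dtype=float) / factors[samples_a].to_numpy()
    b = counts[samples_b].to_numpy(dtype=float) / factors[samples_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]

    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        num = (na - 1) * (va - ma) + (nb - 1) * (vb - mb)
        den = (na - 1) * ma**2 + (nb - 1) * mb**2
        raw = np.where(den > 0, num / den, 0.0)
        if dispersion == "common":
            common = max(float(np.median(np.maximum(raw, 0.0))), DISPERSION_FLOOR)
            alpha = np.full_like(raw, common)
        else:
            alpha = np.maximum(raw, DISPERSION_FLOOR)

        # zero group means would make the log ratio diverge; fall back to the
        # display pseudo-count for the test in that corner
        ta = np.where(ma > 0, ma, np.nan)
        tb = np.where(mb > 0, mb, np.nan)
        use_pseudo = (ma == 0) | (mb == 0)
        ta = np.where(use_pseudo, ma + 0.5, ta)
        tb = np.where(use_pseudo, mb + 0.5, tb)

        var = (ta + alpha * ta**2) / (na * ta**2) + (tb + alpha * tb**2) / (nb * tb**2)
        se = np.sqrt(var)
        z = (np.log(ta) - np.log(tb)) / se
    df = na + nb - 2
    p = 2.0 * stats.t.sf(np.abs(z), df)

    log2fc = np.log2((ma + 0.5) / (mb + 0.5))
    all_zero = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    low = (a.sum(axis=1) + b.sum(axis=1)) < min_total
    p = np.where(low, np.nan, p)
    p = np.where(all_zero, 1.0, p)
    log2fc = np.where(all_zero, 0.0, log2fc)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "mean_a": ma,
            "mean_b": mb,
        },
        index=counts.index,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries propagate as NaN and do not count toward the number of
    tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    vals = p[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact null enumeration when nx + ny <= 16 and there are no ties;
    otherwise the normal approximation with midranks, tie correction and
    continuity correction.  Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def select_samples(
    design: pd.DataFrame,
    sex: str | None = None,
    tissue: str | None = None,
    treatment: str | None = None,
) -> list[str]:
    """Sample names matching the given design-factor levels."""
    mask = pd.Series(True, index=design.index)
    if sex is not None:
        mask &= design["sex"] == sex
    if tissue is not None:
        mask &= design["tissue"] == tissue
    if treatment is not None:
        mask &= design["treatment"] == treatment
    return list(design.index[mask])


_CONTRAST_CODE = {"C": "control", "D": "knockdown"}


def parse_contrast(contrast: str) -> tuple[dict, dict]:
    """Parse a label like 'CF-CM' or 'DM-CM' into two group selectors."""
    try:
        first, second = contrast.split("-")
        groups = []
        for code in (first, second):
            treatment, sex = code[0], code[1]
            groups.append({"treatment": _CONTRAST_CODE[treatment], "sex": sex})
        return groups[0], groups[1]
    except (ValueError, KeyError, IndexError):
        raise ValueError(
            f"contrast must look like 'CF-CM' with C/D and F/M codes, got {contrast!r}"
        ) from None


def run_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str,
    tissue: str,
    factors: pd.Series | None = None,
    min_total: float = 1.0,
) -> pd.DataFrame:
    """DE table for one named contrast within one tissue, with BH adjustment."""
    sel_a, sel_b = parse_contrast(contrast)
    samples_a = select_samples(design, tissue=tissue, **sel_a)
    samples_b = select_samples(design, tissue=tissue, **sel_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"contrast {contrast} in tissue {tissue!r} needs >= 2 replicates per group"
        )
    res = nb_test(counts, samples_a, samples_b, factors=factors, min_total=min_total)
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    res.loc[res["p"] == 1.0, "p_adj"] = 1.0  # all-zero genes are reported, not tested
    res["contrast"] = contrast
    res["tissue"] = tissue
    return res


def replicate_qc(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    lengths: pd.Series,
) -> pd.DataFrame:
    """Pairwise Pearson correlations of log2(FPKM+1) within each design cell.

    Zero-variance samples yield NaN r and are flagged in the ``defined``
    column.
    """
    logf = np.log2(fpkm(counts, lengths) + 1.0)
    rows = []
    for (sex, tissue, treatment), cell in design.groupby(
        ["sex", "tissue", "treatment"], sort=True
    ):
        samples = list(cell.index)
        if len(samples) < 2:
            raise ValueError(
                f"cell ({sex},{tissue},{treatment}) has < 2 replicates"
            )
        for s1, s2 in itertools.combinations(samples, 2):
            v1, v2 = logf[s1].to_numpy(), logf[s2].to_numpy()
            if v1.std() == 0 or v2.std() == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(v1, v2)[0, 1])
            rows.append(
                {
                    "sex": sex,
                    "tissue": tissue,
                    "treatment": treatment,
                    "sample_1": s1,
                    "sample_2": s2,
                    "pearson_r": r,
                    "defined": not np.isnan(r),
                }
            )
    return pd.DataFrame(rows)
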