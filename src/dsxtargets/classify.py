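"""Sex-bias and Dsx-target classification, shift analysis, repertoire comparison.

Classification is a pure function of DE tables and promoter site counts:

* sex-biased (per tissue): significant in CF-CM; sign of log2FC gives the
  direction (positive = female-biased).
* Dsx-mediated (per sex, per tissue): significant in the knockdown-vs-
  control contrast for that sex (DF-CF or DM-CM); higher in control =
  activated by Dsx, higher in knockdown = suppressed.
* putative Dsx target: mediated AND >= min_sites significant predicted
  binding sites in the gene's eligible 5-kb upstream window.

Repertoires are compared across sexes per tissue: targets shared with the
same regulatory direction vs opposite directions, and a per-tissue mode
call (modulator: disjoint male/female repertoires; switch: a substantial
shared-opposite component).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust, fpkm, select_samples, wilcoxon_ranksum

__all__ = [
    "classify_sex_bias",
    "classify_mediated",
    "putative_targets",
    "shift_analysis",
    "compare_repertoires",
    "ortholog_recovery",
    "RepertoireComparison",
]


def classify_sex_bias(de: pd.DataFrame, alpha_adj: float = 0.05) -> pd.Series:
    """Labels 'female' / 'male' / 'none' from a CF-CM (or DF-DM) DE table.

    Strictly p_adj < alpha_adj; positive log2FC means female-biased under
    the first-minus-second contrast convention.
    """
    if "p_adj" not in de.columns:
        raise ValueError("DE table lacks a p_adj column")
    sig = de["p_adj"] < alpha_adj
    labels = np.where(
        sig & (de["log2fc"] > 0), "female", np.where(sig & (de["log2fc"] < 0), "male", "none")
    )
    return pd.Series(labels, index=de.index, name="sex_bias")


def classify_mediated(de: pd.DataFrame, alpha_adj: float = 0.05) -> pd.Series:
    """Labels 'activated' / 'suppressed' / 'none' from a DX-CX DE table.

    The contrast must be knockdown-vs-control within one sex (DF-CF or
    DM-CM).  log2FC < 0 (higher in control) = activated by Dsx; log2FC > 0
    (higher in knockdown) = suppressed by Dsx.
    """
    contrast = de["contrast"].iloc[0] if "contrast" in de.columns else None
    if contrast is not None:
        first, second = contrast.split("-")
        if not (first[0] == "D" and second[0] == "C" and first[1] == second[1]):
            raise ValueError(
                f"mediated classification needs a DX-CX contrast, got {contrast!r}"
            )
    sig = de["p_adj"] < alpha_adj
    labels = np.where(
        sig & (de["log2fc"] < 0),
        "activated",
        np.where(sig & (de["log2fc"] > 0), "suppressed", "none"),
    )
    return pd.Series(labels, index=de.index, name="mediated")


def putative_targets(
    mediated: pd.Series, site_counts: dict[str, int] | pd.Series, min_sites: int = 5
) -> pd.Series:
    """Boolean target flags: mediated != 'none' AND site count >= min_sites.

    Genes absent from ``site_counts`` were ineligible for a promoter window
    and are never targets.
    """
    sc = pd.Series(site_counts)
    n = sc.reindex(mediated.index)
    flags = (mediated != "none") & (n >= min_sites)
    return flags.fillna(False).astype(bool).rename("is_target")


def shift_analysis(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    lengths: pd.Series,
    sex_bias_by_tissue: dict[str, pd.Series],
    alpha_adj: float = 0.05,
    pseudo: float = 1.0,
    min_shift: float = 0.5,
) -> pd.DataFrame:
    """How sex-biased gene sets shift when one sex is knocked down.

    For each tissue and each control-defined sex-biased gene set, the
    per-gene female-vs-male log2 fold change (mean FPKM, +``pseudo``) is
    computed in the all-control context and in the contexts where females
    resp. males are knocked down.  Each knockdown context is compared with
    the control context by a Wilcoxon rank-sum test on the per-gene logFC
    distributions, BH-adjusted across all comparisons, and summarized as
    'increased' / 'decreased' / 'unchanged'.  The directional summary
    requires both adjusted significance and a median shift of at least
    ``min_shift`` log2 units, so statistically resolvable but biologically
    negligible drifts stay 'unchanged'; the raw p-values are always
    reported.  Empty gene sets are skipped.
    """
    f = fpkm(counts, lengths)

    def _mean(tissue, sex, treatment):
        cols = select_samples(design, sex=sex, tissue=tissue, treatment=treatment)
        return f[cols].mean(axis=1)

    rows = []
    for tissue, bias in sex_bias_by_tissue.items():
        mf_c = _mean(tissue, "F", "control")
        mm_c = _mean(tissue, "M", "control")
        mf_d = _mean(tissue, "F", "knockdown")
        mm_d = _mean(tissue, "M", "knockdown")
        contexts = {
            "knockdown_female": (mf_d, mm_c),
            "knockdown_male": (mf_c, mm_d),
        }
        lfc_control = np.log2((mf_c + pseudo) / (mm_c + pseudo))
        for set_label in ("female", "male"):
            genes = bias.index[bias == set_label]
            if len(genes) == 0:
                continue
            base = lfc_control.loc[genes].to_numpy()
            for ctx, (num, den) in contexts.items():
                shifted = np.log2(
                    (num.loc[genes] + pseudo) / (den.loc[genes] + pseudo)
                ).to_numpy()
                stat, p = wilcoxon_ranksum(shifted, base)
                rows.append(
                    {
                        "tissue": tissue,
                        "gene_set": f"{set_label}_biased",
                        "context": ctx,
                        "n_genes": len(genes),
                        "median_lfc_control": float(np.median(base)),
                        "median_lfc_context": float(np.median(shifted)),
                        "statistic": stat,
                        "p": p,
                    }
                )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    delta = out["median_lfc_context"] - out["median_lfc_control"]
    out["direction"] = np.where(
        (out["p_adj"] >= alpha_adj) | (np.abs(delta) < min_shift),
        "unchanged",
        np.where(delta > 0, "increased", "decreased"),
    )
    return out


@dataclass
class RepertoireComparison:
    """Cross-sex target comparison for one tissue."""

    tissue: str
    target_m: set[str]
    target_f: set[str]
    shared_same: set[str] = field(default_factory=set)
    shared_opposite: set[str] = field(default_factory=set)
    mode: str = "modulator"

    def summary(self) -> dict:
        return {
            "tissue": self.tissue,
            "n_target_m": len(self.target_m),
            "n_target_f": len(self.target_f),
            "n_shared_same": len(self.shared_same),
            "n_shared_opposite": len(self.shared_opposite),
            "mode": self.mode,
            "shared_same": sorted(self.shared_same),
            "shared_opposite": sorted(self.shared_opposite),
        }


def compare_repertoires(
    mediated_m: pd.Series,
    mediated_f: pd.Series,
    targets_m: pd.Series,
    targets_f: pd.Series,
    tissue: str,
    switch_fraction: float = 0.05,
) -> RepertoireComparison:
    """Split shared targets into same- vs opposite-direction and call the mode.

    mode = 'switch' when the shared-opposite fraction of the target union is
    at least ``switch_fraction`` and exceeds the shared-same count;
    'modulator' when the repertoires are disjoint or the fraction falls
    below the threshold; otherwise 'mixed'.  The threshold is a heuristic
    formalization, not a published value.
    """
    set_m = set(targets_m.index[targets_m])
    set_f = set(targets_f.index[targets_f])
    inter = set_m & set_f
    union = set_m | set_f
    same = {g for g in inter if mediated_m[g] == mediated_f[g]}
    opposite = inter - same
    frac = len(opposite) / len(union) if union else 0.0
    if frac >= switch_fraction and len(opposite) > len(same):
        mode = "switch"
    elif not inter or frac < switch_fraction:
        mode = "modulator"
    else:
        mode = "mixed"
    return RepertoireComparison(tissue, set_m, set_f, same, opposite, mode)


def cross_tissue_sharing(targets_by_tissue: dict[str, pd.Series]) -> pd.DataFrame:
    """Tissue x tissue table of shared target counts for one sex."""
    tissues = list(targets_by_tissue)
    sets = {t: set(s.index[s]) for t, s in targets_by_tissue.items()}
    mat = [[len(sets[a] & sets[b]) for b in tissues] for a in tissues]
    return pd.DataFrame(mat, index=tissues, columns=tissues)


def ortholog_recovery(
    our_targets: set[str],
    foreign_targets: set[str],
    similarity: pd.DataFrame,
    min_identity: float = 80.0,
) -> dict:
    """Fraction of foreign-study targets recovered among our targets.

    ``similarity`` needs columns gene_a (this species), gene_b (foreign)
    and identity (percent).  Pairs are reduced to reciprocal best hits
    (highest identity, ties broken lexicographically); an ortholog is a
    foreign target with a reciprocal partner at >= ``min_identity``
    percent identity; it is recovered when that partner is one of our
    targets.  With no orthologs the fraction is NaN and flagged.
    """
    req = {"gene_a", "gene_b", "identity"}
    if not req.issubset(similarity.columns):
        raise ValueError(f"similarity table needs columns {sorted(req)}")
    sim = similarity[similarity["identity"] >= min_identity]
    sim = sim.sort_values(
        ["identity", "gene_a", "gene_b"], ascending=[False, True, True]
    )
    best_for_b = sim.drop_duplicates("gene_b", keep="first")
    best_for_a = sim.drop_duplicates("gene_a", keep="first")
    reciprocal = best_for_b.merge(best_for_a, on=["gene_a", "gene_b", "identity"])
    partner = dict(zip(reciprocal["gene_b"], reciprocal["gene_a"]))
    orthologs = {g for g in foreign_targets if g in partner}
    recovered = {g for g in orthologs if partner[g] in our_targets}
    n_orth, n_rec = len(orthologs), len(recovered)
    return {
        "n_orthologs": n_orth,
        "n_recovered": n_rec,
        "fraction": (n_rec / n_orth) if n_orth else float("nan"),
        "defined": n_orth > 0,
    }
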