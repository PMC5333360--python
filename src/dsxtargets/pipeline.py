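"""Pipeline driver: scan -> associate -> DE contrasts -> classify -> compare.

``run_stages`` chains the in-memory stages and returns a results bundle;
``run_pipeline`` wraps it with file input/output and a machine-readable
summary JSON.  Thresholds default to the analysis's standard values
(site alpha 0.005, 5-kb windows, >= 5 sites, adjusted p < 0.05, 80 %
identity) and every run logs the thresholds actually used, since the
downstream classification is threshold-dependent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import classify as cl
from . import diffexpr as de
from . import fileio
from .promoter import GeneModel, build_windows, count_sites
from .pwm import PWM, BackgroundModel
from .scan import scan

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_stages", "run_pipeline"]

CONTRASTS = ("CF-CM", "DF-DM", "DF-CF", "DM-CM")


@dataclass
class PipelineConfig:
    """Paths and thresholds for a file-based pipeline run."""

    genome: str
    gff: str
    pwm: str
    counts: str
    design: str
    outdir: str
    pwm_format: str = "jaspar"
    alpha_site: float = 0.005
    window: int = 5000
    min_sites: int = 5
    alpha_adj: float = 0.05
    min_identity: float = 80.0
    switch_fraction: float = 0.05
    background: str = "genome"  # or "uniform"
    overlap_scope: str = "body+window"
    category_map: str | None = None
    similarity: str | None = None
    foreign_targets: str | None = None
    enrich_resamples: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha_site < 1 or not 0 < self.alpha_adj < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
        if self.window <= 0 or self.min_sites < 0:
            raise ValueError("window must be > 0 and min_sites >= 0")
        required = ["genome", "gff", "pwm", "counts", "design"]
        optional = ["category_map", "similarity", "foreign_targets"]
        for name in required + optional:
            path = getattr(self, name)
            if name in optional and path is None:
                continue
            if not Path(path).exists():
                raise FileNotFoundError(f"missing input for stage setup: {name} = {path}")


def run_stages(
    genome: dict[str, str],
    genes: list[GeneModel],
    pwm: PWM,
    counts: pd.DataFrame,
    design: pd.DataFrame,
    lengths: pd.Series,
    alpha_site: float = 0.005,
    window: int = 5000,
    min_sites: int = 5,
    alpha_adj: float = 0.05,
    switch_fraction: float = 0.05,
    background: str = "genome",
    overlap_scope: str = "body+window",
    run_shift: bool = True,
) -> dict:
    """Run the in-memory analysis chain and return a results bundle.

    Keys of the returned dict: ``sites``, ``site_counts``, ``de`` (nested
    {tissue: {contrast: frame}}), ``sex_bias``, ``mediated``, ``targets``,
    ``shift``, ``comparisons``, ``qc``, ``summary``.
    """
    if background == "genome":
        bg = BackgroundModel.from_sequences(genome)
    elif background == "uniform":
        bg = BackgroundModel.uniform()
    else:
        raise ValueError("background must be 'genome' or 'uniform'")
    logger.info(
        "thresholds: alpha_site=%g window=%d min_sites=%d alpha_adj=%g "
        "switch_fraction=%g background=%s", alpha_site, window, min_sites,
        alpha_adj, switch_fraction, background,
    )

    logger.info("stage scan: %d sequences", len(genome))
    sites = scan(genome, pwm, bg, alpha=alpha_site)

    logger.info("stage associate: %d genes, %d sites", len(genes), len(sites))
    seq_lengths = {name: len(s) for name, s in genome.items()}
    windows = build_windows(genes, seq_lengths, L=window, scope=overlap_scope)
    counts_per_gene = {c.gene_id: c.n_sites for c in count_sites(windows, sites)}

    tissues = sorted(design["tissue"].unique())
    factors = de.size_factors(counts)
    de_tables: dict[str, dict[str, pd.DataFrame]] = {}
    for tissue in tissues:
        de_tables[tissue] = {}
        for contrast in CONTRASTS:
            logger.info("stage detest: %s %s", tissue, contrast)
            de_tables[tissue][contrast] = de.run_contrast(
                counts, design, contrast, tissue, factors=factors
            )

    sex_bias = {t: cl.classify_sex_bias(de_tables[t]["CF-CM"], alpha_adj) for t in tissues}
    mediated = {
        t: {
            "M": cl.classify_mediated(de_tables[t]["DM-CM"], alpha_adj),
            "F": cl.classify_mediated(de_tables[t]["DF-CF"], alpha_adj),
        }
        for t in tissues
    }
    targets = {
        t: {
            sex: cl.putative_targets(mediated[t][sex], counts_per_gene, min_sites)
            for sex in "MF"
        }
        for t in tissues
    }

    shift = (
        cl.shift_analysis(counts, design, lengths, sex_bias, alpha_adj)
        if run_shift
        else pd.DataFrame()
    )

    comparisons = {
        t: cl.compare_repertoires(
            mediated[t]["M"], mediated[t]["F"], targets[t]["M"], targets[t]["F"],
            tissue=t, switch_fraction=switch_fraction,
        )
        for t in tissues
    }

    qc = de.replicate_qc(counts, design, lengths)

    summary = {
        "parameters": {
            "alpha_site": alpha_site,
            "window": window,
            "min_sites": min_sites,
            "alpha_adj": alpha_adj,
            "switch_fraction": switch_fraction,
            "background": background,
            "background_freqs": list(bg.freqs),
            "switch_rule": "heuristic shared-opposite fraction, not a published rule",
        },
        "n_sites": len(sites),
        "n_eligible_genes": len(counts_per_gene),
        "tissues": {
            t: {
                "mode": comparisons[t].mode,
                "n_sex_biased_female": int((sex_bias[t] == "female").sum()),
                "n_sex_biased_male": int((sex_bias[t] == "male").sum()),
                "n_mediated_m": int((mediated[t]["M"] != "none").sum()),
                "n_mediated_f": int((mediated[t]["F"] != "none").sum()),
                "n_target_m": int(targets[t]["M"].sum()),
                "n_target_f": int(targets[t]["F"].sum()),
                "n_shared_same": len(comparisons[t].shared_same),
                "n_shared_opposite": len(comparisons[t].shared_opposite),
            }
            for t in tissues
        },
        "qc_min_pearson_r": float(qc["pearson_r"].min()),
    }
    return {
        "background": bg,
        "sites": sites,
        "site_counts": counts_per_gene,
        "de": de_tables,
        "sex_bias": sex_bias,
        "mediated": mediated,
        "targets": targets,
        "shift": shift,
        "comparisons": comparisons,
        "qc": qc,
        "summary": summary,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; writes all declared outputs plus summary.json."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = fileio.read_fasta(config.genome)
    genes = fileio.read_gff3(config.gff)
    pwm = fileio.read_pwm(config.pwm, fmt=config.pwm_format)
    counts = fileio.read_tsv(config.counts, index_col=0)
    design = fileio.read_tsv(config.design, index_col=0)
    if "length" in counts.columns:
        lengths = counts.pop("length")
    else:
        lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})

    results = run_stages(
        genome, genes, pwm, counts, design, lengths,
        alpha_site=config.alpha_site, window=config.window,
        min_sites=config.min_sites, alpha_adj=config.alpha_adj,
        switch_fraction=config.switch_fraction, background=config.background,
        overlap_scope=config.overlap_scope,
    )

    fileio.write_bed6(fileio.sites_to_bed6(results["sites"], pwm.name),
                      outdir / "sites.bed")
    fileio.write_tsv(fileio.sites_to_table(results["sites"]),
                     outdir / "sites.tsv", index=False)
    sc = pd.DataFrame(
        sorted(results["site_counts"].items()), columns=["gene_id", "n_sites"]
    )
    fileio.write_tsv(sc, outdir / "site_counts.tsv", index=False)
    for tissue, tables in results["de"].items():
        for contrast, table in tables.items():
            fileio.write_tsv(table, outdir / f"de_{tissue}_{contrast}.tsv")
    for tissue in results["sex_bias"]:
        frame = pd.DataFrame(
            {
                "sex_bias": results["sex_bias"][tissue],
                "mediated_M": results["mediated"][tissue]["M"],
                "mediated_F": results["mediated"][tissue]["F"],
                "is_target_M": results["targets"][tissue]["M"],
                "is_target_F": results["targets"][tissue]["F"],
            }
        )
        fileio.write_tsv(frame, outdir / f"classification_{tissue}.tsv")
    if not results["shift"].empty:
        fileio.write_tsv(results["shift"], outdir / "shift_analysis.tsv", index=False)
    fileio.write_tsv(results["qc"], outdir / "replicate_qc.tsv", index=False)
    comp = pd.DataFrame([c.summary() for c in results["comparisons"].values()])
    fileio.write_tsv(
        comp.drop(columns=["shared_same", "shared_opposite"]),
        outdir / "repertoire_comparison.tsv", index=False,
    )

    # optional stages
    if config.category_map is not None:
        from .enrichment import gene_scores, gsr

        cats = fileio.read_tsv(config.category_map)
        for tissue in results["de"]:
            for sex, contrast in (("M", "DM-CM"), ("F", "DF-CF")):
                padj = results["de"][tissue][contrast]["p_adj"].dropna()
                enr = gsr(gene_scores(padj), cats,
                          n_resamples=config.enrich_resamples, seed=config.seed)
                fileio.write_tsv(enr, outdir / f"enrichment_{tissue}_{sex}.tsv",
                                 index=False)
    if config.similarity is not None and config.foreign_targets is not None:
        sim = fileio.read_tsv(config.similarity)
        foreign = set(
            pd.read_csv(config.foreign_targets, sep="\t", header=None)[0].astype(str)
        )
        ours = set()
        for tissue in results["targets"]:
            for sex in "MF":
                flags = results["targets"][tissue][sex]
                ours |= set(flags.index[flags])
        rec = cl.ortholog_recovery(ours, foreign, sim, config.min_identity)
        results["summary"]["ortholog_recovery"] = rec

    with open(outdir / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=2, sort_keys=True)
    results["summary_path"] = str(outdir / "summary.json")
    return results
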