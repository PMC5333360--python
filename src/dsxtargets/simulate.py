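"""Synthetic genomes, planted binding sites and NB count matrices with known truth.

The generator emulates the study conditions the pipeline is built for: a
multi-chromosome genome of i.i.d. background sequence with genes on both
strands, PWM-sampled motif instances planted in the 5-kb upstream windows
of designated target genes, and negative-binomial read counts for a
2 sexes x 4 tissues x 2 treatments x n replicates design with planted gene
classes.

Gene classes and the expression model (log2 mean offsets from a per-gene
baseline b_g, with planted effect e = ``effect_log2fc``):

===========================  =======================================================
class                        model
===========================  =======================================================
female_biased                Dsx suppresses the gene in males: control M at -e,
                             knockdown M back to baseline; females constant.
                             Sex-biased in control; a true target in males.
male_biased                  mirror: Dsx activates in males (control M at +e,
                             knockdown M baseline); a true target in males.
dsx_activated_M              constitutively high in females (+e both treatments);
                             in males +e under control, baseline under knockdown.
                             Not sex-biased in control; a true target in males.
dsx_suppressed_M             mirror with -e; a true target in males.
dsx_activated_F /            as above with the sexes swapped; true targets in
dsx_suppressed_F             females.
shared_antagonistic          switch-tissue only: control M +e, control F -e, both
                             at baseline under knockdown; a true target in both
                             sexes with opposite directions.
dsx_independent_sex_biased   +e in one sex (random sign) in BOTH treatments; not a
                             target, no planted sites.
null                         baseline everywhere.
===========================  =======================================================

Sex-limited classes act in the modulator tissues (every tissue except the
configured switch tissue); shared_antagonistic acts only in the switch
tissue.  Every true-target gene carries ``planted_sites_per_target``
(>= 5) motif instances in its upstream window; all other genes carry
none.  Seeds are split hierarchically (genome / planting / counts) so the
stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .promoter import GeneModel, upstream_window
from .pwm import ALPHABET, PWM, encode_sequence

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "default_pwm",
    "generate_genome",
    "simulate_counts",
    "evaluate_targets",
]

TARGET_CLASSES = (
    "female_biased",
    "male_biased",
    "dsx_activated_M",
    "dsx_suppressed_M",
    "dsx_activated_F",
    "dsx_suppressed_F",
    "shared_antagonistic",
)
ALL_CLASSES = TARGET_CLASSES + ("dsx_independent_sex_biased", "null")

_COMP = str.maketrans("ACGT", "TGCA")


def default_pwm(pseudocount: float = 0.01) -> PWM:
    """A 13-bp Dsx-like matrix (synthetic stand-in, not the CIS-BP matrix).

    Pseudo-palindromic around an ACAATGT-style DM-domain core, with a
    dominant base probability of 0.85 per informative position.  Built from
    idealized counts, not measured binding data.
    """
    consensus = "GACAATGTTGCAA"
    weak = {3, 9}  # two degenerate flanking positions
    counts = []
    for i, base in enumerate(consensus):
        row = [5.0, 5.0, 5.0, 5.0]
        if i in weak:
            row[ALPHABET.index(base)] = 40.0
        else:
            row = [5.0] * 4
            row[ALPHABET.index(base)] = 85.0
        counts.append(row)
    return PWM.from_counts(np.array(counts), name="dsx_like_synth",
                           pseudocount=pseudocount)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 8
    n_genes: int = 2000
    chrom_length: int | None = None  # derived from packing when None
    gene_length_range: tuple[int, int] = (1000, 3000)
    background_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    motif: PWM = field(default_factory=default_pwm)
    planted_sites_per_target: int = 5
    upstream_length: int = 5000
    consensus_sites: bool = False  # plant exact consensus instead of PWM samples
    tissues: tuple[str, ...] = ("brain", "genitalia", "thoracic_horn", "head_horn")
    switch_tissue: str = "head_horn"
    replicates: int = 6
    class_fractions: dict = field(
        default_factory=lambda: {
            "female_biased": 0.05,
            "male_biased": 0.05,
            "dsx_activated_M": 0.05,
            "dsx_suppressed_M": 0.05,
            "dsx_activated_F": 0.02,
            "dsx_suppressed_F": 0.02,
            "shared_antagonistic": 0.04,
            "dsx_independent_sex_biased": 0.04,
        }
    )
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    # log2 baseline expression: 32-1024 expected counts, i.e. robustly
    # expressed genes (very low-count genes are filtered before DE anyway)
    mean_log_range: tuple[float, float] = (5.0, 10.0)

    def __post_init__(self):
        f = np.asarray(self.background_freqs, dtype=float)
        if abs(f.sum() - 1.0) > 1e-12 or np.any(f <= 0):
            raise ValueError("background_freqs must be positive and sum to 1")
        if sum(self.class_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to <= 1 (remainder is null)")
        unknown = set(self.class_fractions) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if self.planted_sites_per_target < 5:
            raise ValueError("planted_sites_per_target must be >= 5 for target classes")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.switch_tissue not in self.tissues:
            raise ValueError("switch_tissue must be one of tissues")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("gene_length_range must be (min, max)")
        if self.motif.length >= self.upstream_length:
            raise ValueError("motif length must be < upstream window length")

    @property
    def modulator_tissues(self) -> tuple[str, ...]:
        return tuple(t for t in self.tissues if t != self.switch_tissue)

    def spawn_rngs(self) -> dict[str, np.random.Generator]:
        """Hierarchical seeds: genome, planting and counts streams."""
        genome_ss, plant_ss, count_ss = np.random.SeedSequence(self.seed).spawn(3)
        return {
            "genome": np.random.default_rng(genome_ss),
            "planting": np.random.default_rng(plant_ss),
            "counts": np.random.default_rng(count_ss),
        }


@dataclass
class TruthTable:
    """Planted ground truth: per-gene class, directions and site plantings.

    ``genes`` has one row per gene (gene_id, gene_class, planted_sites,
    length); ``plantings`` one row per planted instance (gene_id, seq_id,
    start, strand, word).  ``direction(gene_id, sex, tissue)`` returns the
    true Dsx-modulation direction: +1 activated, -1 suppressed, 0 none.
    """

    genes: pd.DataFrame
    plantings: pd.DataFrame
    config: SimulationConfig

    def direction(self, gene_id: str, sex: str, tissue: str) -> int:
        cls = self._class_of(gene_id)
        return class_direction(cls, sex, tissue, self.config)

    def _class_of(self, gene_id: str) -> str:
        return self._class_map()[gene_id]

    def _class_map(self) -> dict[str, str]:
        if not hasattr(self, "_cmap"):
            self._cmap = dict(zip(self.genes["gene_id"], self.genes["gene_class"]))
        return self._cmap

    def true_targets(self, sex: str, tissue: str) -> set[str]:
        """Genes truly Dsx-modulated at (sex, tissue) with >= 5 planted sites."""
        cmap = self._class_map()
        planted = dict(zip(self.genes["gene_id"], self.genes["planted_sites"]))
        return {
            g
            for g, c in cmap.items()
            if class_direction(c, sex, tissue, self.config) != 0 and planted[g] >= 5
        }

    def to_frame(self) -> pd.DataFrame:
        """Flat per-gene table with one direction column per (tissue, sex)."""
        out = self.genes.copy()
        for tissue in self.config.tissues:
            for sex in "FM":
                out[f"dir_{tissue}_{sex}"] = [
                    class_direction(c, sex, tissue, self.config)
                    for c in out["gene_class"]
                ]
        return out


def class_direction(cls: str, sex: str, tissue: str, config: SimulationConfig) -> int:
    """True Dsx-modulation direction (+1 activated, -1 suppressed, 0 none)."""
    modulator = tissue != config.switch_tissue
    if cls == "shared_antagonistic" and not modulator:
        return 1 if sex == "M" else -1
    if not modulator:
        return 0
    if sex == "M":
        return {"female_biased": -1, "male_biased": 1,
                "dsx_activated_M": 1, "dsx_suppressed_M": -1}.get(cls, 0)
    return {"dsx_activated_F": 1, "dsx_suppressed_F": -1}.get(cls, 0)


def _assign_classes(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Class labels for n_genes, floor(fraction * n) per class, rest null."""
    labels = []
    for cls in ALL_CLASSES[:-1]:
        n = int(np.floor(config.class_fractions.get(cls, 0.0) * config.n_genes))
        labels.extend([cls] * n)
    labels.extend(["null"] * (config.n_genes - len(labels)))
    labels = np.array(labels)
    rng.shuffle(labels)
    return list(labels)


def _sample_motif_word(pwm: PWM, rng: np.random.Generator, consensus: bool) -> str:
    if consensus:
        return pwm.consensus
    draws = [rng.choice(4, p=row / row.sum()) for row in pwm.probs]
    return "".join(ALPHABET[b] for b in draws)


def generate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthTable]:
    """Background genome with placed genes and planted upstream motif sites.

    Genes are laid out in per-gene slots of (upstream window + gene body)
    separated by short gaps, so no gene body or upstream window intersects
    another gene body: every gene passes the non-overlap promoter filter
    and has the full upstream clearance.  Raises when the requested genes
    do not fit on the requested chromosomes.
    """
    rngs = config.spawn_rngs()
    g_rng, p_rng = rngs["genome"], rngs["planting"]

    lmin, lmax = config.gene_length_range
    gap = 200
    slot = config.upstream_length + lmax + gap
    per_chrom = int(np.ceil(config.n_genes / config.n_chromosomes))
    needed = per_chrom * slot + gap
    chrom_length = config.chrom_length or needed
    if chrom_length < needed:
        raise ValueError(
            f"infeasible packing: {per_chrom} genes/chromosome need "
            f"{needed} bp (slot = {config.upstream_length} upstream + "
            f"{lmax} max gene + {gap} gap) but chrom_length = {chrom_length}"
        )

    classes = _assign_classes(config, g_rng)
    base_bytes = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    freqs = np.asarray(config.background_freqs)

    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    gene_rows = []
    plant_rows = []
    gi = 0
    for ci in range(config.n_chromosomes):
        seq_id = f"chr{ci + 1}"
        codes = g_rng.choice(4, size=chrom_length, p=freqs).astype(np.uint8)
        pos = gap
        n_here = min(per_chrom, config.n_genes - gi)
        for _ in range(n_here):
            glen = int(g_rng.integers(lmin, lmax + 1))
            strand = "+" if g_rng.random() < 0.5 else "-"
            if strand == "+":
                body_start0 = pos + config.upstream_length
            else:
                body_start0 = pos
            gene = GeneModel(
                gene_id=f"gene{gi + 1:05d}",
                seq_id=seq_id,
                start=body_start0 + 1,
                end=body_start0 + glen,
                strand=strand,
            )
            cls = classes[gi]
            n_plant = 0
            if cls in TARGET_CLASSES:
                n_plant = config.planted_sites_per_target
                w = upstream_window(gene, chrom_length, config.upstream_length)
                k = config.motif.length
                # non-overlapping positions inside the window
                free = w.length - n_plant * k
                if free < 0:
                    raise ValueError("upstream window too small for planted sites")
                cuts = np.sort(p_rng.integers(0, free + 1, size=n_plant))
                starts = [int(w.start + cuts[j] + j * k) for j in range(n_plant)]
                for s0 in starts:
                    word = _sample_motif_word(config.motif, p_rng, config.consensus_sites)
                    site_strand = "+" if p_rng.random() < 0.5 else "-"
                    written = word if site_strand == "+" else word.translate(_COMP)[::-1]
                    codes[s0 : s0 + k] = encode_sequence(written)
                    plant_rows.append(
                        {
                            "gene_id": gene.gene_id,
                            "seq_id": seq_id,
                            "start": s0,
                            "strand": site_strand,
                            "word": word,
                        }
                    )
            genes.append(gene)
            gene_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "gene_class": cls,
                    "planted_sites": n_plant,
                    "length": glen,
                    "seq_id": seq_id,
                    "strand": strand,
                }
            )
            gi += 1
            pos += slot
        genome[seq_id] = base_bytes[codes].tobytes().decode("ascii")
    if gi < config.n_genes:
        raise ValueError(
            f"infeasible packing: placed {gi} of {config.n_genes} genes on "
            f"{config.n_chromosomes} chromosomes of {chrom_length} bp"
        )
    truth = TruthTable(pd.DataFrame(gene_rows), pd.DataFrame(plant_rows), config)
    return genome, genes, truth


def _log2_offset(cls: str, sex: str, tissue: str, treatment: str,
                 config: SimulationConfig, indep_sign: int) -> float:
    """Planted log2 expression offset for one gene class in one sample cell."""
    e = config.effect_log2fc
    modulator = tissue != config.switch_tissue
    control = treatment == "control"
    if cls == "shared_antagonistic":
        if modulator or not control:
            return 0.0
        return e if sex == "M" else -e
    if cls == "dsx_independent_sex_biased":
        biased_sex = "F" if indep_sign > 0 else "M"
        return e if sex == biased_sex else 0.0
    if not modulator:
        return 0.0
    if cls == "female_biased":
        return -e if (sex == "M" and control) else 0.0
    if cls == "male_biased":
        return e if (sex == "M" and control) else 0.0
    if cls == "dsx_activated_M":
        return e if (sex == "F" or control) else 0.0
    if cls == "dsx_suppressed_M":
        return -e if (sex == "F" or control) else 0.0
    if cls == "dsx_activated_F":
        return e if (sex == "M" or control) else 0.0
    if cls == "dsx_suppressed_F":
        return -e if (sex == "M" or control) else 0.0
    return 0.0


def simulate_counts(
    config: SimulationConfig, truth: TruthTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts (genes x samples) and the sample design table.

    Counts are NB with mean mu_gs = 2**(b_g + class offset) and
    Var = mu + alpha mu^2; alpha = 0 degenerates to Poisson.  The counts
    RNG stream is independent of the genome stream, so identical seeds
    reproduce identical tables.
    """
    if config.nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    rng = config.spawn_rngs()["counts"]
    gene_ids = list(truth.genes["gene_id"])
    classes = list(truth.genes["gene_class"])
    n_genes = len(gene_ids)

    lo, hi = config.mean_log_range
    baseline = rng.uniform(lo, hi, size=n_genes)
    indep_sign = np.where(rng.random(n_genes) < 0.5, 1, -1)

    design_rows = []
    sample_names = []
    for tissue in config.tissues:
        for sex in "FM":
            for treatment in ("control", "knockdown"):
                for rep in range(1, config.replicates + 1):
                    code = ("C" if treatment == "control" else "D") + sex
                    name = f"{code}_{tissue}_r{rep}"
                    sample_names.append(name)
                    design_rows.append(
                        {
                            "sample": name,
                            "sex": sex,
                            "tissue": tissue,
                            "treatment": treatment,
                            "replicate": rep,
                        }
                    )
    design = pd.DataFrame(design_rows).set_index("sample")

    # genes sharing (class, independent-bias sign) share offsets in every cell
    keys = [(cls, int(s)) for cls, s in zip(classes, indep_sign)]
    uniq = sorted(set(keys))
    key_idx = np.array([uniq.index(k) for k in keys])

    mat = np.empty((n_genes, len(sample_names)), dtype=np.int64)
    alpha = config.nb_dispersion
    for j, name in enumerate(sample_names):
        row = design.loc[name]
        per_key = np.array(
            [
                _log2_offset(cls, row["sex"], row["tissue"], row["treatment"],
                             config, sign)
                for cls, sign in uniq
            ]
        )
        mu = np.exp2(baseline + per_key[key_idx])
        if np.any(mu <= 0):
            raise ValueError("non-positive NB mean")
        if alpha == 0:
            mat[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / alpha
            mat[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(mat, index=gene_ids, columns=sample_names)
    counts.index.name = "gene_id"
    return counts, design


def write_dataset(config: SimulationConfig, outdir) -> dict[str, str]:
    """Generate and write a full synthetic dataset to ``outdir``.

    Emits genome.fa, genes.gff3, motif.jaspar, counts.tsv (with a length
    column), design.tsv and truth.tsv; returns the path map.
    """
    from pathlib import Path

    from . import fileio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = generate_genome(config)
    counts, design = simulate_counts(config, truth)
    lengths = pd.Series(
        {g.gene_id: g.end - g.start + 1 for g in genes}, name="length"
    )
    counts_out = counts.copy()
    counts_out.insert(0, "length", lengths.reindex(counts.index))
    paths = {
        "genome": str(outdir / "genome.fa"),
        "gff": str(outdir / "genes.gff3"),
        "pwm": str(outdir / "motif.jaspar"),
        "counts": str(outdir / "counts.tsv"),
        "design": str(outdir / "design.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "plantings": str(outdir / "plantings.tsv"),
    }
    fileio.write_fasta(genome, paths["genome"])
    fileio.write_gff3(genes, paths["gff"])
    fileio.write_pwm_jaspar(config.motif, paths["pwm"])
    fileio.write_tsv(counts_out, paths["counts"])
    fileio.write_tsv(design, paths["design"])
    fileio.write_tsv(truth.to_frame(), paths["truth"], index=False)
    fileio.write_tsv(truth.plantings, paths["plantings"], index=False)
    return paths


def evaluate_targets(
    called: dict[tuple[str, str], set[str]], truth: TruthTable
) -> pd.DataFrame:
    """Sensitivity and false-discovery proportion of target calls vs truth.

    ``called`` maps (sex, tissue) to the set of gene ids the pipeline
    labelled putative targets there.
    """
    rows = []
    for (sex, tissue), calls in sorted(called.items()):
        true = truth.true_targets(sex, tissue)
        tp = len(calls & true)
        rows.append(
            {
                "sex": sex,
                "tissue": tissue,
                "n_true": len(true),
                "n_called": len(calls),
                "tp": tp,
                "sensitivity": tp / len(true) if true else float("nan"),
                "fdp": (len(calls) - tp) / len(calls) if calls else 0.0,
            }
        )
    return pd.DataFrame(rows)
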