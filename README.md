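# dsxtargets

Inference of sex- and tissue-specific transcription-factor target
repertoires from bulk RNA-seq counts and a genome, built around the
regulatory logic of *doublesex* (Dsx) — the insect sex-determination
transcription factor whose sex-specific isoforms share one DNA-binding
domain.  Given a genome (FASTA), gene models (GFF3), a Dsx-style position
weight matrix, and a gene × sample count table from a control vs
dsx-knockdown design, the package answers: which genes does Dsx regulate,
in which sex and tissue, in which direction — and does a tissue use Dsx as
a **modulator** (disjoint male/female target sets) or as a **switch** (the
same genes regulated in opposite directions in the two sexes)?

It is a library for programmatic use (with a thin `dsxtargets` CLI for the
pipeline stages), aimed at researchers studying sexual dimorphism and
regulatory evolution who want the full inference chain testable end to end
against planted ground truth.

## The inference chain

1. **Binding-site prediction.** Every length-*k* window *w* on both strands
   is scored as log-odds against a zero-order background,
   s(w) = Σᵢ log₂ (pᵢ(wᵢ) / bg(wᵢ)) bits.  The null distribution of scores
   is computed **exactly** (up to a conservative 10⁻³-bit discretization)
   by dynamic-programming convolution, giving each site a tail probability
   P(S ≥ s); sites are called at *P* < 0.005.
2. **Promoter association.** Each gene's 5-kb window upstream of its TSS is
   built (strand-aware, clipped at sequence bounds); genes whose body or
   window intersects another gene body are excluded; sites fully inside an
   eligible window are counted.
3. **Differential expression.** Counts are scaled by median-of-ratios size
   factors; each contrast (CF-CM, DF-DM, DF-CF, DM-CM per tissue; C =
   control, D = knockdown) gets a Wald test on log(μ̂_A/μ̂_B) under a
   negative-binomial model Var = μ + αμ² with a common (across-gene median
   method-of-moments) dispersion and a Student-t reference with
   n_A + n_B − 2 df, then Benjamini–Hochberg adjustment.
4. **Classification.** Sex-biased = significant in CF-CM (sign gives
   direction).  Dsx-mediated = significant in DF-CF or DM-CM (higher in
   control = activated, higher in knockdown = suppressed).  **Putative
   target** = mediated AND ≥ 5 significant sites in the eligible window.
5. **Repertoire comparison.** Per tissue, shared targets are split into
   same-direction vs opposite-direction sets; a tissue is a *switch* when
   the opposite-direction fraction of the target union is substantial,
   otherwise a *modulator*.  A Wilcoxon shift analysis tracks how
   control-defined sex-biased gene sets move when either sex is knocked
   down, and gene-score-resampling enrichment tests functional categories.
6. **Synthetic truth.** A first-class generator plants all of the above —
   background genome, genes on both strands, ≥ 5 PWM-sampled motif
   instances upstream of every true target, and NB counts for a
   2 sexes × 4 tissues × 2 treatments × 6 replicates design with planted
   gene classes — so every stage is testable without any download.

## Worked example

```python
import pandas as pd
from dsxtargets import (SimulationConfig, generate_genome, simulate_counts,
                        run_stages, evaluate_targets)

cfg = SimulationConfig(seed=1, n_genes=600, n_chromosomes=3)
genome, genes, truth = generate_genome(cfg)
counts, design = simulate_counts(cfg, truth)
lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})
results = run_stages(genome, genes, cfg.motif, counts, design, lengths)
for tissue, info in results["summary"]["tissues"].items():
    print(tissue, info["mode"], info["n_target_m"], info["n_target_f"],
          info["n_shared_opposite"])
```

prints (from `examples/04_classify_targets.py`):

```
brain: mode = modulator
  targets: 120 male, 24 female; shared same-direction 0, opposite 0
genitalia: mode = modulator
  targets: 122 male, 24 female; shared same-direction 0, opposite 0
head_horn: mode = switch
  targets: 25 male, 24 female; shared same-direction 0, opposite 24
thoracic_horn: mode = modulator
  targets: 121 male, 24 female; shared same-direction 0, opposite 0
```

i.e. the three modulator tissues have many more male than female targets
with no overlap between the sexes, while the one switch-like tissue's male
and female repertoires coincide almost entirely — regulated in opposite
directions.  Against the planted truth this run recovers every true target
(sensitivity 1.0) with a false-discovery proportion ≤ 0.04 per sex ×
tissue.  The `examples/` directory holds one short script per capability
(simulation, scanning, DE, classification, enrichment).

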