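# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.  No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
compute.

## Binding-site model

A PWM is a k × 4 matrix of per-position nucleotide probabilities
(1 ≤ k ≤ 30).  Matrices built from counts receive a pseudocount of 0.01
per cell before renormalization so log-odds entries are finite.  A window
w is scored in bits against a zero-order background bg:
s(w) = Σᵢ log₂(pᵢ(wᵢ)/bg(wᵢ)).  The background defaults to the base
composition of the scanned genome (a uniform option exists); it is a
zero-order model — no dinucleotide or higher-order structure.

**Exact p-values.** Per-position scores are floored onto an integer grid
of `granularity` = 10⁻³ bits, and the distribution of gridded scores under
bg is computed by dynamic-programming convolution (memory is
Σᵢ(maxᵢ−minᵢ)/granularity bins; construction refuses tables above 5·10⁷
bins).  The scanner scores windows on the same grid, so tail probabilities
are exact for scanner scores.  Because two words with equal continuous
scores can grid differently by up to k−1 bins, a site's reported p-value
is the tail at (gridded score − (k−1) bins).  This guarantees the reported
p is **never smaller** than the exact continuous-score tail probability,
at the price of a conservative bias bounded by ~2k granularity units of
score (≈0.03 bits at k = 14).  The α-level threshold is the smallest
attainable gridded score whose conservative p ≤ α (default α = 0.005); a
no-call sentinel is returned when no score qualifies.

Reverse-strand windows are scored as the forward score of their reverse
complement under the same matrix and background, which makes strand
symmetry exact for any background composition.  Windows containing N are
skipped, not scored: assembly gaps should not produce sites.  Overlapping
calls, including both-strand calls at near-palindromic loci, count as
distinct sites by default (`merge_overlaps` keeps only the best call per
overlapping run).

## Promoter association

The TSS is the 5′ gene end from the GFF record.  The upstream window is
the L = 5000 bp immediately upstream, clipped at sequence bounds (clipped
windows stay eligible; no minimum length is imposed).  The non-overlap
filter reads "non-overlapping with other genes" strictly: a gene is
ineligible when its body **or** its upstream window intersects any other
gene's body (half-open intervals, strand-agnostic).  A body-only scope is
selectable.  Sites must be fully contained in the window — a site half
outside the 5 kb is not within it — and both strands count toward one
gene, since TF binding is strand-agnostic at this resolution.

## Differential expression

Counts are scaled by DESeq-style median-of-ratios size factors (computed
over genes positive in all samples).  For a contrast A vs B within one
tissue (labels CF-CM, DF-DM, DF-CF, DM-CM; first-minus-second on the log
scale, so CF-CM > 0 is female-biased), each gene gets a Wald statistic

  z = log(μ̂_A/μ̂_B) / se,  se² = Σ_g (μ̂_g + α μ̂_g²)/(n_g μ̂_g²)

under the NB variance Var = μ + αμ².  The dispersion α is estimated per
gene by method of moments pooled across both groups, and the **across-gene
median** of those estimates is used as a single common dispersion (classic
common-dispersion NB testing).  Rationale: at n = 6 + 6 the per-gene
moment estimate collapses to ~0 for a noticeable fraction of lower-count
genes, which inflates the Wald statistic exactly in the small-p tail that
BH rejection depends on; a common estimate removes that failure mode
without empirical-Bayes machinery.  The raw per-gene variant (floored at
10⁻⁸) remains available via `dispersion="per-gene"`.  The reference
distribution is Student-t with n_A + n_B − 2 df rather than normal — the
dispersion is estimated, and at six replicates the normal reference is
measurably anti-conservative.  Measured on the package's own calibration
simulation (20,000 null NB genes, μ = 100, α = 0.1, 6 vs 6): type-I error
≈ 0.034 at p < 0.05, power ≈ 1.0 for |log2FC| = 2 at p_adj < 0.05 (see
`tests/test_acceptance.py`).

Displayed log2 fold changes add a 0.5 pseudo-count to both group means
(display only; the test uses raw means, falling back to the pseudo-count
when a group mean is zero).  Genes with summed scaled counts below 1
across the contrast's samples are excluded from testing (NaN p, excluded
from the BH m); all-zero genes report log2FC = 0, p = 1.  BH adjustment is
the standard step-up, order-preserving, with NaN propagation.  This engine
deliberately reimplements none of DESeq2's dispersion shrinkage or LFC
moderation: the package's contribution is the classification chain, and
the DE engine is a documented simplified stand-in.

Wilcoxon rank-sum tests use exact enumeration for n_x + n_y ≤ 16 without
ties, otherwise the normal approximation with midranks, tie correction and
continuity correction.  Replicate QC reports pairwise Pearson correlations
of log₂(FPKM+1) within each sex × tissue × treatment cell; FPKM is
count / (length/10³ · column-sum/10⁶).

## Classification and repertoire comparison

All classification is a pure function of DE tables and site counts — no
randomness.  Thresholds are strict (`p_adj < 0.05`): sex-biased from
CF-CM sign; mediated from DF-CF/DM-CM (higher in control = activated by
Dsx); putative target = mediated AND ≥ 5 sites in the eligible window
(genes without an eligible window are never targets).  No effect-size
floor is applied to "mediated" (an optional minimum |log2FC| exists but
defaults to 0).

The shift analysis computes, per control-defined sex-biased gene set, the
per-gene F-vs-M log2 FPKM ratio (pseudo-count 1) in the all-control
context and in the knockdown-female (DF vs CM) and knockdown-male (CF vs
DM) contexts, compares each knockdown context to control by rank-sum, and
adjusts across all comparisons.  The directional summary (increased /
decreased / unchanged) requires adjusted significance **and** a median
shift ≥ 0.5 log2 units: across many set-context combinations, pure-noise
median drifts of ~0.1 log2 units occasionally reach nominal significance,
and an arrow that small is not a regulatory statement.  Raw p-values are
always reported.

Per tissue, shared targets split into same-direction vs opposite-direction
sets.  The mode rule is an explicit formalization (flagged as heuristic in
the output metadata): *switch* when |shared_opposite| / |target union| ≥
`switch_fraction` (default 0.05) and opposite outnumbers same; *modulator*
when the repertoires are disjoint or the fraction is below threshold;
*mixed* otherwise.  Ortholog recovery reduces a similarity table to
reciprocal best pairs (ties: highest identity, then lexicographic id) at
≥ 80 % identity and reports the recovered fraction of the foreign target
set.

## Gene score resampling

Scores are −log₁₀(p_adj) capped at 10 (a p_adj floor of 10⁻¹⁰).  A
category's statistic is the **mean** member score; the null is the mean of
random same-size draws **without replacement from the scored-gene
universe** (not the genome), with the add-one estimator
p = (1 + #{null ≥ observed})/(R + 1) so p is never 0.  Categories outside
[5, 200] members after dropping unscored genes are excluded and logged.
Resampling is seeded and bit-reproducible; the key matrix is chunked to
bound memory at ~64 MB.

## The synthetic generator

The generator emulates the study design: an i.i.d. background genome
(default base composition A/T 0.3, C/G 0.2 — complement-symmetric, so the
scanner's strand symmetry is exact in expectation), genes of 1–3 kb on
both strands laid out in per-gene slots of upstream-window + body
separated by ≥ 200 bp gaps (so the non-overlap filter passes all genes
and every gene has full 5-kb clearance), and a
2 sexes × 4 tissues × 2 treatments × 6 replicates NB count design.

Gene classes and their log2 mean offsets from a per-gene baseline b_g
(effect e = 2 by default) are tabulated in `dsxtargets/simulate.py`; the
essentials: sex-limited target classes act in the three modulator tissues
(e.g. *female_biased* = Dsx suppresses the gene in males, giving
female-biased control expression and a male target; *dsx_activated_M* =
activated in males but constitutively high in females, hence mediated
without sex bias), *shared_antagonistic* acts only in the designated
switch tissue (control males +e, control females −e, both converging to
baseline under knockdown), and *dsx_independent_sex_biased* keeps its sex
bias under knockdown.  Every true-target gene carries exactly
`planted_sites_per_target` (≥ 5) motif instances at non-overlapping
positions in its upstream window, sampled column-wise from the PWM
(consensus planting is available for exact-recovery tests) with uniform
strand; all other genes carry none.  Class counts are ⌊fraction × n⌋;
defaults put 4× more male-limited than female-limited target genes,
mirroring the asymmetric biology the pipeline is meant to resolve.

Baseline log2 expression is uniform on (5, 10), i.e. ~32–1024 expected
counts: robustly expressed genes.  This matters — a 4-fold drop from
single-digit counts is undetectable at six replicates by any test, and
real analyses filter such genes before testing.  Dispersion is a single
α = 0.1 for all genes (Var = μ + αμ²; α = 0 degenerates to Poisson).
Seeds split hierarchically into genome / planting / counts streams, so
identical configurations are byte-reproducible and stages can be
regenerated independently.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: read-level noise and mapping ambiguity
(counts are drawn directly), GC/length bias, isoforms and overlapping gene
models, correlated dispersion structure across genes, batch effects,
partial knockdown efficiency, higher-order genome composition (real
promoters are not i.i.d. background), and enhancers outside the fixed
5-kb upstream window.  The shipped Dsx-like PWM is a synthetic stand-in
built from an idealized ACAATGT-style core, not a measured binding model.

## Numerical choices and degenerate inputs

* Score grid 10⁻³ bits with floor rounding and the −(k−1)-bin query shift
  (conservativeness over precision); DP table capped at 5·10⁷ bins.
* Dispersion floor 10⁻⁸; 0.5 pseudo-count for displayed fold changes; the
  t reference df is n_A + n_B − 2.
* Sites at p = 0 map to BED score 1000; BED scores are −10·log₁₀p rounded.
* Ties in ortholog best-hit selection break by identity then gene id;
  merge-overlaps keeps the highest score, earliest start.
* Zero-length promoter windows (TSS at a sequence edge) yield a site count
  of 0; zero-variance samples yield flagged NaN correlations; empty gene
  sets skip their shift comparisons; an empty ortholog set reports NaN
  with a `defined: false` flag.
* At α = 0.005 a 5-kb double-stranded window accrues tens of chance sites
  under any realistic PWM (the attained tail sits near the threshold), so
  the ≥ 5-site criterion rarely excludes a mediated gene on background
  composition alone — a property of the published thresholds themselves,
  visible directly in the synthetic runs.

## Known limitations

The DE engine is intentionally simpler than DESeq2 (no shrinkage, no
covariates, each tissue tested separately).  The switch/modulator rule is
a formalization of a qualitative published distinction, not an estimated
quantity.  Enrichment implements one GSR variant (mean statistic); other
statistics would need new code.  Exact PWM p-values assume a zero-order
background; repeat-rich or strongly structured genomes violate that
assumption and shift the calibration.
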