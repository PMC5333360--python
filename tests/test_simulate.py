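"""Synthetic-data generator: determinism, planted truth, count model moments."""

import numpy as np
import pandas as pd
import pytest

from dsxtargets.simulate import (
    ALL_CLASSES,
    SimulationConfig,
    TARGET_CLASSES,
    class_direction,
    default_pwm,
    generate_genome,
    simulate_counts,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _small_cfg(**kw):
    base = dict(seed=5, n_genes=80, n_chromosomes=2, replicates=2)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenomeGeneration:
    def test_same_seed_identical_outputs(self):
        cfg = _small_cfg()
        g1, genes1, t1 = generate_genome(cfg)
        g2, genes2, t2 = generate_genome(cfg)
        assert g1 == g2
        assert genes1 == genes2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(t1.plantings, t2.plantings)

    def test_truth_records_planted_sites_in_upstream_window(self):
        cfg = _small_cfg()
        genome, genes, truth = generate_genome(cfg)
        gmap = {g.gene_id: g for g in genes}
        k = cfg.motif.length
        for row in truth.plantings.itertuples(index=False):
            gene = gmap[row.gene_id]
            if gene.strand == "+":
                w_start, w_end = gene.start - 1 - cfg.upstream_length, gene.start - 1
            else:
                w_start, w_end = gene.end, gene.end + cfg.upstream_length
            assert w_start <= row.start and row.start + k <= w_end
        counts = truth.plantings.groupby("gene_id").size()
        targets = truth.genes[truth.genes["gene_class"].isin(TARGET_CLASSES)]
        assert (counts.reindex(targets["gene_id"]) == cfg.planted_sites_per_target).all()

    def test_planted_words_recoverable_from_sequence(self):
        """Every recorded planting matches the genome at its coordinate/strand."""
        cfg = _small_cfg(consensus_sites=True)
        genome, genes, truth = generate_genome(cfg)
        k = cfg.motif.length
        consensus = cfg.motif.consensus
        for row in truth.plantings.itertuples(index=False):
            written = genome[row.seq_id][row.start : row.start + k]
            if row.strand == "-":
                written = written.translate(_COMP)[::-1]
            assert written == consensus == row.word

    def test_exact_consensus_rescan_finds_all_plantings(self):
        cfg = _small_cfg(consensus_sites=True)
        genome, genes, truth = generate_genome(cfg)
        consensus = cfg.motif.consensus
        rc = consensus.translate(_COMP)[::-1]
        for row in truth.plantings.itertuples(index=False):
            probe = consensus if row.strand == "+" else rc
            assert genome[row.seq_id].startswith(probe, row.start)

    def test_background_frequencies_within_binomial_error(self):
        cfg = SimulationConfig(seed=6, n_genes=2, n_chromosomes=1,
                               chrom_length=1_000_000)
        genome, genes, truth = generate_genome(cfg)
        seq = genome["chr1"]
        n = len(seq)
        for base, f in zip("ACGT", cfg.background_freqs):
            observed = seq.count(base) / n
            se = np.sqrt(f * (1 - f) / n)
            # planted sites and placed genes perturb a negligible fraction
            assert abs(observed - f) <= 3 * se + 100 / n

    def test_class_balance_matches_fractions(self):
        cfg = _small_cfg(n_genes=200)
        _, _, truth = generate_genome(cfg)
        counts = truth.genes["gene_class"].value_counts()
        for cls, frac in cfg.class_fractions.items():
            assert counts.get(cls, 0) == int(np.floor(frac * 200))

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(_small_cfg(chrom_length=10_000))

    def test_genes_on_both_strands(self):
        _, genes, _ = generate_genome(_small_cfg())
        strands = {g.strand for g in genes}
        assert strands == {"+", "-"}


class TestCountSimulation:
    def test_same_seed_identical_counts(self):
        cfg = _small_cfg()
        _, _, truth = generate_genome(cfg)
        c1, d1 = simulate_counts(cfg, truth)
        c2, d2 = simulate_counts(cfg, truth)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_design_shape(self):
        cfg = _small_cfg(replicates=3)
        _, _, truth = generate_genome(cfg)
        counts, design = simulate_counts(cfg, truth)
        assert counts.shape == (80, 2 * 2 * 4 * 3)
        cells = design.groupby(["sex", "tissue", "treatment"]).size()
        assert (cells == 3).all()

    def test_poisson_limit_variance_mean_ratio(self):
        """alpha = 0 degenerates to Poisson: var/mean ~ 1 over 10,000 draws."""
        cfg = SimulationConfig(
            seed=8, n_genes=6, n_chromosomes=1, replicates=625,
            nb_dispersion=0.0, mean_log_range=(7.0, 7.0),
        )
        _, _, truth = generate_genome(cfg)
        counts, design = simulate_counts(cfg, truth)
        null_gene = truth.genes.loc[truth.genes["gene_class"] == "null", "gene_id"].iloc[0]
        x = counts.loc[null_gene].to_numpy(dtype=float)
        assert len(x) == 10_000
        ratio = x.var(ddof=1) / x.mean()
        assert 0.97 <= ratio <= 1.03

    def test_nb_moments_match_formula(self):
        """Sample mean/variance of NB(mu=128, alpha=0.1) within 3 SE of theory."""
        cfg = SimulationConfig(
            seed=9, n_genes=6, n_chromosomes=1, replicates=625,
            nb_dispersion=0.1, mean_log_range=(7.0, 7.0),
        )
        _, _, truth = generate_genome(cfg)
        counts, _ = simulate_counts(cfg, truth)
        null_gene = truth.genes.loc[truth.genes["gene_class"] == "null", "gene_id"].iloc[0]
        x = counts.loc[null_gene].to_numpy(dtype=float)
        n = len(x)
        mu, alpha = 128.0, 0.1
        var = mu + alpha * mu**2
        se_mean = np.sqrt(var / n)
        assert abs(x.mean() - mu) <= 3 * se_mean
        m4 = ((x - x.mean()) ** 4).mean()
        se_var = np.sqrt(max(m4 - var**2, 0) / n)
        assert abs(x.var(ddof=1) - var) <= 3 * se_var

    def test_dsx_independent_bias_survives_knockdown(self):
        cfg = _small_cfg(n_genes=400, replicates=6)
        _, _, truth = generate_genome(cfg)
        counts, design = simulate_counts(cfg, truth)
        indep = truth.genes.loc[
            truth.genes["gene_class"] == "dsx_independent_sex_biased", "gene_id"
        ]

        def lfc(treatment):
            f = counts.loc[indep, design.index[(design["sex"] == "F")
                                               & (design["treatment"] == treatment)
                                               & (design["tissue"] == "brain")]]
            m = counts.loc[indep, design.index[(design["sex"] == "M")
                                               & (design["treatment"] == treatment)
                                               & (design["tissue"] == "brain")]]
            return np.log2(f.mean(axis=1) + 1) - np.log2(m.mean(axis=1) + 1)

        # same expected F-M bias magnitude in control and knockdown
        assert np.allclose(lfc("control"), lfc("knockdown"), atol=1.0)
        assert np.abs(lfc("control")).median() > 1.0

    def test_negative_dispersion_rejected(self):
        cfg = _small_cfg()
        _, _, truth = generate_genome(cfg)
        object.__setattr__(cfg, "nb_dispersion", -0.5)
        with pytest.raises(ValueError, match="dispersion"):
            simulate_counts(cfg, truth)


class TestTruthTable:
    def test_every_gene_has_exactly_one_class(self):
        cfg = _small_cfg()
        _, _, truth = generate_genome(cfg)
        assert truth.genes["gene_id"].is_unique
        assert truth.genes["gene_class"].isin(ALL_CLASSES).all()

    def test_target_direction_conventions(self):
        cfg = SimulationConfig()
        # shared antagonistic: activated in males, suppressed in females, switch only
        assert class_direction("shared_antagonistic", "M", "head_horn", cfg) == 1
        assert class_direction("shared_antagonistic", "F", "head_horn", cfg) == -1
        assert class_direction("shared_antagonistic", "M", "brain", cfg) == 0
        # sex-limited target classes act in modulator tissues only
        assert class_direction("male_biased", "M", "brain", cfg) == 1
        assert class_direction("female_biased", "M", "brain", cfg) == -1
        assert class_direction("dsx_activated_F", "F", "brain", cfg) == 1
        assert class_direction("dsx_activated_F", "M", "brain", cfg) == 0
        assert class_direction("null", "M", "brain", cfg) == 0

    def test_true_targets_require_planted_sites(self):
        cfg = _small_cfg()
        _, _, truth = generate_genome(cfg)
        targets = truth.true_targets("M", "brain")
        planted = dict(zip(truth.genes["gene_id"], truth.genes["planted_sites"]))
        assert all(planted[g] >= 5 for g in targets)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"background_freqs": (0.5, 0.5, 0.1, 0.1)},
            {"planted_sites_per_target": 4},
            {"replicates": 1},
            {"switch_tissue": "wing"},
            {"class_fractions": {"null": 0.5, "nonsense": 0.5}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _small_cfg(**kw)
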