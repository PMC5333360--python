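"""Shared fixtures and independent brute-force oracles.

The oracles here recompute expected values by enumeration or direct
formula, independent of the library code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from dsxtargets import (
    SimulationConfig,
    evaluate_targets,
    generate_genome,
    run_stages,
    simulate_counts,
)
from dsxtargets.pwm import BackgroundModel, PWM, log_odds


# -- PWM oracles ----------------------------------------------------------

def enumerate_word_scores(pwm: PWM, bg: BackgroundModel):
    """All 4^k words with continuous log-odds score and background probability."""
    lo = log_odds(pwm, bg)
    k = pwm.length
    bgf = bg.array
    words = np.array(list(itertools.product(range(4), repeat=k)))
    scores = lo[np.arange(k), words].sum(axis=1)
    probs = bgf[words].prod(axis=1)
    return words, scores, probs


def enumerate_gridded(dist, bg: BackgroundModel):
    """Word scores on the scanner's integer grid, with probabilities."""
    k = dist.k
    bgf = bg.array
    words = np.array(list(itertools.product(range(4), repeat=k)))
    scores = dist.int_matrix[np.arange(k), words].sum(axis=1)
    probs = bgf[words].prod(axis=1)
    return scores, probs


def oracle_tail(scores: np.ndarray, probs: np.ndarray, s: float) -> float:
    return float(probs[scores >= s].sum())


def random_pwm(rng: np.random.Generator, k: int, sharp: float = 5.0) -> PWM:
    """A random Dirichlet PWM; larger ``sharp`` concentrates columns."""
    alpha = np.full(4, 0.5)
    probs = rng.dirichlet(alpha * sharp / 2, size=k)
    return PWM(probs, name=f"rand{k}")


# -- Wilcoxon oracle ------------------------------------------------------

def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided rank-sum p by enumerating all C(nx+ny, nx) assignments."""
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()  # midranks (no ties assumed)
    w_obs = ranks[:nx].sum()
    mean_w = nx * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


# -- end-to-end fixture ---------------------------------------------------

E2E_SEEDS = (101, 202, 303)


def run_synthetic_pipeline(seed: int):
    """Default-condition synthetic run: returns (results, truth, evaluation)."""
    cfg = SimulationConfig(seed=seed)
    genome, genes, truth = generate_genome(cfg)
    counts, design = simulate_counts(cfg, truth)
    lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})
    results = run_stages(genome, genes, cfg.motif, counts, design, lengths)
    called = {
        (sex, tissue): set(
            results["targets"][tissue][sex].index[results["targets"][tissue][sex]]
        )
        for tissue in results["targets"]
        for sex in "MF"
    }
    evaluation = evaluate_targets(called, truth)
    return results, truth, evaluation


@pytest.fixture(scope="session")
def e2e_runs():
    """Full synthetic pipeline under default conditions for three seeds."""
    return {seed: run_synthetic_pipeline(seed) for seed in E2E_SEEDS}


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast synthetic dataset for unit-level pipeline tests."""
    cfg = SimulationConfig(seed=7, n_genes=160, n_chromosomes=2, replicates=3)
    genome, genes, truth = generate_genome(cfg)
    counts, design = simulate_counts(cfg, truth)
    lengths = pd.Series({g.gene_id: g.end - g.start + 1 for g in genes})
    return cfg, genome, genes, truth, counts, design, lengths
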