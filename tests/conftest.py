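"""Shared fixtures: small synthetic cohorts and identifiable cell mixtures."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from csfaging.simulate import (
    CohortConfig,
    make_planted_clock,
    simulate_beta,
    simulate_cell_mixtures,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant cohort with mixtures, planted clock and noise-free betas."""
    cfg = CohortConfig(n_participants=40, blood_subset_n=8, seed=123)
    sheet, truth = simulate_cohort(cfg)
    mix = simulate_cell_mixtures(sheet, K=3, decay_rate=0.15, n_probes=150, seed=123)
    clock = make_planted_clock(mix, n_clock_probes=60, seed=123)
    betas = simulate_beta(sheet, truth, mix, clock, noise_sd=0.0, seed=123)
    return {"config": cfg, "sheet": sheet, "truth": truth, "mix": mix, "clock": clock, "betas": betas}


def make_identifiable_mixture(K: int, n_samples: int = 60, n_probes: int = 200, seed: int = 0):
    """Noise-free mixture satisfying the separability conditions for exact
    recovery: each cell type has anchor probes (beta 1 in that type, 0 in the
    others) and at least one pure sample."""
    rng = np.random.default_rng(seed)
    profiles = rng.uniform(0.0, 1.0, size=(K, n_probes))
    block = 20
    for k in range(K):
        profiles[:, block * k : block * (k + 1)] = 0.0
        profiles[k, block * k : block * (k + 1)] = 1.0
    W = rng.dirichlet(np.ones(K), size=n_samples)
    W[:K] = np.eye(K)
    X = pd.DataFrame(
        profiles.T @ W.T,
        index=[f"p{i:04d}" for i in range(n_probes)],
        columns=[f"s{i:03d}" for i in range(n_samples)],
    )
    return X, W, profiles


def best_permutation_error(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Max absolute weight error under the best column permutation."""
    K = truth.shape[1]
    return min(
        float(np.abs(estimated[:, list(perm)] - truth).max())
        for perm in itertools.permutations(range(K))
    )
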