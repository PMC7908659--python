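"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from triplethet import CountMatrix, SimulationConfig, simulate_triplets


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted structure; hybrid expectation equals mid-parent."""
    cfg = SimulationConfig(
        n_genes=3000, seed=101, frac_deg=0.0, frac_nonadditive=0.0,
        frac_cis_ase=0.0, baseline_log_sd=0.8,
        library_size_range=(1.5e6, 2.0e6),
    )
    return simulate_triplets(cfg)


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong planted DEG / non-additive / cis-ASE structure.

    Depth is set so every gene has a line mean of at least ~50 normalized
    counts, which makes the planted effect sizes separable at 2 replicates.
    """
    cfg = SimulationConfig(
        n_genes=4000, seed=202, baseline_log_sd=0.5,
        frac_deg=0.1, deg_log2fc_magnitude=3.0,
        frac_nonadditive=0.05, nonadditive_margin_log2=2.0,
        nonadditive_mode_mix={
            "high_parent_dominance": 0.0, "low_parent_dominance": 0.0,
            "over_dominance": 0.5, "under_dominance": 0.5,
        },
        frac_cis_ase=0.1, cis_bias=0.85,
        library_size_range=(2.0e6, 2.5e6),
    )
    return simulate_triplets(cfg)


def toy_count_matrix(rng: np.random.Generator, n_genes: int = 50,
                     lines=("A", "B", "AxB"), n_reps: int = 2) -> CountMatrix:
    rows = []
    for line in lines:
        role = "hybrid" if "x" in line else "parent"
        for r in range(1, n_reps + 1):
            rows.append({"sample_id": f"{line}-{r}", "line": line,
                         "replicate": r, "role": role})
    samples = pd.DataFrame(rows).set_index("sample_id")
    counts = pd.DataFrame(
        rng.poisson(100, size=(n_genes, len(samples))),
        index=[f"g{i}" for i in range(n_genes)], columns=samples.index,
    )
    return CountMatrix(counts, samples)
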