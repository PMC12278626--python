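import numpy as np
import pandas as pd
import pytest

from sexde import preprocess
from sexde.simulate import SimulationConfig, simulate_counts


def small_config(**kwargs) -> SimulationConfig:
    """Desk-scale simulation config for unit tests."""
    base = dict(
        n_genes=600,
        n_individuals_per_stage=30,
        n_escape_genes=5,
        n_inactive_genes=10,
        seed=0,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def prenatal_cohort():
    """One simulated prenatal cohort shared by read-only tests."""
    cfg = small_config(seed=42)
    counts, samples, genes, truth = simulate_counts(cfg, "prenatal")
    return cfg, counts, samples, genes, truth


@pytest.fixture(scope="session")
def prenatal_norm(prenatal_cohort):
    """Normalized prenatal expression with marker genes removed."""
    _, counts, samples, genes, _ = prenatal_cohort
    markers = set(genes.loc[genes["marker"] != "", "gene_id"])
    sub = counts.loc[[g for g in counts.index if g not in markers]]
    norm = preprocess.normalize(sub)
    meta = samples.set_index("sample_id")
    return norm, meta
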