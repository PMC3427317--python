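"""Shared fixtures: small synthetic scenarios generated once per session.

Correlation-structure scenarios (hub recovery, module recovery, divergence)
use 12 samples per condition: with only 4 samples the null Pearson r is
uniform on [−1, 1], so correlation ranks carry almost no signal and the
planted structure is not assessable. Differential-expression scenarios keep
the study's 4 + 4 design.
"""

import numpy as np
import pytest
from hypothesis import settings

import diffcoex as dc
from diffcoex import expression as expr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """Default study-sized dataset: 2000 genes, 4 + 4 samples."""
    config = dc.SyntheticConfig(seed=11)
    matrix, design, truth = dc.generate_expression(config)
    return config, matrix, design, truth


@pytest.fixture(scope="session")
def hub_scenario():
    """One planted hub (50 satellites) over background noise, 12 + 12 samples."""
    config = dc.SyntheticConfig(
        n_genes=800,
        n_samples_per_condition=12,
        n_hubs=1,
        hub_degree_target=50,
        modules=(),
        de_fraction=0.0,
        seed=23,
    )
    matrix, design, truth = dc.generate_expression(config)
    ratios = expr.to_log2_ratio(matrix)
    return config, ratios, design, truth


@pytest.fixture(scope="session")
def module_scenario():
    """Planted conserved and condition-specific modules, 25 + 25 samples.

    Cluster recovery needs the pairwise r matrix estimated precisely enough
    that null correlations (sd ≈ 1/sqrt(n−1)) stay clear of the
    within-module correlation; 25 samples per condition gives sd ≈ 0.2.
    """
    config = dc.SyntheticConfig(
        n_genes=600,
        n_samples_per_condition=25,
        n_hubs=0,
        de_fraction=0.0,
        seed=37,
    )
    matrix, design, truth = dc.generate_expression(config)
    ratios = expr.to_log2_ratio(matrix)
    return config, ratios, design, truth


@pytest.fixture(scope="session")
def chip_scenario():
    """Annotation plus peaks with zero dropout and no decoys (exact recovery)."""
    config = dc.SyntheticConfig(n_genes=500, seed=5)
    matrix, design, truth = dc.generate_expression(config)
    annot, peaks, marks, gene_sets = dc.generate_annotation_and_peaks(
        config, truth, list(matrix.gene_ids), dropout=0.0, n_decoys=0
    )
    return config, truth, annot, peaks, marks, gene_sets


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
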