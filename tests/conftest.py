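"""Shared fixtures: one small planted cohort, processed through the
discovery chain once per session so every module can test against it."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from immunodissect import (
    assign_immune_class,
    consensus_cluster,
    exemplar_genes,
    identify_immune_factor,
    mad_filter,
    nmf,
    split_immune_subtypes,
    ssgsea_scores,
)
from immunodissect.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_samples=120, n_genes=800, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return ssgsea_scores(small_cohort.expression, small_cohort.gene_sets)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    filtered = mad_filter(small_cohort.expression, 600)
    return nmf(filtered, 3, n_restarts=3, max_iter=300, seed=1)


@pytest.fixture(scope="session")
def small_immune_factor(small_model, small_scores):
    idx, _ = identify_immune_factor(
        small_model, small_scores.row("immune_signature")
    )
    return idx


@pytest.fixture(scope="session")
def small_exemplars(small_model, small_immune_factor):
    return exemplar_genes(small_model, small_immune_factor)


@pytest.fixture(scope="session")
def small_assignment(small_cohort, small_scores, small_exemplars):
    _, partition = consensus_cluster(
        small_cohort.expression.loc[small_exemplars.genes], seed=3
    )
    labels2 = assign_immune_class(
        partition, small_scores.row("immune_signature")
    )
    return split_immune_subtypes(
        labels2,
        small_scores.row("activated_stroma"),
        immune_scores=small_scores.row("immune_signature"),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
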