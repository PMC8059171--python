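"""Shared fixtures: the small simulated dataset and its preprocessed and
scored derivatives, computed once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from paraspec.containers import RunConfig
from paraspec.preprocess import adjust_covariates, filter_genes, log_transform, region_means
from paraspec.simulate import fixture_small
from paraspec.specificity import score_specificity


@pytest.fixture(scope="session")
def fixture_data():
    """(expression raw_rpkm, samples, annotation, ground truth) at seed 1."""
    return fixture_small(1)


@pytest.fixture(scope="session")
def adjusted(fixture_data):
    expr, samples, _, _ = fixture_data
    return adjust_covariates(log_transform(filter_genes(expr, samples)), samples)


@pytest.fixture(scope="session")
def r7_means(adjusted, fixture_data):
    _, samples, _, _ = fixture_data
    return region_means(adjusted, samples, level="r7")


@pytest.fixture(scope="session")
def tau_scored(adjusted, fixture_data):
    """(tau result table, permutation null) at 200 permutations, seed 1."""
    _, samples, _, _ = fixture_data
    return score_specificity(adjusted, samples, n_permutations=200, seed=1)


@pytest.fixture(scope="session")
def config():
    return RunConfig(n_permutations=200, rng_seed=1)
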