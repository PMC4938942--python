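"""Shared fixtures: small synthetic cohorts used across the suite."""

import numpy as np
import pandas as pd
import pytest

from csdecomp import (Cohort, CohortSpec, CovariateSpec, OutcomeSpec,
                      generate_cohort)


def binary_cov(name, p_public, p_private):
    return CovariateSpec(name, "binary",
                         {"public": p_public, "private": p_private})


def make_spec(n_public, n_private, covariates, coefficients, group_effect=0.0,
              link="probit", seed=0, outcome="elcs"):
    return CohortSpec(
        n_public=n_public, n_private=n_private, covariates=tuple(covariates),
        outcomes=(OutcomeSpec(outcome, coefficients, group_effect, link),),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two binary covariates with different mixes plus a group effect."""
    spec = make_spec(
        1200, 800,
        [binary_cov("x1", 0.3, 0.6), binary_cov("x2", 0.2, 0.5)],
        {"intercept": -1.0, "x1": 0.8, "x2": 0.6},
        group_effect=0.25, seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def composition_cohort():
    """Gap driven entirely by covariate composition (shared coefficients)."""
    spec = make_spec(
        10_000, 10_000,
        [binary_cov("x1", 0.3, 0.6), binary_cov("x2", 0.2, 0.5)],
        {"intercept": -1.0, "x1": 0.8, "x2": 0.6},
        group_effect=0.0, seed=21,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def coefficient_cohort():
    """Identical covariate mixes; the gap is all group effect."""
    spec = make_spec(
        10_000, 10_000,
        [binary_cov("x1", 0.4, 0.4), binary_cov("x2", 0.3, 0.3)],
        {"intercept": -1.0, "x1": 0.8, "x2": 0.6},
        group_effect=0.3, seed=22,
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_cohort():
    """Six-row hand-built cohort: 3 public / 3 private, one binary covariate."""
    df = pd.DataFrame({
        "group": ["public"] * 3 + ["private"] * 3,
        "x": [1, 0, 1, 0, 0, 1],
        "y": [1, 0, 1, 0, 1, 0],
    })
    return Cohort(data=df, outcome_names=("y",), covariates=None, provenance=None)
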