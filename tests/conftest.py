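"""Shared fixtures: a seeded synthetic cohort and a trained classifier.

Session scope keeps the LOOCV training (the expensive step) to a single
run per test session.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import prognosig as pg

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """n=60 cohort, 250 probes, 8 informative probes on one latent factor."""
    cfg = pg.SimulationConfig(
        n_samples=60, n_probes=250, n_informative=8, effect_size=1.0, seed=5
    )
    return pg.generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared(small_cohort):
    expr, clinical, truth = small_cohort
    matrix, state = pg.prepare_training_matrix(
        expr, pg.reference_probe_set(truth)
    )
    return matrix, state


@pytest.fixture(scope="session")
def trained(small_cohort, prepared):
    """Classifier trained end to end (screen + LOOCV + rank metagenes)."""
    expr, clinical, truth = small_cohort
    matrix, state = prepared
    return pg.MetageneRiskClassifier().fit(matrix, clinical, preprocess=state)


@pytest.fixture()
def toy_survival():
    """6 subjects, one binary covariate, no ties."""
    return pg.SurvivalData(
        times=np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]),
        events=np.array([1, 0, 1, 1, 0, 1]),
        covariates=pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]}),
    )
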