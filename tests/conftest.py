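"""Shared fixtures: small recordings and cached cohort pipeline runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from motornet import CohortConfig
from motornet.model import MotorNetworkAnalysis
from motornet.recording import HemodynamicRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_recording(rng) -> HemodynamicRecording:
    """Band-unconstrained Gaussian noise, 22 channels × 120 s at 10 Hz."""
    return HemodynamicRecording(
        subject_id="noise", data=rng.standard_normal((22, 1200)), fs=10.0
    )


_COHORT_CACHE: dict[int, object] = {}


def fit_default_cohort(seed: int):
    """Full default cohort run (42 subjects, base metrics only), cached.

    Used by the group-ordering and correlation-sign recovery tests, which
    evaluate the same seeded cohorts.
    """
    if seed not in _COHORT_CACHE:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MotorNetworkAnalysis.from_synthetic(
                CohortConfig(seed=seed), n_random=0
            )
            _COHORT_CACHE[seed] = model.fit(classify=False)
    return _COHORT_CACHE[seed]


@pytest.fixture(scope="session")
def recovery_seeds() -> list[int]:
    """Master seeds for the multi-seed parameter-recovery checks."""
    return list(range(1, 11))


@pytest.fixture(scope="session")
def normalized_cohort_results():
    """Default cohort (seed 1) with γ/λ/δ at the reduced 20-reference mode.

    Shared by the small-world recovery check and the classification
    sanity check (which needs all eight AUC features).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MotorNetworkAnalysis.from_synthetic(CohortConfig(seed=1), n_random=20)
        return model.fit(classify=False, run_stats=False)
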