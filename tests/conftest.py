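"""Shared fixtures: synthetic trials, a small trained cohort, rng."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rehabmotion.assessment import AssessConfig, canonical_registry, loso_train
from rehabmotion.features import assessment_preset, extract_features
from rehabmotion.synth import SyntheticMotionSpec, generate_cohort, simulate_abduction

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_trial():
    """One noiseless hip-abduction trial with ground truth."""
    spec = SyntheticMotionSpec(noise_sd=0.0, seed=1)
    return simulate_abduction(spec)


@pytest.fixture(scope="session")
def noisy_trial():
    spec = SyntheticMotionSpec(seed=7)
    return simulate_abduction(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact labelled cohort (5 subjects x 6 trials, 25% faulted)."""
    return generate_cohort(5, 6, fault_rate=0.25, seed=3)


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    return {(t.subject_id, t.trial_id): extract_features(t.sequence, assessment_preset())
            for t in small_cohort.trials}


@pytest.fixture(scope="session")
def small_registries(small_cohort, small_cohort_features):
    """Leave-one-subject-out registries trained on the small cohort."""
    return loso_train(small_cohort_features, small_cohort.labels,
                      canonical_registry(), seed=3, config=AssessConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
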