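"""Shared fixtures: small synthetic cohorts and derived feature tables."""

import numpy as np
import pytest

import fogsense as fs
from fogsense.evaluate import cohort_feature_table


@pytest.fixture(scope="session")
def small_config() -> fs.GeneratorConfig:
    """A reduced cohort for unit tests: 4 subjects (3 freezers), 2 min each."""
    return fs.GeneratorConfig(
        n_subjects=4, n_freezers=3, recording_length=120.0, seed=7
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return fs.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def shank_table(small_cohort) -> fs.FeatureTable:
    """Left+right shank (accel+gyro) features for the small cohort."""
    cfg = fs.PipelineConfig(channels=fs.expand_subset("left_shank,right_shank"))
    recs = [r for r, _ in small_cohort]
    anns = [a for _, a in small_cohort]
    return cohort_feature_table(recs, anns, cfg)


@pytest.fixture()
def random_table() -> fs.FeatureTable:
    """Pure-noise two-class table with several subjects (no signal)."""
    rng = np.random.default_rng(42)
    n, p = 240, 12
    montage = fs.full_montage()
    feature_ids = [(montage[j], fs.FEATURE_NAMES[j % 13]) for j in range(p)]
    return fs.FeatureTable(
        rng.normal(size=(n, p)),
        feature_ids,
        (rng.random(n) < 0.25).astype(np.uint8),
        np.array([f"S{i % 4}" for i in range(n)], dtype=object),
        np.arange(n) * 0.5,
    )


def make_table(values, labels, subjects=None) -> fs.FeatureTable:
    """Build a FeatureTable from bare arrays, fabricating feature ids."""
    values = np.asarray(values, dtype=float)
    montage = fs.full_montage()
    p = values.shape[1]
    feature_ids = [(montage[j % 48], fs.FEATURE_NAMES[j // 48 % 13]) for j in range(p)]
    labels = np.asarray(labels, dtype=np.uint8)
    if subjects is None:
        subjects = np.array([f"S{i % 3}" for i in range(len(values))], dtype=object)
    return fs.FeatureTable(
        values, feature_ids, labels, np.asarray(subjects, dtype=object),
        np.arange(len(values), dtype=float),
    )
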