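"""Shared fixtures: synthetic alert-driven datasets and fitted models.

Everything is generated programmatically at test time from the simulator;
heavyweight objects (the n=400 study-condition dataset and the fingerprint
random-forest trained on it) are session-scoped so the suite pays for them
once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import skinsens as ss

warnings.filterwarnings("ignore", category=UserWarning)


#: Study conditions for the signal-recovery checks: 400 entries, 3:1
#: sensitizer imbalance, 5% label noise, generator seed 7.
STUDY_CONFIG = ss.SyntheticConfig(n=400, seed=7, label_noise=0.05, binary_ratio=3.0)


@pytest.fixture(scope="session")
def study_records():
    entries, truth = ss.simulate.simulate_library(STUDY_CONFIG)
    records = ss.simulate.assign_outcomes(entries, ss.DEFAULT_ALERTS, STUDY_CONFIG, truth)
    return records, truth


@pytest.fixture(scope="session")
def study_binary(study_records):
    """Curated binary WES dataset at the study conditions."""
    records, _ = study_records
    kept, _ = ss.standardize_records(records)
    deduped, _ = ss.resolve_duplicates(kept, "WES", level="hazard")
    return ss.assemble_binary(deduped, "WES")


@pytest.fixture(scope="session")
def study_multiclass(study_records):
    records, _ = study_records
    kept, _ = ss.standardize_records(records)
    deduped, _ = ss.resolve_duplicates(kept, "WES", level="potency")
    return ss.assemble_multiclass(deduped, "WES")


@pytest.fixture(scope="session")
def study_cv(study_binary):
    """5-fold external CV of the fingerprint random forest (seed 7)."""
    config = ss.RunConfig(
        task="binary", scheme="WES", feature_kind="ecfp4",
        algorithm="random_forest", seed=7,
    )
    return ss.crossvalidate(study_binary, config)


@pytest.fixture(scope="session")
def study_bundle(study_binary):
    """Fingerprint random forest refitted on the full study dataset."""
    config = ss.RunConfig(
        task="binary", scheme="WES", feature_kind="ecfp4",
        algorithm="random_forest", seed=7,
    )
    bundle, _ = ss.fit_bundle(study_binary, config)
    return bundle


@pytest.fixture(scope="session")
def small_records():
    """A small (n=120) synthetic table with doses, for cheap unit tests."""
    config = ss.SyntheticConfig(n=120, seed=5)
    records, truth = ss.simulate_dataset(config)
    return records, truth, config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
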