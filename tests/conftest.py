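"""Shared fixtures.

BLAS threading is pinned to one thread so that training trajectories are
bit-reproducible regardless of the host's core count.
"""

import os

os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")
os.environ.setdefault("MKL_NUM_THREADS", "1")

import numpy as np
import pytest
from hypothesis import settings
from threadpoolctl import threadpool_limits

threadpool_limits(limits=1)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from fedecg import (  # noqa: E402
    CohortSpec,
    FederationConfig,
    NetworkSpec,
    TrainingConfig,
    generate_cohort,
    shard_non_iid,
    split_by_subject,
)
from fedecg.federation import FederatedLSTMClassifier  # noqa: E402


@pytest.fixture(scope="session")
def small_cohort():
    """120-record cohort with subject structure, for cheap pipeline tests."""
    return generate_cohort(CohortSpec(n_per_class=(40, 40, 40), seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """3000-record balanced cohort for distributional checks."""
    return generate_cohort(CohortSpec(n_per_class=(1000, 1000, 1000), seed=11))


@pytest.fixture
def tiny_net():
    return NetworkSpec(lstm_units=(6, 4), dropout_rate=0.2)


@pytest.fixture
def tiny_train():
    return TrainingConfig(batch_size=16, local_epochs=2, seed=0)


@pytest.fixture(scope="session")
def e2e_run():
    """The reference full-scale federated simulation.

    Default cohort (1500 records per class), 67/33 subject-level split,
    10 non-IID clients (label skew 0.5), per-client SMOTE, 15 communication
    rounds of 15 local epochs with Adam at lr 0.001 and batch 32, seed 0.
    Shared across tests because it takes several minutes.
    """
    cohort = generate_cohort(CohortSpec(seed=0))
    train, test = split_by_subject(cohort, 0.33, seed=0)
    shards = shard_non_iid(train, n_clients=10, label_skew=0.5,
                           size_skew=5.0, seed=0)
    est = FederatedLSTMClassifier(
        fed_config=FederationConfig(rounds=15, seed=0)
    )
    est.fit(shards, eval_set=test)
    return {"est": est, "train": train, "test": test, "shards": shards,
            "cohort": cohort}
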