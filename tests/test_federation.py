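"""FedAvg aggregation algebra, the round loop, and federated cross-validation."""

import numpy as np
import pytest

import fedecg.federation as federation
from fedecg.cohort import ClientShard, CohortSpec, generate_cohort, shard_non_iid
from fedecg.features import FeatureMatrix
from fedecg.federation import (
    FederatedLSTMClassifier,
    FederationConfig,
    aggregate_fedavg,
    federated_kfold,
    run_rounds,
)
from fedecg.lstm import (
    LSTMClassifier,
    ModelParameters,
    NetworkSpec,
    TrainingConfig,
    initialize_parameters,
)


def _scalar_params(*vals):
    return [ModelParameters([("w", np.array([float(v)]))]) for v in vals]


class TestAggregation:
    def test_idempotent_on_identical_clients(self):
        theta = initialize_parameters(NetworkSpec(lstm_units=(4,)), seed=0)
        for sizes in (None, [3, 5, 7]):
            agg = aggregate_fedavg([theta, theta, theta], sizes)
            np.testing.assert_allclose(agg.flatten(), theta.flatten(),
                                       atol=1e-15)

    def test_uniform_and_weighted_means(self):
        a, b = _scalar_params(2, 4)
        assert aggregate_fedavg([a, b]).flatten()[0] == pytest.approx(3.0)
        assert aggregate_fedavg([a, b], [1, 3]).flatten()[0] == pytest.approx(3.5)

    def test_opposite_parameters_cancel_exactly(self):
        theta = initialize_parameters(NetworkSpec(lstm_units=(3,)), seed=1)
        neg = theta.unflatten(-theta.flatten())
        agg = aggregate_fedavg([theta, neg, theta, neg])
        assert np.all(agg.flatten() == 0.0)

    def test_uniform_permutation_invariant(self):
        ps = _scalar_params(1, 2, 7, -3)
        f = aggregate_fedavg(ps).flatten()
        g = aggregate_fedavg(ps[::-1]).flatten()
        np.testing.assert_array_equal(f, g)

    def test_equal_sizes_reduce_to_uniform(self):
        ps = _scalar_params(1.5, -2.5, 4.0)
        np.testing.assert_allclose(
            aggregate_fedavg(ps, [5, 5, 5]).flatten(),
            aggregate_fedavg(ps).flatten(), atol=1e-15,
        )

    def test_registry_mismatch_and_empty_rejected(self):
        a = initialize_parameters(NetworkSpec(lstm_units=(3,)), seed=0)
        b = initialize_parameters(NetworkSpec(lstm_units=(4,)), seed=0)
        with pytest.raises(ValueError, match="registr"):
            aggregate_fedavg([a, b])
        with pytest.raises(ValueError):
            aggregate_fedavg([])
        with pytest.raises(ValueError):
            aggregate_fedavg([a, a], [1, -1])


def _mini_setup(seed=0, n_clients=3):
    cohort = generate_cohort(CohortSpec(n_per_class=(60, 60, 60), seed=seed))
    from fedecg.cohort import split_by_subject
    train, test = split_by_subject(cohort, 0.33, seed=seed)
    shards = shard_non_iid(train, n_clients, label_skew=1.0, seed=seed)
    return shards, test


class TestRoundLoop:
    def test_zero_rounds_returns_initial_model(self):
        shards, test = _mini_setup()
        fed = FederationConfig(n_clients=3, rounds=0, seed=4)
        est, history = run_rounds(
            shards, NetworkSpec(lstm_units=(5,)), TrainingConfig(local_epochs=1),
            fed, test,
        )
        assert history == []
        init = initialize_parameters(NetworkSpec(lstm_units=(5,)), seed=4)
        np.testing.assert_array_equal(
            est.global_model_.get_weights().flatten(), init.flatten()
        )

    def test_single_client_round_equals_local_training(self):
        """With one client and one round, FedAvg returns that client's
        locally trained parameters."""
        shards, test = _mini_setup(n_clients=1)
        spec = NetworkSpec(lstm_units=(6,))
        fed = FederationConfig(n_clients=1, rounds=1, smote=False, seed=3)
        tcfg = TrainingConfig(local_epochs=2, seed=10)
        est, _ = run_rounds(shards, spec, tcfg, fed, test)

        init = initialize_parameters(spec, fed.seed)
        clf = LSTMClassifier(lstm_units=spec.lstm_units,
                             dropout_rate=spec.dropout_rate).set_weights(init)
        # same derived per-client seed the round loop uses (round 1, client 0)
        replay_cfg = TrainingConfig(local_epochs=2, seed=10 + 0 + 100003 * 1)
        from fedecg.features import FeatureScaler
        scaler = FeatureScaler().fit(shards[0].data)
        Xs = scaler.transform(shards[0].data)
        clf.fit(Xs, shards[0].data.labels, init_params=init, config=replay_cfg)
        np.testing.assert_array_equal(
            est.global_model_.get_weights().flatten(),
            clf.get_weights().flatten(),
        )

    def test_round_record_identities(self):
        shards, test = _mini_setup(seed=2)
        fed = FederationConfig(n_clients=3, rounds=2, seed=2)
        est, history = run_rounds(
            shards, NetworkSpec(lstm_units=(6, 4)),
            TrainingConfig(local_epochs=1), fed, test,
        )
        assert len(history) == 2
        for rec in history:
            assert rec.mc_rate == pytest.approx(1.0 - rec.accuracy, abs=1e-15)
            assert rec.recall == pytest.approx(rec.accuracy, abs=1e-12)
            for v in (rec.accuracy, rec.f1, rec.fnr, rec.fpr, rec.mc_rate,
                      rec.precision, rec.recall):
                assert 0.0 <= v <= 1.0
            assert rec.loss >= 0.0
        assert list(est.history_frame().columns) == federation.HISTORY_COLUMNS

    def test_leakage_detection(self):
        shards, test = _mini_setup(seed=5)
        leaky = ClientShard(0, test.take(np.arange(5)))
        with pytest.raises(ValueError, match="leakage"):
            FederatedLSTMClassifier(
                NetworkSpec(lstm_units=(4,)), TrainingConfig(local_epochs=0),
                FederationConfig(n_clients=1, rounds=0),
            ).fit([leaky], eval_set=test)

    def test_only_parameters_cross_the_client_boundary(self, monkeypatch):
        """The server aggregation sees ModelParameters (and sizes) only,
        never feature matrices."""
        seen = []
        original = federation.aggregate_fedavg

        def spy(params_list, sizes=None):
            seen.append((list(params_list), sizes))
            return original(params_list, sizes)

        monkeypatch.setattr(federation, "aggregate_fedavg", spy)
        shards, test = _mini_setup(seed=6)
        run_rounds(shards, NetworkSpec(lstm_units=(4,)),
                   TrainingConfig(local_epochs=1),
                   FederationConfig(n_clients=3, rounds=2, seed=6), test)
        assert len(seen) == 2
        for params_list, _ in seen:
            assert all(isinstance(p, ModelParameters) for p in params_list)
            assert not any(isinstance(p, (FeatureMatrix, np.ndarray))
                           for p in params_list)

    def test_size_weighted_mode_runs(self):
        shards, test = _mini_setup(seed=7)
        fed = FederationConfig(n_clients=3, rounds=1, aggregation="size_weighted",
                               seed=7)
        _, history = run_rounds(shards, NetworkSpec(lstm_units=(4,)),
                                TrainingConfig(local_epochs=1), fed, test)
        assert len(history) == 1


class TestFederatedKfold:
    def test_every_record_in_exactly_one_fold(self):
        data = generate_cohort(CohortSpec(n_per_class=(40, 40, 40), seed=8))
        table, summary = federated_kfold(
            data, k=3, net_spec=NetworkSpec(lstm_units=(5,)),
            train_config=TrainingConfig(local_epochs=1),
            fed_config=FederationConfig(n_clients=2, rounds=1, seed=8),
        )
        assert len(table) == 3
        assert {"mean", "sd"} == set(summary.columns)
        assert table["accuracy"].between(0, 1).all()
        # partition property: the test folds cover the dataset exactly once
        assert table["n_test"].sum() == data.n

    def test_leave_one_out_boundary(self):
        data = generate_cohort(
            CohortSpec(n_per_class=(4, 4, 4), records_per_subject=1, seed=10)
        )
        table, _ = federated_kfold(
            data, k=data.n, net_spec=NetworkSpec(lstm_units=(2,)),
            train_config=TrainingConfig(local_epochs=0),
            fed_config=FederationConfig(n_clients=2, rounds=1, smote=False,
                                        seed=10),
        )
        assert len(table) == data.n

    def test_k_exceeding_subjects_raises(self):
        data = generate_cohort(CohortSpec(n_per_class=(20, 20, 20), seed=11))
        n_subjects = len(np.unique(data.subject_ids))
        with pytest.raises(ValueError, match="subjects"):
            federated_kfold(data, k=n_subjects + 1)
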