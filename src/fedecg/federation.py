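"""Server-side orchestration: FedAvg aggregation, the communication-round
loop, and the federated cross-validation protocol.

The simulation is single-process: clients are in-memory actors, and the only
state that crosses the client boundary is the parameter registry (plus the
18 scalar standardisation statistics the server averages to build its
evaluation scaler).  Each communication round broadcasts the global
parameters, runs every client's local training from them, aggregates the
returned registries (uniform mean by default, dataset-size-weighted
optionally), and scores the new global model on the held-out test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ClientShard, shard_non_iid
from .features import FeatureMatrix, FeatureScaler, average_scalers
from .lstm import (
    LSTMClassifier,
    ModelParameters,
    NetworkSpec,
    TrainingConfig,
    initialize_parameters,
)
from .metrics import classification_metrics, confusion_matrix, roc_auc_ovr
from .rebalance import smote_oversample

__all__ = [
    "FederationConfig", "RoundRecord", "aggregate_fedavg",
    "FederatedLSTMClassifier", "run_rounds", "federated_kfold",
]

HISTORY_COLUMNS = [
    "Round", "Accuracy", "F1 Score", "FNR", "FPR", "Loss", "MC Rate",
    "Precision", "Recall",
]


@dataclass
class FederationConfig:
    """Federation hyperparameters.

    All clients participate in every round.  ``aggregation`` is ``uniform``
    (plain elementwise mean of client parameters) or ``size_weighted``
    (weights |D_i| / |D|).  Sharding and per-client SMOTE settings live here
    because cross-validation needs to re-shard inside each fold.
    """

    n_clients: int = 10
    rounds: int = 15
    aggregation: str = "uniform"
    label_skew: float = 0.5
    size_skew: float = 5.0
    smote: bool = True
    smote_k: int = 5
    record_round_zero: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_clients < 1:
            raise ValueError("n_clients must be >= 1")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.aggregation not in ("uniform", "size_weighted"):
            raise ValueError("aggregation must be 'uniform' or 'size_weighted'")


@dataclass
class RoundRecord:
    """Per-communication-round held-out metrics (one history row)."""

    round: int
    accuracy: float
    f1: float
    fnr: float
    fpr: float
    loss: float
    mc_rate: float
    precision: float
    recall: float
    auc: float | None = None

    def as_row(self) -> dict:
        return {
            "Round": self.round, "Accuracy": self.accuracy, "F1 Score": self.f1,
            "FNR": self.fnr, "FPR": self.fpr, "Loss": self.loss,
            "MC Rate": self.mc_rate, "Precision": self.precision,
            "Recall": self.recall,
        }


def aggregate_fedavg(
    params_list: Sequence[ModelParameters],
    sizes: Sequence[int] | None = None,
) -> ModelParameters:
    """Federated averaging of client parameter registries.

    With ``sizes`` None this is the plain mean ``(1/N) sum theta_i``; with
    sizes it is the dataset-size-weighted mean ``sum (|D_i|/|D|) theta_i``.
    """
    params_list = list(params_list)
    if not params_list:
        raise ValueError("no client parameters to aggregate")
    ref = params_list[0]
    for p in params_list[1:]:
        if not ref.same_registry(p):
            raise ValueError("client parameter registries differ in shape/order")
    if sizes is None:
        w = np.full(len(params_list), 1.0 / len(params_list))
    else:
        sizes = np.asarray(list(sizes), dtype=float)
        if sizes.shape[0] != len(params_list) or np.any(sizes <= 0):
            raise ValueError("sizes must be positive, one per client")
        w = sizes / sizes.sum()
    stacked = np.stack([p.flatten() for p in params_list])
    return ref.unflatten(w @ stacked)


def _check_disjoint(shards: Sequence[ClientShard], test_set: FeatureMatrix) -> None:
    if test_set.subject_ids is None:
        return
    test_subjects = set(np.unique(test_set.subject_ids).tolist())
    test_subjects.discard("synthetic")
    for shard in shards:
        if shard.data.subject_ids is None:
            continue
        overlap = test_subjects.intersection(shard.data.subject_ids.tolist())
        if overlap:
            raise ValueError(
                f"leakage: subject(s) {sorted(overlap)[:3]} appear in both "
                f"client {shard.client_id} and the test set"
            )


class FederatedLSTMClassifier:
    """FedAvg-trained LSTM over simulated institutions.

    ``fit(shards, eval_set=...)`` consumes a list of :class:`ClientShard`
    (each an institution's private labelled data) rather than a pooled
    ``(X, y)`` — pooling is exactly what federation avoids.  After fitting,
    ``global_model_`` is the aggregated :class:`LSTMClassifier`,
    ``scaler_`` the server-side evaluation scaler, and ``history_`` the
    per-round held-out metric records.
    """

    def __init__(
        self,
        net_spec: NetworkSpec | None = None,
        train_config: TrainingConfig | None = None,
        fed_config: FederationConfig | None = None,
    ):
        self.net_spec = net_spec or NetworkSpec()
        self.train_config = train_config or TrainingConfig()
        self.fed_config = fed_config or FederationConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {
            "net_spec": self.net_spec, "train_config": self.train_config,
            "fed_config": self.fed_config,
        }

    def set_params(self, **kw) -> "FederatedLSTMClassifier":
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    # -- client-side preparation (local, private) -------------------------
    def _prepare_clients(self, shards: Sequence[ClientShard]):
        fed = self.fed_config
        prepared = []
        for shard in shards:
            local = shard.data
            if fed.smote and len(np.unique(local.labels)) > 1:
                counts = local.class_counts()
                # oversample only classes with >=2 records; singletons stay
                target = {
                    c: int(counts.max()) for c in range(len(counts))
                    if counts[c] >= 2
                }
                local = smote_oversample(
                    local, k_neighbors=fed.smote_k, target=target,
                    seed=fed.seed + shard.client_id,
                )
            if local.n >= 2:
                scaler = FeatureScaler().fit(local)
            else:
                scaler = FeatureScaler()
                scaler.mean_ = np.zeros(local.values.shape[1])
                scaler.scale_ = np.ones(local.values.shape[1])
                scaler.n_samples_seen_ = local.n
            X = scaler.transform(local)
            prepared.append(
                {"client_id": shard.client_id, "X": X, "y": local.labels,
                 "scaler": scaler, "size": local.n}
            )
        return prepared

    def _evaluate(self, model: LSTMClassifier, scaler: FeatureScaler,
                  test_set: FeatureMatrix, round_index: int) -> RoundRecord:
        Xs = scaler.transform(test_set)
        probs = model.predict_proba(Xs)
        pred = np.argmax(probs, axis=1)
        cm = confusion_matrix(test_set.labels, pred)
        losses = -np.log(probs[np.arange(test_set.n), test_set.labels] + 1e-12)
        row = classification_metrics(cm, losses=losses)
        auc = roc_auc_ovr(test_set.labels, probs)["macro"]
        return RoundRecord(
            round=round_index, accuracy=row.accuracy, f1=row.f1, fnr=row.fnr,
            fpr=row.fpr, loss=row.loss, mc_rate=row.mc_rate,
            precision=row.precision, recall=row.recall, auc=auc,
        )

    def fit(self, shards: Sequence[ClientShard],
            eval_set: FeatureMatrix | None = None) -> "FederatedLSTMClassifier":
        fed = self.fed_config
        fed.validate()
        self.train_config.validate()
        shards = list(shards)
        if not shards:
            raise ValueError("need at least one client shard")
        if eval_set is not None:
            _check_disjoint(shards, eval_set)

        clients = self._prepare_clients(shards)
        sizes = [c["size"] for c in clients]
        self.scaler_ = average_scalers([c["scaler"] for c in clients], sizes)

        global_params = initialize_parameters(self.net_spec, fed.seed)
        template = LSTMClassifier(
            lstm_units=self.net_spec.lstm_units,
            dropout_rate=self.net_spec.dropout_rate,
            n_classes=self.net_spec.n_classes,
        )
        self.history_ = []
        self.client_losses_ = []

        def eval_round(params: ModelParameters, r: int) -> None:
            if eval_set is None:
                return
            model = template.set_weights(params)
            self.history_.append(self._evaluate(model, self.scaler_, eval_set, r))

        if fed.record_round_zero:
            eval_round(global_params, 0)

        for r in range(1, fed.rounds + 1):
            round_params: list[ModelParameters] = []
            round_losses = []
            for c in clients:
                cfg = TrainingConfig(
                    batch_size=self.train_config.batch_size,
                    local_epochs=self.train_config.local_epochs,
                    learning_rate=self.train_config.learning_rate,
                    optimizer=self.train_config.optimizer,
                    seed=self.train_config.seed + c["client_id"] + 100003 * r,
                )
                clf = template.set_weights(global_params)
                if cfg.local_epochs > 0:
                    clf.fit(c["X"], c["y"], init_params=global_params, config=cfg)
                    round_losses.append(clf.final_loss_)
                round_params.append(clf.get_weights())
            global_params = aggregate_fedavg(
                round_params,
                sizes if fed.aggregation == "size_weighted" else None,
            )
            self.client_losses_.append(round_losses)
            eval_round(global_params, r)

        self.global_model_ = template.set_weights(global_params)
        self.client_sizes_ = sizes
        return self

    # -- inference through the aggregated global model --------------------
    def predict_proba(self, data: FeatureMatrix | np.ndarray) -> np.ndarray:
        X = self.scaler_.transform(data)
        return self.global_model_.predict_proba(X)

    def predict(self, data) -> np.ndarray:
        return np.argmax(self.predict_proba(data), axis=1)

    def score(self, data: FeatureMatrix) -> float:
        return float(np.mean(self.predict(data) == data.labels))

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_row() for r in self.history_],
                            columns=HISTORY_COLUMNS)


def run_rounds(
    shards: Sequence[ClientShard],
    net_spec: NetworkSpec | None = None,
    train_config: TrainingConfig | None = None,
    fed_config: FederationConfig | None = None,
    test_set: FeatureMatrix | None = None,
) -> tuple[FederatedLSTMClassifier, list[RoundRecord]]:
    """Run the full communication-round loop; returns the fitted federated
    estimator and its per-round history."""
    est = FederatedLSTMClassifier(net_spec, train_config, fed_config)
    est.fit(shards, eval_set=test_set)
    return est, est.history_


def federated_kfold(
    data: FeatureMatrix,
    k: int = 10,
    net_spec: NetworkSpec | None = None,
    train_config: TrainingConfig | None = None,
    fed_config: FederationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subject-grouped federated k-fold cross-validation.

    Folds are built over subjects so no subject straddles folds.  For each
    fold the remaining data is sharded non-IID, federated training runs, and
    the held-out fold is scored with the final global model.  Returns the
    per-fold metric table and a mean/sd summary.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.subject_ids is None:
        raise ValueError("federated_kfold requires subject_ids")
    fed = fed_config or FederationConfig()
    subjects = np.unique(data.subject_ids)
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds number of subjects ({len(subjects)})")
    rng = np.random.default_rng(fed.seed)
    rng.shuffle(subjects)
    fold_of_subject = {s: i % k for i, s in enumerate(subjects)}
    fold_idx = np.array([fold_of_subject[s] for s in data.subject_ids])

    rows = []
    for fold in range(k):
        test = data.take(np.flatnonzero(fold_idx == fold))
        train = data.take(np.flatnonzero(fold_idx != fold))
        shards = shard_non_iid(
            train, n_clients=fed.n_clients, label_skew=fed.label_skew,
            size_skew=fed.size_skew, seed=fed.seed + fold,
        )
        est = FederatedLSTMClassifier(net_spec, train_config, fed)
        est.fit(shards, eval_set=test)
        rec = est.history_[-1]
        rows.append({"fold": fold, "n_test": test.n,
                     **{k_.lower(): v for k_, v in
                        rec.as_row().items() if k_ != "Round"},
                     "auc": rec.auc})
    table = pd.DataFrame(rows)
    metric_cols = [c for c in table.columns if c not in ("fold", "n_test")]
    summary = pd.DataFrame({"mean": table[metric_cols].mean(),
                            "sd": table[metric_cols].std(ddof=1)})
    return table, summary
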