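"""Classifier training harness: normalization, trace-recording trainers,
the logistic-regression + RFE comparator, and the end-to-end experiment.

The trainers are deliberately small: a multilayer perceptron (or plain
logistic SGD when ``hidden_layers=0``) driven one minibatch at a time so
that a full :class:`~ceilstop.trace.TrainingTrace` — loss and accuracy on
every partition, every epoch — is recorded. The toolkit decides *epochs*;
callers that need the weights of a particular epoch should checkpoint in
their own framework.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier

from .stopping import CeilingSpec, RuleParams, establish_ceiling, stop_ceiling, apply_named_rules
from .synthgen import PairedDataset, PopulationSpec, sample_paired_dataset, split_grouped
from .trace import EpochRecord, StopDecision, TrainingTrace, oracle_epoch

__all__ = [
    "TrainConfig",
    "FeatureScaler",
    "FittedModel",
    "ExperimentResult",
    "normalize_features",
    "train_classifier",
    "rfe_logistic",
    "run_experiment",
    "DEFAULT_RULES",
]

#: Registry rules applied by :func:`run_experiment` (the ceiling rule is
#: added separately with the measured ceiling).
DEFAULT_RULES = ["gl", "pq3", "pq6", "patience3", "patience6", "dk"]


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the trace-recording trainer.

    Defaults follow a small tabular protocol: six hidden layers, batch
    size 32, learning rate 0.01 under Adam, binary cross-entropy, 2000
    epochs. ``hidden_layers=0`` degenerates to logistic regression fit by
    minibatch SGD. Hidden width is not part of the protocol; 32 is a
    reasonable default for feature vectors of a dozen dimensions.
    """

    hidden_layers: int = 6
    hidden_width: int = 32
    batch_size: int = 32
    learning_rate: float = 0.01
    epochs: int = 2000
    seed: int = 0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")
        if min(self.hidden_width, self.batch_size, self.epochs) < 1:
            raise ValueError("hidden_width, batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class FeatureScaler:
    """Frozen per-feature affine scaler fit on the training partition."""

    mean: np.ndarray
    scale: np.ndarray  # SD with zeros replaced by 1, so constant features map to 0

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class FittedModel:
    """A trained classifier plus its provenance."""

    kind: str  # "mlp" or "logistic"
    model: Any
    scaler: Optional[FeatureScaler] = None
    selected_features: Optional[tuple[int, ...]] = None
    trace: Optional[TrainingTrace] = None
    metrics: Mapping[str, float] = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is not None:
            X = self.scaler.transform(X)
        if self.selected_features is not None:
            X = X[:, list(self.selected_features)]
        return self.model.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def normalize_features(
    train_features: np.ndarray, *other_features: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray], FeatureScaler]:
    """Standardize features to the training set's mean and SD.

    The scaler is fit on the training partition only and then applied,
    frozen, to every other partition — no statistic of the validation or
    test data leaks into the transform. Features with zero training SD
    map to 0.
    """
    train_features = np.asarray(train_features, dtype=float)
    if train_features.size == 0:
        raise ValueError("training feature matrix is empty")
    mean = train_features.mean(axis=0)
    sd = train_features.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    scaler = FeatureScaler(mean=mean, scale=scale)
    return scaler.transform(train_features), [scaler.transform(np.asarray(x, float)) for x in other_features], scaler


def _partition_arrays(
    data: PairedDataset, channel: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for part in ("train", "val", "test_subset", "test_novel"):
        df = data.subset(part)
        if len(df):
            out[part] = (
                df[data.channel_columns(channel)].to_numpy(dtype=float),
                df["label"].to_numpy(dtype=int),
            )
    return out


def _bce(model, X: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(X)
    return float(log_loss(y, p, labels=[0, 1]))


def _acc(model, X: np.ndarray, y: np.ndarray) -> float:
    p = model.predict_proba(X)[:, 1]
    return float(np.mean((p >= 0.5) == y))


def train_classifier(
    data: PairedDataset, channel: str, config: TrainConfig = TrainConfig()
) -> tuple[FittedModel, TrainingTrace]:
    """Train a classifier on one channel, recording a full training trace.

    The network is a ReLU MLP optimized by Adam on binary cross-entropy,
    stepped one shuffled minibatch at a time so that loss and accuracy on
    every available partition are evaluated after each epoch. The
    ``combined`` channel concatenates direct and indirect features.
    Deterministic given ``config.seed``.
    """
    parts = _partition_arrays(data, channel)
    if "train" not in parts or "val" not in parts:
        raise ValueError("dataset must have non-empty train and val partitions")
    X_train, y_train = parts["train"]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training partition contains a single class")

    scaler = None
    if config.normalize:
        X_train, others, scaler = normalize_features(
            X_train, *(parts[p][0] for p in parts if p != "train")
        )
        for name, Xn in zip((p for p in parts if p != "train"), others):
            parts[name] = (Xn, parts[name][1])
        parts["train"] = (X_train, y_train)

    rng = np.random.default_rng(config.seed)
    init_seed = int(rng.integers(2**31 - 1))
    if config.hidden_layers >= 1:
        kind = "mlp"
        model = MLPClassifier(
            hidden_layer_sizes=(config.hidden_width,) * config.hidden_layers,
            activation="relu",
            solver="adam",
            learning_rate_init=config.learning_rate,
            max_iter=1,
            random_state=init_seed,
        )
    else:
        kind = "logistic"
        model = SGDClassifier(
            loss="log_loss",
            penalty=None,
            learning_rate="constant",
            eta0=config.learning_rate,
            random_state=init_seed,
        )

    n = len(y_train)
    records = []
    classes = np.array([0, 1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for epoch in range(1, config.epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                model.partial_fit(X_train[batch], y_train[batch], classes=classes)
            rec = EpochRecord(
                epoch=epoch,
                train_loss=_bce(model, X_train, y_train),
                val_loss=_bce(model, *parts["val"]),
                train_acc=_acc(model, X_train, y_train),
                val_acc=_acc(model, *parts["val"]),
                test_acc_subset=(
                    _acc(model, *parts["test_subset"]) if "test_subset" in parts else None
                ),
                test_acc_novel=(
                    _acc(model, *parts["test_novel"]) if "test_novel" in parts else None
                ),
            )
            records.append(rec)
    trace = TrainingTrace(
        tuple(records),
        {"channel": channel, "seed": config.seed, "kind": kind},
    )
    fitted = FittedModel(kind=kind, model=model, scaler=scaler, trace=trace)
    return fitted, trace


def rfe_logistic(data: PairedDataset, channel: str = "direct") -> FittedModel:
    """Logistic regression with recursive feature elimination.

    Features are standardized on the training partition; RFE then ranks
    features by iteratively dropping the one with the smallest absolute
    coefficient. For each candidate feature count the top-ranked subset is
    refit and scored on the validation partition; the count with the best
    validation accuracy wins, ties going to fewer features. The returned
    model's ``metrics`` carry validation and (where present) test
    accuracies.
    """
    parts = _partition_arrays(data, channel)
    if "train" not in parts or "val" not in parts:
        raise ValueError("dataset must have non-empty train and val partitions")
    X_train, y_train = parts["train"]
    p = X_train.shape[1]
    if p < 2:
        raise ValueError("RFE needs at least 2 features")
    X_train, others, scaler = normalize_features(
        X_train, *(parts[q][0] for q in parts if q != "train")
    )
    scaled = dict(zip((q for q in parts if q != "train"), others))
    scaled["train"] = X_train

    base = LogisticRegression(max_iter=2000)
    ranker = RFE(base, n_features_to_select=1, step=1)
    ranker.fit(X_train, y_train)
    # ranking_ == 1 is the last-surviving feature; rank r joins the model
    # when keeping the top-r features.
    order = np.argsort(ranker.ranking_)

    best = None  # (val_acc, -n_features, features, model)
    X_val, y_val = scaled["val"], parts["val"][1]
    for n_keep in range(1, p + 1):
        feats = np.sort(order[:n_keep])
        m = LogisticRegression(max_iter=2000)
        m.fit(X_train[:, feats], y_train)
        val_acc = float(np.mean(m.predict(X_val[:, feats]) == y_val))
        key = (val_acc, -n_keep)
        if best is None or key > best[0]:
            best = (key, feats, m)
    (val_acc, neg_n), feats, model = best
    metrics = {"val_acc": val_acc, "n_features": int(-neg_n)}
    for part in ("test_subset", "test_novel"):
        if part in scaled:
            Xp, yp = scaled[part], parts[part][1]
            metrics[f"{part}_acc"] = float(np.mean(model.predict(Xp[:, feats]) == yp))
    return FittedModel(
        kind="logistic",
        model=model,
        scaler=scaler,
        selected_features=tuple(int(f) for f in feats),
        metrics=metrics,
    )


@dataclass
class ExperimentResult:
    """Everything :func:`run_experiment` produces."""

    data: PairedDataset
    direct_model: FittedModel
    direct_trace: TrainingTrace
    indirect_model: FittedModel
    indirect_trace: TrainingTrace
    comparator: FittedModel
    ceiling: CeilingSpec
    decisions: list[StopDecision]
    report: "pd.DataFrame"  # noqa: F821 — evaluate builds it; annotated lazily


def split_study(
    data: PairedDataset,
    record_fractions: tuple[float, float, float] = (0.80, 0.16, 0.04),
    novel_subject_fraction: float = 0.25,
    seed: int = 0,
) -> PairedDataset:
    """Two-stage study split producing both test flavours.

    First a subject-level hold-out (``novel_subject_fraction`` of subjects
    per class) is tagged ``test_novel`` — those subjects contribute no
    records anywhere else. The remaining records are then split
    record-wise into train/val/``test_subset`` by ``record_fractions``.
    """
    if not 0 < novel_subject_fraction < 1:
        raise ValueError("novel_subject_fraction must lie in (0, 1)")
    # Stage 1: subject-level carve-out. Reuse the grouped splitter with the
    # novel fraction as its "test" share, then re-split its train+val pool.
    rest = 1.0 - novel_subject_fraction
    staged = split_grouped(
        data,
        (rest * 0.8, rest * 0.2, novel_subject_fraction),
        mode="subject",
        seed=seed,
    )
    pool_mask = staged.frame["partition"] != "test_novel"
    pool = PairedDataset(
        staged.frame[pool_mask].reset_index(drop=True), data.dim, data.k, data.spec
    )
    pool_split = split_grouped(pool, record_fractions, mode="record", seed=seed + 1)
    out = staged.frame.copy()
    out.loc[pool_mask, "partition"] = pool_split.frame["partition"].to_numpy()
    return PairedDataset(out, data.dim, data.k, data.spec)


def run_experiment(
    spec: PopulationSpec,
    config: TrainConfig = TrainConfig(),
    rules: Sequence[str] = tuple(DEFAULT_RULES),
    rule_params: RuleParams = RuleParams(),
    ceiling_margin: float = 0.0,
    novel_subject_fraction: float = 0.25,
    outdir: Optional[str] = None,
) -> ExperimentResult:
    """End-to-end pipeline: sample, split, train both channels, establish
    the ceiling from the direct channel, and score every stopping rule on
    the indirect trace.

    Stages: (1) sample a paired dataset; (2) split with a subject-level
    novel-test hold-out plus a record-level train/val/test_subset split;
    (3) train the direct-channel model and read off its novel-test
    accuracy at the epoch of minimum validation loss; (4) corroborate with
    the logistic+RFE comparator and build a :class:`CeilingSpec`;
    (5) train the indirect-channel model recording its full trace;
    (6) apply every requested rule plus the ceiling rule post hoc and
    assemble the comparison report. Deterministic for fixed spec+config.
    """
    from . import evaluate  # local import to avoid a cycle

    data = sample_paired_dataset(spec)
    data = split_study(data, novel_subject_fraction=novel_subject_fraction, seed=spec.seed)

    direct_model, direct_trace = train_classifier(data, "direct", config)
    best = oracle_epoch(direct_trace)
    direct_acc = direct_trace[best - 1].test_acc_novel
    if direct_acc is None:
        raise RuntimeError("direct trace lacks novel-test accuracy")

    comparator = rfe_logistic(data, "direct")
    comparator_acc = comparator.metrics.get("test_novel_acc", comparator.metrics["val_acc"])
    ceiling = establish_ceiling(
        direct_acc,
        comparator_acc,
        tolerance=0.02,
        margin=ceiling_margin,
        provenance="direct-channel novel-subject test accuracy at the min-val-loss epoch",
    )

    indirect_model, indirect_trace = train_classifier(data, "indirect", config)

    params = replace(rule_params, ceiling=ceiling.value, ceiling_margin=ceiling.margin)
    decisions = apply_named_rules(indirect_trace, list(rules), params)
    decisions.append(stop_ceiling(indirect_trace, params))
    report = evaluate.compare_rules(indirect_trace, decisions, ceiling)

    result = ExperimentResult(
        data=data,
        direct_model=direct_model,
        direct_trace=direct_trace,
        indirect_model=indirect_model,
        indirect_trace=indirect_trace,
        comparator=comparator,
        ceiling=ceiling,
        decisions=decisions,
        report=report,
    )
    if outdir is not None:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(result: ExperimentResult, outdir: str) -> None:
    from pathlib import Path

    from .trace import write_trace
    from .evaluate import write_report

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.data.to_csv(out / "dataset.csv")
    write_trace(result.direct_trace, out / "trace_direct.csv")
    write_trace(result.indirect_trace, out / "trace_indirect.csv")
    write_report(result.report, out / "report.csv", ceiling=result.ceiling)
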