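"""Six-class chest-movement LSTM: training, evaluation, LOSO cross-validation.

The network mirrors a compact sequence classifier: sequence input with 3
channels (one per accelerometer axis), a first LSTM layer of 20 hidden units,
a dropout layer (p = 0.1), a second LSTM layer of 30 hidden units whose last
output feeds a dense softmax over the six movement classes.  Training uses
cross-entropy loss and stochastic gradient descent with momentum
(learning rate 0.001, momentum 0.9, mini-batch 30, 300 epochs, no early
stopping).  Leave-one-subject-out (LOSO) cross-validation holds out each
subject in turn and averages fold accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import LstmNet, SgdMomentum
from .preprocess import FeatureSequence
from .signal_synth import ACTIVITY_LABELS

__all__ = [
    "LstmConfig",
    "TrainedClassifier",
    "ConfusionMatrix",
    "LosoResult",
    "train",
    "predict",
    "evaluate",
    "loso_cv",
    "save_model",
    "load_model",
]


@dataclass
class LstmConfig:
    """Hyperparameters of the movement classifier."""

    input_channels: int = 3
    hidden1: int = 20
    hidden2: int = 30
    dropout_p: float = 0.1
    n_classes: int = 6
    minibatch: int = 30
    max_epochs: int = 300
    learning_rate: float = 0.001
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_channels", "hidden1", "hidden2", "n_classes", "minibatch", "max_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class TrainedClassifier:
    """A trained network plus the feature standardization fitted on its training set."""

    net: LstmNet
    config: LstmConfig
    classes: tuple[str, ...]
    feat_mean: np.ndarray  # (T, C) per-bin, per-axis mean of the training features
    feat_sd: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feat_mean) / self.feat_sd


@dataclass
class ConfusionMatrix:
    """6x6 counts; rows are predicted classes, columns actual classes."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


@dataclass
class LosoResult:
    """Per-held-out-subject accuracies and confusion matrices."""

    subjects: tuple[str, ...]
    fold_accuracies: tuple[float, ...]
    fold_confusions: tuple[ConfusionMatrix, ...]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def _stack_features(features: list[FeatureSequence]) -> np.ndarray:
    arrs = [np.asarray(f.spectra, dtype=float) for f in features]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"feature sequences have mixed shapes: {shapes}")
    return np.stack(arrs)


def _encode_labels(labels, classes: tuple[str, ...]) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([idx[l] for l in labels], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; expected one of {classes}") from None


def train(
    features: list[FeatureSequence],
    labels,
    config: LstmConfig | None = None,
    classes: tuple[str, ...] = ACTIVITY_LABELS,
) -> TrainedClassifier:
    """Train the LSTM on spectral feature sequences.

    Features are standardized per (frequency-bin, axis) using training-set
    statistics, stored with the model so inference applies the same scaling.
    Deterministic given ``config.seed``: shuffling, weight initialization and
    dropout masks all derive from it.  The returned history holds per-epoch
    mean mini-batch loss and mini-batch accuracy as observed during training
    (dropout active).
    """
    if config is None:
        config = LstmConfig()
    X = _stack_features(features)
    y = _encode_labels(labels, classes)
    if len(X) != len(y):
        raise ValueError("features and labels must have equal length")
    if X.shape[2] != config.input_channels:
        raise ValueError(f"expected {config.input_channels} channels, got {X.shape[2]}")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-8, 1.0, sd)
    Xs = (X - mean) / sd

    ss = np.random.SeedSequence([config.seed, 0x5EED])
    init_seed, shuffle_seed, drop_seed = (int(s) for s in ss.generate_state(3) >> np.uint32(1))
    net = LstmNet(config.input_channels, config.hidden1, config.hidden2,
                  config.n_classes, config.dropout_p, seed=init_seed)
    opt = SgdMomentum(net.params, lr=config.learning_rate, momentum=config.momentum)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    drop_rng = np.random.default_rng(drop_seed)

    n = len(Xs)
    eye = np.eye(config.n_classes)
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    for _epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.minibatch):
            idx = order[start : start + config.minibatch]
            xb, yb = Xs[idx], y[idx]
            probs, ctx = net.forward(xb, dropout_rng=drop_rng)
            losses.append(net.loss(probs, eye[yb]))
            correct += int((probs.argmax(axis=1) == yb).sum())
            grads = net.backward(ctx, eye[yb])
            opt.step(net.params, grads)
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(correct / n)

    return TrainedClassifier(
        net=net, config=config, classes=classes,
        feat_mean=mean, feat_sd=sd, history=history,
    )


def predict(model: TrainedClassifier, features: list[FeatureSequence]):
    """Predict a label and class-probability vector per window.

    Inference is deterministic (dropout disabled); ties in the softmax are
    broken toward the lowest canonical class index.
    """
    X = _stack_features(features)
    if X.shape[1:] != model.feat_mean.shape:
        raise ValueError(
            f"feature shape {X.shape[1:]} does not match model input {model.feat_mean.shape}"
        )
    probs, _ = model.net.forward(model.standardize(X), dropout_rng=None)
    labels = [model.classes[i] for i in probs.argmax(axis=1)]
    return labels, probs


def evaluate(model: TrainedClassifier, features: list[FeatureSequence], labels) -> ConfusionMatrix:
    """Confusion matrix on a labeled test set (rows predicted, columns actual)."""
    if len(features) == 0:
        raise ValueError("test set must be non-empty")
    y_true = _encode_labels(labels, model.classes)
    pred_labels, _ = predict(model, features)
    y_pred = _encode_labels(pred_labels, model.classes)
    k = len(model.classes)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (y_pred, y_true), 1)
    return ConfusionMatrix(counts=counts, classes=model.classes)


def loso_cv(
    subject_data: dict[str, tuple[list[FeatureSequence], list]],
    config: LstmConfig | None = None,
    classes: tuple[str, ...] = ACTIVITY_LABELS,
) -> LosoResult:
    """Leave-one-subject-out cross-validation.

    Each fold trains on all subjects but one and tests on the held-out
    subject; fold seeds derive deterministically from ``config.seed`` so the
    whole run is reproducible.  The summary accuracy is the arithmetic mean
    of fold accuracies.
    """
    if config is None:
        config = LstmConfig()
    subjects = tuple(subject_data.keys())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    accs: list[float] = []
    cms: list[ConfusionMatrix] = []
    for fold, held_out in enumerate(subjects):
        train_feats: list[FeatureSequence] = []
        train_labels: list = []
        for s in subjects:
            if s == held_out:
                continue
            f, l = subject_data[s]
            train_feats.extend(f)
            train_labels.extend(l)
        fold_seed = int(np.random.SeedSequence([config.seed, 1000 + fold]).generate_state(1)[0] >> np.uint32(1))
        fold_config = LstmConfig(**{**asdict(config), "seed": fold_seed})
        model = train(train_feats, train_labels, fold_config, classes=classes)
        test_feats, test_labels = subject_data[held_out]
        cm = evaluate(model, test_feats, test_labels)
        accs.append(cm.accuracy)
        cms.append(cm)
    return LosoResult(subjects=subjects, fold_accuracies=tuple(accs), fold_confusions=tuple(cms))


def save_model(model: TrainedClassifier, path) -> None:
    """Serialize a trained model (weights + config + scaling) to one .npz file."""
    meta = {
        "config": asdict(model.config),
        "classes": list(model.classes),
        "history": model.history,
    }
    arrays = {
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        "feat_mean": model.feat_mean,
        "feat_sd": model.feat_sd,
        **{"param_" + k: v for k, v in model.net.params.items()},
    }
    # write through a handle so numpy does not append ".npz" to the path
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> TrainedClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        config = LstmConfig(**meta["config"])
        net = LstmNet(config.input_channels, config.hidden1, config.hidden2,
                      config.n_classes, config.dropout_p, seed=0)
        for k in list(net.params):
            net.params[k] = data["param_" + k]
        return TrainedClassifier(
            net=net,
            config=config,
            classes=tuple(meta["classes"]),
            feat_mean=data["feat_mean"],
            feat_sd=data["feat_sd"],
            history=meta["history"],
        )
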