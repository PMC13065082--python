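"""CNN host classifier, exposed as a Model / Results pair.

``HostClassifier`` holds the training data (feature tensors and host-taxon
labels) and the architecture/training configuration; ``fit()`` trains the
network and returns a ``HostClassifierResults`` carrying the learned
weights, the label map, the training history and prediction methods.

Architecture (defaults): two 5x5 same-padding convolutions (64 then 128
channels), each followed by ReLU and 2x2 max pooling, then a flatten, a
512-unit fully connected ReLU layer, and a softmax output over host taxa.
For k = 7 the activation chain is (3,128,128) -> (64,128,128) -> (64,64,64)
-> (128,64,64) -> (128,32,32).

Training minimizes categorical cross-entropy with Adam at learning rate
0.001.  When a validation set is supplied, the weights with the best
validation accuracy are kept and training stops early once the accuracy has
not improved for ``patience`` epochs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import Adam, ConvNet, softmax
from .features import CornerAssignment, FeatureTensor

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "HostClassifier",
    "HostClassifierResults",
    "PredictionResult",
    "split_dataset",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the classifier.

    k sets the input side 2^k; each conv block halves the side, so 2^k must
    be divisible by 2^len(conv_channels).
    """

    n_classes: int
    k: int = 7
    conv_channels: tuple[int, ...] = (64, 128)
    kernel_size: int = 5
    fc_units: int = 512

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if (2**self.k) % (2 ** len(self.conv_channels)) != 0:
            raise ValueError(
                f"input side {2**self.k} not divisible by "
                f"2^{len(self.conv_channels)} conv blocks"
            )

    @property
    def input_side(self) -> int:
        return 2**self.k

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "k": self.k,
            "conv_channels": list(self.conv_channels),
            "kernel_size": self.kernel_size,
            "fc_units": self.fc_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, categorical cross-entropy."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "seed": self.seed,
        }


def split_dataset(
    items: Sequence, ratios: tuple[int, ...] = (8, 1, 1), seed: int = 0
) -> tuple[list, ...]:
    """Random disjoint, exhaustive partition of ``items`` (default 8:1:1
    train/validation/test); reproducible under a fixed seed."""
    n = len(items)
    if n < len(ratios) * 2 or n < 10:
        raise ValueError(f"too few items ({n}) for a {ratios} split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    total = sum(ratios)
    bounds = [int(n * sum(ratios[: i + 1]) / total) for i in range(len(ratios))]
    parts: list[list] = []
    start = 0
    for b in bounds:
        parts.append([items[i] for i in order[start:b]])
        start = b
    return tuple(parts)


def _stack(tensors: Sequence[FeatureTensor], k: int) -> np.ndarray:
    for t in tensors:
        if t.k != k:
            raise ValueError(f"tensor with k={t.k} mixed into a k={k} batch")
    return np.stack([t.data for t in tensors]).astype(np.float32)


@dataclass(frozen=True)
class PredictionResult:
    """Per-sequence class probabilities and ranked host-taxon calls."""

    ids: tuple[str, ...]
    classes: tuple[str, ...]
    probabilities: np.ndarray  # (n, n_classes), rows sum to 1
    ranked: np.ndarray  # (n, n_classes) int class indices, best first

    @property
    def top1(self) -> list[str]:
        return [self.classes[i] for i in self.ranked[:, 0]]

    def top_k(self, k: int) -> list[list[str]]:
        k = min(k, len(self.classes))
        return [[self.classes[i] for i in row[:k]] for row in self.ranked]


class HostClassifier:
    """Host-taxon classifier over CGR feature tensors.

    Parameters
    ----------
    tensors, labels:
        Training sequences as normalized ``FeatureTensor`` objects with a
        host taxon per sequence.  All classes must be represented.
    validation:
        Optional ``(tensors, labels)`` pair used for best-epoch selection
        and early stopping.
    """

    def __init__(
        self,
        tensors: Sequence[FeatureTensor],
        labels: Sequence[str],
        ids: Sequence[str] | None = None,
        config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        validation: tuple[Sequence[FeatureTensor], Sequence[str]] | None = None,
    ) -> None:
        if len(tensors) != len(labels):
            raise ValueError("tensors and labels differ in length")
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise ValueError(
                f"training labels contain a single class {classes}; "
                "at least two are required"
            )
        k = tensors[0].k
        self.config = config or ModelConfig(n_classes=len(classes), k=k)
        if self.config.n_classes != len(classes):
            raise ValueError(
                f"config declares {self.config.n_classes} classes but labels "
                f"contain {len(classes)}"
            )
        if self.config.k != k:
            raise ValueError(f"config k={self.config.k} but tensors have k={k}")
        self.train_config = train_config or TrainConfig()
        self.classes = tuple(classes)
        self.corners = tensors[0].corners
        self._class_index = {c: i for i, c in enumerate(self.classes)}
        self.X = _stack(tensors, k)
        self.y = np.array([self._class_index[l] for l in labels], dtype=np.int64)
        self.ids = tuple(ids) if ids is not None else tuple(
            f"seq{i}" for i in range(len(tensors))
        )
        if validation is not None:
            vt, vl = validation
            self.X_val = _stack(vt, k)
            self.y_val = np.array(
                [self._class_index[l] for l in vl], dtype=np.int64
            )
        else:
            self.X_val = self.y_val = None

    @classmethod
    def from_dataset(
        cls,
        tensors_by_id: dict[str, FeatureTensor],
        label_table: dict[str, str],
        **kwargs,
    ) -> "HostClassifier":
        """Build from an id-keyed tensor store and a label table, keeping
        only sequences present in both."""
        ids = [i for i in tensors_by_id if i in label_table]
        return cls(
            [tensors_by_id[i] for i in ids],
            [label_table[i] for i in ids],
            ids=ids,
            **kwargs,
        )

    def fit(self) -> "HostClassifierResults":
        """Train the CNN; returns results with the best-validation weights
        (or the final weights when no validation set was given)."""
        cfg, tc = self.config, self.train_config
        rng = np.random.default_rng(tc.seed)
        net = ConvNet(
            in_side=cfg.input_side,
            in_ch=3,
            conv_channels=cfg.conv_channels,
            ksize=cfg.kernel_size,
            fc_units=cfg.fc_units,
            n_classes=cfg.n_classes,
            rng=rng,
        )
        opt = Adam(net.params, lr=tc.learning_rate)
        n = self.X.shape[0]
        history: list[dict] = []
        best_acc = -1.0
        best_epoch = 0
        best_params = [p.copy() for p in net.params]
        epochs_run = 0
        for epoch in range(1, tc.max_epochs + 1):
            epochs_run = epoch
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                loss, grads = net.loss_and_grads(self.X[idx], self.y[idx])
                opt.step(grads)
                losses.append(loss)
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if self.X_val is not None:
                val_pred = net.predict_proba(self.X_val).argmax(axis=1)
                val_acc = float((val_pred == self.y_val).mean())
                record["val_accuracy"] = val_acc
                if val_acc > best_acc:
                    best_acc = val_acc
                    best_epoch = epoch
                    best_params = [p.copy() for p in net.params]
                elif epoch - best_epoch >= tc.patience:
                    history.append(record)
                    break
            history.append(record)
        if self.X_val is not None:
            net.set_params(best_params)
        else:
            best_epoch = epochs_run
            best_acc = float("nan")
        return HostClassifierResults(
            config=cfg,
            train_config=tc,
            classes=self.classes,
            corners=self.corners,
            weights=[p.copy() for p in net.params],
            history=history,
            best_epoch=best_epoch,
            val_accuracy=best_acc,
        )


@dataclass
class HostClassifierResults:
    """Fitted classifier: weights, label map, history, and predictions."""

    config: ModelConfig
    train_config: TrainConfig
    classes: tuple[str, ...]
    corners: CornerAssignment
    weights: list[np.ndarray]
    history: list[dict]
    best_epoch: int
    val_accuracy: float
    _net: ConvNet | None = field(default=None, repr=False, compare=False)

    def _network(self) -> ConvNet:
        if self._net is None:
            cfg = self.config
            net = ConvNet(
                in_side=cfg.input_side,
                in_ch=3,
                conv_channels=cfg.conv_channels,
                ksize=cfg.kernel_size,
                fc_units=cfg.fc_units,
                n_classes=cfg.n_classes,
                rng=np.random.default_rng(0),
            )
            net.set_params(self.weights)
            self._net = net
        return self._net

    @property
    def epochs_run(self) -> int:
        return len(self.history)

    def predict(
        self,
        tensors: Sequence[FeatureTensor],
        ids: Sequence[str] | None = None,
        batch_size: int = 64,
    ) -> PredictionResult:
        """Class probabilities and ranked calls for new sequences.

        Ranking is by descending probability; ties break toward the lower
        class index.
        """
        X = _stack(tensors, self.config.k)
        net = self._network()
        probs = np.concatenate(
            [
                softmax(net.forward(X[i : i + batch_size]).astype(np.float64))
                for i in range(0, X.shape[0], batch_size)
            ]
        )
        ranked = np.argsort(-probs, axis=1, kind="stable")
        if ids is None:
            ids = [f"seq{i}" for i in range(len(tensors))]
        return PredictionResult(
            ids=tuple(ids),
            classes=self.classes,
            probabilities=probs,
            ranked=ranked,
        )

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        cfg = self.config
        lines = [
            "Host classifier (CGR signature CNN)",
            "=" * 46,
            f"{'k (grid side 2^k)':<28}{cfg.k} ({cfg.input_side})",
            f"{'conv channels':<28}{cfg.conv_channels}",
            f"{'fully connected units':<28}{cfg.fc_units}",
            f"{'host taxa (classes)':<28}{cfg.n_classes}",
            f"{'parameters':<28}{sum(p.size for p in self.weights)}",
            f"{'epochs run':<28}{self.epochs_run}",
            f"{'best epoch':<28}{self.best_epoch}",
            f"{'validation accuracy':<28}{self.val_accuracy:.4f}",
            "-" * 46,
            f"{'layer':<12}{'output shape'}",
        ]
        for name, shape in self._network().layer_shapes():
            lines.append(f"{name:<12}{shape}")
        return "\n".join(lines)

    def save(self, path) -> None:
        """Single-file checkpoint: weights + label map + configuration +
        corner assignment, so prediction is self-describing."""
        meta = {
            "config": self.config.to_dict(),
            "train_config": self.train_config.to_dict(),
            "classes": list(self.classes),
            "corners": self.corners.to_dict(),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "val_accuracy": self.val_accuracy,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        buf = io.BytesIO()
        np.savez_compressed(
            buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **arrays,
        )
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "HostClassifierResults":
        with np.load(path) as npz:
            meta = json.loads(npz["meta"].tobytes().decode())
            weights = [npz[f"w{i}"] for i in range(len(npz.files) - 1)]
        return cls(
            config=ModelConfig.from_dict(meta["config"]),
            train_config=TrainConfig(**meta["train_config"]),
            classes=tuple(meta["classes"]),
            corners=CornerAssignment.from_dict(meta["corners"]),
            weights=weights,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
            val_accuracy=meta["val_accuracy"],
        )
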