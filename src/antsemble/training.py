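"""The three CNN training regimes and model scoring.

* **general** — one network trained on pooled pictures from every view, so it
  can classify a specimen picture regardless of perspective;
* **specific** — one network per view, trained from scratch on that view's
  pictures only;
* **transfer** — one network per view, warm-started from the trained general
  model's weights and fine-tuned on that view's pictures.

Training is plain SGD with momentum and step learning-rate decay on a
softmax/cross-entropy loss.  Validation top-1 accuracy is monitored at a
fixed interval and the checkpoint with the best validation accuracy (ties
resolved to the earliest iteration) is the model returned.

Iteration counts are optimizer iterations (mini-batch steps).  Full-scale
studies of this kind run tens of thousands of steps; the defaults here are
deliberately desk-scale and fully configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datamodel import (
    VIEWS,
    DatasetSplit,
    EmptyDatasetError,
    ImageSample,
    MultiViewDataset,
    View,
    flatten_to_samples,
    to_square,
)
from .netspec import ArchitectureDescriptor
from .nn import (
    Network,
    SGDMomentum,
    compile_network,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "Hyperparams",
    "TrainedModel",
    "TrainingHistory",
    "train_general",
    "train_specific",
    "train_transfer",
    "score_image",
    "extract_penultimate_features",
    "save_checkpoint",
    "load_checkpoint",
]

REGIMES = ("general", "specific", "transfer")


@dataclass
class Hyperparams:
    """Optimizer settings; all defaults are desk-scale.

    ``iterations`` counts mini-batch SGD steps.  The learning rate is
    ``learning_rate * lr_decay ** (it // lr_decay_interval)``.
    """

    iterations: int = 600
    batch_size: int = 16
    learning_rate: float = 0.01
    lr_decay: float = 0.5
    lr_decay_interval: int = 250
    momentum: float = 0.9
    weight_decay: float = 1e-4
    validation_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        for name in ("batch_size", "lr_decay_interval", "validation_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0 or not (0 < self.lr_decay <= 1):
            raise ValueError("invalid learning-rate schedule")
        if self.iterations and self.validation_interval > self.iterations:
            raise ValueError("validation_interval must not exceed iterations")


@dataclass
class TrainingHistory:
    """Validation checkpoints recorded during training.

    ``points`` holds ``(iteration, mean training loss since the previous
    point, validation top-1 accuracy)``; ``best_iteration`` is the argmax of
    validation accuracy with ties resolved to the earliest point.
    """

    points: list[tuple[int, float, float]] = field(default_factory=list)
    best_iteration: int = 0

    @property
    def best_accuracy(self) -> float:
        for it, _, acc in self.points:
            if it == self.best_iteration:
                return acc
        return float("nan")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.points, columns=["iteration", "train_loss", "val_top1"]
        ).to_csv(path, index=False)


@dataclass
class TrainedModel:
    """A trained network: architecture, weights, and provenance.

    ``view`` is present iff the regime is not general.  The compiled network
    is cached lazily; ``weights`` is the list of parameter arrays in layer
    order.
    """

    arch: ArchitectureDescriptor
    weights: list[np.ndarray]
    regime: str
    view: View | None = None
    provenance: dict = field(default_factory=dict)
    _net: Network | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if (self.view is None) != (self.regime == "general"):
            raise ValueError("view must be present iff regime is not general")

    def network(self) -> Network:
        if self._net is None:
            self._net = compile_network(self.arch, np.random.default_rng(0))
            self._net.set_state(self.weights)
        return self._net

    # convenience wrappers
    def score(self, image: ImageSample) -> np.ndarray:
        return score_image(self, image)

    def features(self, image: ImageSample) -> np.ndarray:
        return extract_penultimate_features(self, image)


# ---------------------------------------------------------------------------
# data preparation


def prepare_image(sample: ImageSample, size: int) -> np.ndarray:
    """Resize to the network input square and center intensities at 0."""
    px = sample.pixels
    if px.shape != (size, size):
        px = to_square(px, size)
    return (px - 0.5).astype(np.float32)


def _stack(pairs: Sequence[tuple[ImageSample, int]], size: int):
    x = np.stack([prepare_image(s, size) for s, _ in pairs])[:, None, :, :]
    y = np.asarray([g - 1 for _, g in pairs], dtype=np.int64)
    return x, y


def _batched_top1(net: Network, x: np.ndarray, y: np.ndarray,
                  chunk: int = 64) -> float:
    hits = 0
    for lo in range(0, len(x), chunk):
        logits = net.forward(x[lo:lo + chunk], train=False)
        hits += int((logits.argmax(axis=1) == y[lo:lo + chunk]).sum())
    return hits / len(x)


# ---------------------------------------------------------------------------
# the training loop


def _fit(
    arch: ArchitectureDescriptor,
    train_pairs: Sequence[tuple[ImageSample, int]],
    val_pairs: Sequence[tuple[ImageSample, int]],
    hp: Hyperparams,
    regime: str,
    view: View | None,
    init_state: list[np.ndarray] | None = None,
    parent_ref: dict | None = None,
) -> tuple[TrainedModel, TrainingHistory]:
    if not train_pairs:
        raise EmptyDatasetError(f"{regime} training set is empty")
    n_labels = arch.n_labels
    if any(g < 1 or g > n_labels for _, g in train_pairs):
        raise ValueError("genus label outside the architecture's label range")

    root = np.random.SeedSequence((hp.seed, 0x7A41))
    init_seq, shuffle_seq, drop_seq = root.spawn(3)
    net = compile_network(arch, np.random.default_rng(init_seq))
    if init_state is not None:
        net.set_state(init_state)
    net.set_dropout_rng(np.random.default_rng(drop_seq))

    xtr, ytr = _stack(train_pairs, arch.input_size)
    has_val = len(val_pairs) > 0
    if has_val:
        xval, yval = _stack(val_pairs, arch.input_size)

    history = TrainingHistory()
    best_acc, best_it, best_state = -1.0, 0, None
    provenance = {
        "hyperparams": asdict(hp),
        "regime": regime,
        "view": view.value if view else None,
    }
    if parent_ref:
        provenance["parent"] = parent_ref

    if hp.iterations == 0:
        weights = net.get_state()
        return (
            TrainedModel(arch, weights, regime, view, provenance),
            history,
        )

    opt = SGDMomentum(net, hp.learning_rate, hp.momentum, hp.weight_decay)
    shuffle_rng = np.random.default_rng(shuffle_seq)
    order = shuffle_rng.permutation(len(xtr))
    cursor = 0
    loss_acc, loss_n = 0.0, 0
    for it in range(1, hp.iterations + 1):
        take = min(hp.batch_size, len(xtr))
        if cursor + take > len(order):
            order = shuffle_rng.permutation(len(xtr))
            cursor = 0
        idx = order[cursor:cursor + take]
        cursor += take
        logits = net.forward(xtr[idx], train=True)
        loss, dlogits = softmax_cross_entropy(logits, ytr[idx])
        net.backward(dlogits)
        opt.lr = hp.learning_rate * hp.lr_decay ** (it // hp.lr_decay_interval)
        opt.step()
        loss_acc += loss
        loss_n += 1
        if it % hp.validation_interval == 0 or it == hp.iterations:
            acc = _batched_top1(net, xval, yval) if has_val else float("nan")
            history.points.append((it, loss_acc / max(loss_n, 1), acc))
            loss_acc, loss_n = 0.0, 0
            if has_val and acc > best_acc:
                best_acc, best_it = acc, it
                best_state = net.get_state()

    if best_state is not None:
        weights = best_state
        history.best_iteration = best_it
    else:  # no validation data: keep the final weights
        weights = net.get_state()
        history.best_iteration = hp.iterations
    return TrainedModel(arch, weights, regime, view, provenance), history


def train_general(
    split: DatasetSplit,
    arch: ArchitectureDescriptor,
    hp: Hyperparams,
) -> tuple[TrainedModel, TrainingHistory]:
    """Train the general-purpose classifier on pooled pictures of all views."""
    train_pairs = flatten_to_samples(split.train)
    val_pairs = flatten_to_samples(split.validation)
    return _fit(arch, train_pairs, val_pairs, hp, "general", None)


def train_specific(
    split: DatasetSplit,
    view: View,
    arch: ArchitectureDescriptor,
    hp: Hyperparams,
) -> tuple[TrainedModel, TrainingHistory]:
    """Train a from-scratch classifier on one view's pictures only."""
    train_pairs = flatten_to_samples(split.train, views=(view,))
    val_pairs = flatten_to_samples(split.validation, views=(view,))
    return _fit(arch, train_pairs, val_pairs, hp, "specific", view)


def train_transfer(
    parent: TrainedModel,
    split: DatasetSplit,
    view: View,
    hp: Hyperparams,
) -> tuple[TrainedModel, TrainingHistory]:
    """Fine-tune a copy of the general model on one view's pictures.

    The returned model's weights are initialised exactly to the parent's; at
    zero iterations the two are identical.
    """
    if parent.regime != "general":
        raise ValueError("transfer learning requires a general-purpose parent")
    train_pairs = flatten_to_samples(split.train, views=(view,))
    val_pairs = flatten_to_samples(split.validation, views=(view,))
    parent_ref = {"regime": parent.regime,
                  "hyperparams": parent.provenance.get("hyperparams")}
    return _fit(
        parent.arch, train_pairs, val_pairs, hp, "transfer", view,
        init_state=[w.copy() for w in parent.weights],
        parent_ref=parent_ref,
    )


# ---------------------------------------------------------------------------
# scoring and features


def score_image(model: TrainedModel, image: ImageSample) -> np.ndarray:
    """Softmax class-membership scores of one picture; sums to 1.

    Index ``i`` of the returned vector is the score of genus label ``i+1``.
    """
    x = prepare_image(image, model.arch.input_size)[None, None]
    logits = model.network().forward(x, train=False)
    return softmax(logits)[0]


def extract_penultimate_features(model: TrainedModel,
                                 image: ImageSample) -> np.ndarray:
    """Activations of the second-to-last fully connected stage (post-ReLU).

    With the reference architecture this is the 4096-wide vector commonly
    used as an off-the-shelf image descriptor.
    """
    net = model.network()
    if len(net.linear_indices) < 2:
        raise ValueError("architecture has fewer than two fully connected layers")
    x = prepare_image(image, model.arch.input_size)[None, None]
    outs = net.forward_collect(x)
    idx = net.linear_indices[-2]
    # take the ReLU immediately after the penultimate linear layer, if any
    from .nn import ReLU

    if idx + 1 < len(net.layers) and isinstance(net.layers[idx + 1], ReLU):
        idx += 1
    return outs[idx][0]


# ---------------------------------------------------------------------------
# checkpoint I/O


def save_checkpoint(model: TrainedModel, history: TrainingHistory,
                    path: str | Path) -> Path:
    """Write weights (``.npz``) plus a JSON sidecar next to them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"),
             **{f"param_{i:03d}": w for i, w in enumerate(model.weights)})
    sidecar = {
        "architecture": json.loads(model.arch.to_json()),
        "regime": model.regime,
        "view": model.view.value if model.view else None,
        "provenance": model.provenance,
        "history": {
            "points": history.points,
            "best_iteration": history.best_iteration,
        },
    }
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> tuple[TrainedModel, TrainingHistory]:
    path = Path(path)
    with open(path.with_suffix(".json"), encoding="utf-8") as fh:
        sidecar = json.load(fh)
    arch = ArchitectureDescriptor.from_json(json.dumps(sidecar["architecture"]))
    with np.load(path.with_suffix(".npz")) as npz:
        weights = [npz[k] for k in sorted(npz.files)]
    view = View(sidecar["view"]) if sidecar["view"] else None
    model = TrainedModel(arch, weights, sidecar["regime"], view,
                         sidecar.get("provenance", {}))
    hist = TrainingHistory(
        points=[tuple(p) for p in sidecar["history"]["points"]],
        best_iteration=sidecar["history"]["best_iteration"],
    )
    return model, hist
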