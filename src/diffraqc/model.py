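"""Quadrant models: architecture, geometry output stage, losses, training.

A conditioned 512 x 512 quadrant is passed through a convolutional
backbone producing 1000 features, then through two fully connected layers
(FC1: 1000 -> 100 with bias, a rectified linear unit, optionally dropout;
FC2: 100 -> 1 with bias) to a scalar ``s``.  The scalar is interpreted by
one of two output heads:

* ``geometry_resolution`` — ``s`` is an effective radial extent of the
  diffraction in downsampled-pixel units, converted to an inverse
  resolution with the beam wavelength, effective pixel size and detector
  distance:  ``1/d = (2/lambda) sin(0.5 arctan(s p_eff / D))``.
  Modeling inverse resolution keeps the regression target finite and
  division-free; non-positive ``s`` maps to 0 A^-1.
* ``sigmoid_overlap`` — ``s`` is a logit; ``sigmoid(s)`` is the
  probability that the image contains overlapping-lattice diffraction.

Backbone depths 18/34/50 are the canonical residual networks with a
single-channel input stage (see :mod:`diffraqc.resnet`); depth ``"toy"``
is a small convolutional network sized for desk-scale training on the toy
detector preset.  Training uses stochastic gradient descent with momentum
and an optional weight decay, a seeded 90/10 train/test split, per-epoch
loss/accuracy records, and checkpointing at the best test metric.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .resnet import ResNet, RESNET_LAYERS, count_shapes, resnet_param_shapes

__all__ = [
    "ArchitectureSpec", "TrainConfig", "EpochRecord", "ParameterCounts",
    "QuadrantModel", "build_model", "count_parameters", "geometry_head",
    "loss_resolution", "loss_overlap", "accuracy_resolution",
    "accuracy_overlap", "train", "toy_train_config",
    "save_checkpoint", "load_checkpoint", "sigmoid",
]

N_FEATURES = 1000
FC1_OUT = 100
HEADS = ("geometry_resolution", "sigmoid_overlap")

#: fixed input normalization: conditioned (sqrt-quantized) pixel values are
#: small integers; this scale puts typical Bragg peaks at order unity
INPUT_SCALE = 0.1


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structure of a quadrant model.

    ``depth`` selects the backbone: 18/34/50 (canonical residual networks)
    or ``"toy"``.  Exactly one output head; FC dims are fixed.
    """

    depth: int | str = "toy"
    head: str = "geometry_resolution"
    fc1_dropout: bool = False
    dropout_p: float = 0.5
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        if self.depth != "toy" and self.depth not in RESNET_LAYERS:
            raise ValueError("depth must be 'toy', 18, 34 or 50")
        if self.in_channels != 1:
            raise ValueError("quadrant models are single-channel")


@dataclass
class TrainConfig:
    """Optimizer and loop settings.

    The task defaults mirror the reference hyperparameters: resolution —
    momentum 0.9, learning rate 6e-3, mean-absolute loss; overlap —
    momentum 0.9983, weight decay 2.5e-4, learning rate 1.04e-3, binary
    cross-entropy.  Batch size, epoch count and the 90/10 split seed are
    configurable.
    """

    task: str = "resolution"
    lr: float = 6e-3
    momentum: float = 0.9
    weight_decay: float = 0.0
    loss: str = "mae"            # mae | mse | bce
    epochs: int = 20
    batch_size: int = 32
    test_fraction: float = 0.10
    lr_decay: float = 1.0        # multiplicative per-epoch decay
    seed: int = 0
    accuracy_threshold: float = 0.07   # |delta(1/d)| in A^-1, resolution task

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.task not in ("resolution", "overlap"):
            raise ValueError("task must be 'resolution' or 'overlap'")

    @classmethod
    def for_task(cls, task: str, **over) -> "TrainConfig":
        base = dict(task=task)
        if task == "overlap":
            base.update(lr=1.04e-3, momentum=0.9983, weight_decay=2.5e-4,
                        loss="bce")
        base.update(over)
        return cls(**base)


def toy_train_config(task: str, **over) -> TrainConfig:
    """Training settings sized for the toy backbone on toy-detector data.

    The full-scale defaults of :class:`TrainConfig` target many-epoch runs
    on large image sets; for the small toy network a slightly larger step
    and shorter momentum horizon converge in tens of epochs.
    """
    base = dict(task=task, epochs=30)
    if task == "resolution":
        # the geometry head contracts gradients by ~d(1/d)/ds ~ 3e-3 per
        # pixel unit, so the toy step size is much larger than the
        # full-scale default
        base.update(lr=0.5, momentum=0.9, loss="mae")
    else:
        base.update(lr=2e-2, momentum=0.9, weight_decay=1e-4, loss="bce")
    base.update(over)
    return TrainConfig(**base)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    test_loss: float
    train_acc: float
    test_acc: float
    is_best: bool = False


class ParameterCounts(tuple):
    """(backbone, fc1, fc2, total) trainable-scalar counts."""

    def __new__(cls, backbone, fc1, fc2):
        return super().__new__(cls, (backbone, fc1, fc2, backbone + fc1 + fc2))

    backbone = property(lambda self: self[0])
    fc1 = property(lambda self: self[1])
    fc2 = property(lambda self: self[2])
    total = property(lambda self: self[3])


class _ToyStem(nn.Layer):
    """Fixed stem of the toy backbone: scale, crop/pad to 256, 4x mean pool.

    The toy detector preset downsamples to 256 x 256, so the informative
    region of its zero-padded 512 x 512 quadrant is the leading 256 x 256
    corner; cropping it (and zero-padding smaller inputs) gives the conv
    stack a constant 64 x 64 field regardless of input size.
    """

    SIZE = 256
    POOL = 4

    def __init__(self):
        self._pool = nn.BlockMeanPool(self.POOL)

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        s = self.SIZE
        self._in_hw = (h, w)
        if h != s or w != s:
            xc = np.zeros((b, c, s, s), dtype=np.float32)
            xc[:, :, :min(h, s), :min(w, s)] = x[:, :, :s, :s]
            x = xc
        return self._pool.forward(x * INPUT_SCALE, train=train)

    def backward(self, gout):
        g = self._pool.backward(gout) * INPUT_SCALE
        h, w = self._in_hw
        s = self.SIZE
        if h == s and w == s:
            return g
        out = np.zeros((g.shape[0], g.shape[1], h, w), dtype=np.float32)
        out[:, :, :min(h, s), :min(w, s)] = g[:, :, :min(h, s), :min(w, s)]
        return out


def _toy_backbone(rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        _ToyStem(),
        nn.Conv2d(1, 12, 3, stride=2, pad=1, rng=rng, name="conv1"),
        nn.BatchNorm2d(12, name="bn1"),
        nn.ReLU(),
        nn.Conv2d(12, 24, 3, stride=2, pad=1, rng=rng, name="conv2"),
        nn.BatchNorm2d(24, name="bn2"),
        nn.ReLU(),
        nn.Conv2d(24, 32, 3, stride=2, pad=1, rng=rng, name="conv3"),
        nn.BatchNorm2d(32, name="bn3"),
        nn.ReLU(),
        nn.Flatten(),
        nn.Linear(32 * 8 * 8, N_FEATURES, rng=rng, name="proj"),
    )


def sigmoid(z):
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def geometry_head(s, wavelength_A, p_eff_mm, distance_mm):
    """Convert the model scalar to inverse resolution (A^-1).

    ``s`` is an effective radial extent in downsampled-pixel units;
    ``1/d = (2/lambda) sin(0.5 arctan(s p_eff / D))``.  Non-positive ``s``
    maps to 0 A^-1.  Vectorized; raises for invalid geometry.
    """
    lam = np.asarray(wavelength_A, dtype=float)
    p = np.asarray(p_eff_mm, dtype=float)
    D = np.asarray(distance_mm, dtype=float)
    if np.any(lam <= 0) or np.any(p <= 0) or np.any(D <= 0):
        raise ValueError("wavelength, pixel size and distance must be positive")
    s = np.asarray(s, dtype=float)
    u = np.clip(s, 0.0, None) * p / D
    out = (2.0 / lam) * np.sin(0.5 * np.arctan(u)) * (s > 0)
    return float(out) if out.ndim == 0 else out


def geometry_head_grad(s, wavelength_A, p_eff_mm, distance_mm):
    """d(1/d)/ds of :func:`geometry_head` (0 for s <= 0)."""
    lam = np.asarray(wavelength_A, dtype=float)
    p = np.asarray(p_eff_mm, dtype=float)
    D = np.asarray(distance_mm, dtype=float)
    s = np.asarray(s, dtype=float)
    u = np.clip(s, 0.0, None) * p / D
    g = (2.0 / lam) * np.cos(0.5 * np.arctan(u)) * 0.5 * (p / D) / (1.0 + u * u)
    return g * (s > 0)


class QuadrantModel:
    """Backbone + FC head + output stage, with explicit backward pass."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.depth == "toy":
            self.backbone: nn.Layer = _toy_backbone(rng)
        else:
            self.backbone = ResNet(spec.depth, in_channels=spec.in_channels,
                                   n_features=N_FEATURES, rng=rng)
        self.fc1 = nn.Linear(N_FEATURES, FC1_OUT, rng=rng, name="fc1")
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(spec.dropout_p, rng) if spec.fc1_dropout else None
        self.fc2 = nn.Linear(FC1_OUT, 1, rng=rng, name="fc2")
        if spec.head == "geometry_resolution":
            # start the radial-extent scalar inside the head's monotone
            # regime (a plausible mid-detector radius in downsampled px)
            self.fc2.bias.value[:] = 100.0
        self._head_cache = None

    # -- parameter plumbing ---------------------------------------------
    def params(self) -> list[nn.Param]:
        return (self.backbone.params() + self.fc1.params() + self.fc2.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value for i, p in enumerate(self.params())}
        # batch-norm running statistics are state but not parameters
        for j, layer in enumerate(self._bn_layers()):
            state[f"bn{j}.running_mean"] = layer.running_mean
            state[f"bn{j}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]
        for j, layer in enumerate(self._bn_layers()):
            layer.running_mean[...] = state[f"bn{j}.running_mean"]
            layer.running_var[...] = state[f"bn{j}.running_var"]

    def _bn_layers(self):
        found = []

        def walk(layer):
            if isinstance(layer, nn.BatchNorm2d):
                found.append(layer)
            for attr in ("layers",):
                for sub in getattr(layer, attr, []):
                    walk(sub)
            for attr in ("net", "main", "shortcut", "_pool"):
                sub = getattr(layer, attr, None)
                if isinstance(sub, nn.Layer):
                    walk(sub)
        walk(self.backbone)
        return found

    # -- forward / backward ---------------------------------------------
    def scalar(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Raw scalar ``s`` per image, before the output head."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        h = self.backbone.forward(x, train=train)
        h = self.relu.forward(self.fc1.forward(h, train=train), train=train)
        if self.dropout:
            h = self.dropout.forward(h, train=train)
        return self.fc2.forward(h, train=train)[:, 0]

    def forward(self, x: np.ndarray, geom: dict | None = None,
                train: bool = False) -> np.ndarray:
        """Head output per image: inverse resolution (A^-1) or overlap logit.

        ``geom`` (resolution head only) maps ``wavelength_A``, ``p_eff_mm``
        and ``distance_mm`` to scalars or per-image arrays.
        """
        s = self.scalar(x, train=train)
        if self.spec.head == "geometry_resolution":
            if geom is None:
                raise ValueError("resolution head requires geometry")
            args = (geom["wavelength_A"], geom["p_eff_mm"], geom["distance_mm"])
            self._head_cache = (s, args)
            return geometry_head(s, *args)
        self._head_cache = (s, None)
        return s

    def backward(self, gpred: np.ndarray) -> None:
        s, args = self._head_cache
        if self.spec.head == "geometry_resolution":
            gs = gpred * geometry_head_grad(s, *args)
        else:
            gs = gpred
        g = self.fc2.backward(np.asarray(gs, dtype=np.float32)[:, None])
        if self.dropout:
            g = self.dropout.backward(g)
        g = self.relu.backward(g)
        g = self.fc1.backward(g)
        self.backbone.backward(g)

    def predict(self, x: np.ndarray, geom: dict | None = None) -> np.ndarray:
        """Inference-mode output; overlap head returns probabilities."""
        out = self.forward(x, geom=geom, train=False)
        if self.spec.head == "sigmoid_overlap":
            return sigmoid(out)
        return out


def build_model(spec: ArchitectureSpec, seed: int = 0) -> QuadrantModel:
    """Instantiate a quadrant model from its architecture spec."""
    return QuadrantModel(spec, seed=seed)


def count_parameters(model: QuadrantModel) -> ParameterCounts:
    """Exact trainable-scalar counts by stage (backbone, FC1, FC2, total)."""
    n_back = sum(p.size for p in model.backbone.params())
    n_fc1 = sum(p.size for p in model.fc1.params())
    n_fc2 = sum(p.size for p in model.fc2.params())
    return ParameterCounts(n_back, n_fc1, n_fc2)


def count_parameters_for_depth(depth: int, in_channels: int = 1) -> ParameterCounts:
    """Stage counts for a deep backbone from the shape table (no allocation)."""
    n_back = count_shapes(resnet_param_shapes(depth, in_channels))
    return ParameterCounts(n_back, N_FEATURES * FC1_OUT + FC1_OUT, FC1_OUT + 1)


# -- losses and metrics ---------------------------------------------------

def loss_resolution(pred, label, kind: str = "mae"):
    """Mean-squared or mean-absolute error in inverse-resolution units.

    Returns ``(loss, grad_wrt_pred)``; the batch loss is the mean of the
    per-item losses.
    """
    pred = np.asarray(pred, dtype=float)
    label = np.asarray(label, dtype=float)
    diff = pred - label
    n = max(diff.size, 1)
    if kind == "mse":
        return float(np.mean(diff ** 2)), 2.0 * diff / n
    if kind == "mae":
        return float(np.mean(np.abs(diff))), np.sign(diff) / n
    raise ValueError("kind must be 'mae' or 'mse'")


def loss_overlap(logit, label):
    """Binary cross-entropy on ``sigmoid(logit)`` against 0/1 labels.

    Numerically stable log-sum-exp form; returns ``(loss, grad_wrt_logit)``.
    """
    z = np.asarray(logit, dtype=float)
    y = np.asarray(label, dtype=float)
    loss = np.logaddexp(0.0, z) - z * y
    grad = (sigmoid(z) - y) / max(z.size, 1)
    return float(np.mean(loss)), grad


def accuracy_resolution(preds, labels, threshold: float = 0.07) -> float:
    """Fraction of images with |pred - label| <= threshold (A^-1)."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if preds.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return float(np.mean(np.abs(preds - labels) <= threshold))


def accuracy_overlap(probs, labels, threshold: float = 0.5) -> float:
    """Fraction of correct overlapped/single calls at the given threshold."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return float(np.mean((probs >= threshold) == (labels > 0.5)))


# -- training loop --------------------------------------------------------

def _evaluate(model, x, labels, geom_rows, config):
    preds = []
    bs = max(config.batch_size, 1)
    for i in range(0, len(x), bs):
        geom = _slice_geom(geom_rows, slice(i, i + bs))
        preds.append(model.forward(x[i:i + bs], geom=geom, train=False))
    preds = np.concatenate(preds) if preds else np.empty(0)
    if config.task == "resolution":
        loss, _ = loss_resolution(preds, labels, config.loss)
        acc = accuracy_resolution(preds, labels, config.accuracy_threshold)
    else:
        loss, _ = loss_overlap(preds, labels)
        acc = accuracy_overlap(sigmoid(preds), labels)
    return loss, acc


def _slice_geom(geom_rows, sl):
    if geom_rows is None:
        return None
    return {k: v[sl] if np.ndim(v) else v for k, v in geom_rows.items()}


def train(dataset: dict, spec: ArchitectureSpec, config: TrainConfig,
          model: QuadrantModel | None = None):
    """Train a quadrant model; returns ``(records, best_state, model)``.

    ``dataset`` maps ``"images"`` to an (N, H, W) array of conditioned
    quadrants, ``"labels"`` to per-image targets (inverse resolution in
    A^-1, or 0/1 overlap flags), and — for the resolution task —
    ``"geometry"`` to per-image ``wavelength_A`` / ``p_eff_mm`` /
    ``distance_mm`` arrays.  A seeded ``test_fraction`` split is held out;
    ``best_state`` is the weight snapshot at the best test accuracy
    (ties broken by test loss).
    """
    if (config.task == "resolution") != (spec.head == "geometry_resolution"):
        raise ValueError("dataset/config task does not match the model head")
    x = np.asarray(dataset["images"], dtype=np.float32)
    labels = np.asarray(dataset["labels"], dtype=float)
    geom_rows = dataset.get("geometry")
    if spec.head == "geometry_resolution" and geom_rows is None:
        raise ValueError("resolution training requires per-image geometry")
    n = len(x)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(n * config.test_fraction))) if n > 1 else 0
    test_idx, train_idx = order[:n_test], order[n_test:]
    model = model or build_model(spec, seed=config.seed)
    opt = nn.SGD(model.params(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)

    records: list[EpochRecord] = []
    best = (-np.inf, np.inf)
    best_state = None
    for epoch in range(config.epochs):
        perm = train_idx[rng.permutation(len(train_idx))]
        ep_losses, ep_preds, ep_labels = [], [], []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i:i + config.batch_size]
            geom = _slice_geom(geom_rows, idx)
            preds = model.forward(x[idx], geom=geom, train=True)
            if config.task == "resolution":
                loss, grad = loss_resolution(preds, labels[idx], config.loss)
            else:
                loss, grad = loss_overlap(preds, labels[idx])
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            ep_losses.append(loss * len(idx))
            ep_preds.append(preds)
            ep_labels.append(labels[idx])
        train_loss = float(np.sum(ep_losses) / max(len(perm), 1))
        ep_preds = np.concatenate(ep_preds)
        ep_labels = np.concatenate(ep_labels)
        if config.task == "resolution":
            train_acc = accuracy_resolution(ep_preds, ep_labels,
                                            config.accuracy_threshold)
        else:
            train_acc = accuracy_overlap(sigmoid(ep_preds), ep_labels)
        if n_test:
            test_loss, test_acc = _evaluate(model, x[test_idx], labels[test_idx],
                                            _slice_geom(geom_rows, test_idx), config)
        else:
            test_loss, test_acc = train_loss, train_acc
        is_best = (test_acc, -test_loss) > best
        if is_best:
            best = (test_acc, -test_loss)
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        records.append(EpochRecord(epoch, train_loss, test_loss,
                                   train_acc, test_acc, is_best))
        opt.lr *= config.lr_decay
    if best_state is None:
        best_state = model.state_dict()
    return records, best_state, model


# -- checkpoints ----------------------------------------------------------

def save_checkpoint(path, model: QuadrantModel, state: dict | None = None,
                    meta: dict | None = None) -> None:
    """Write weights + architecture spec (+ user metadata) to an .npz file."""
    state = state or model.state_dict()
    header = {"spec": asdict(model.spec), "meta": meta or {}}
    # write through a file handle so numpy never appends its own extension
    with open(path, "wb") as fh:
        np.savez_compressed(fh, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[QuadrantModel, dict]:
    """Rebuild a model from an .npz checkpoint; returns (model, metadata)."""
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        state = {k: z[k] for k in z.files if k != "__header__"}
    spec = ArchitectureSpec(**header["spec"])
    model = build_model(spec)
    model.load_state_dict(state)
    return model, header.get("meta", {})


def records_to_csv(records: list[EpochRecord], path) -> None:
    """Write epoch records as plain CSV (epoch, losses, accuracies, best)."""
    import csv
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "train_loss", "test_loss", "train_acc",
                    "test_acc", "is_best"])
        for r in records:
            w.writerow([r.epoch, f"{r.train_loss:.6g}", f"{r.test_loss:.6g}",
                        f"{r.train_acc:.4f}", f"{r.test_acc:.4f}", int(r.is_best)])
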