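"""Image classifiers and the training loop.

Two architectures are provided:

``alexnet_like``
    five convolutional stages and three fully-connected stages in the classic
    layout (global average pooling replaces the fixed-size adaptive pool so
    any input of at least 64x64 works).
``tiny``
    three strided convolutions plus one linear head; trains in seconds on a
    CPU and is the workhorse for desk-scale experiments and tests.

Both end in a convolutional feature stage, as Grad-CAM requires.  Training
supports plain cross-entropy or the combined right-reasons loss
(:mod:`xleaf.rrr`); with all-zero annotation matrices the two paths produce
bit-identical trajectories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import rrr as rrr_mod
from .autodiff import Tensor
from .leafsim import LabeledDataset
from .rrr import LossSpec

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "Model",
    "build_network",
    "train",
    "evaluate_accuracy",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetworkSpec:
    variant: str = "tiny"  # or "alexnet_like"
    n_classes: int = 2
    input_size: tuple[int, int, int] = (64, 64, 3)  # (U, V, B)

    def validate(self) -> None:
        if self.variant not in ("tiny", "alexnet_like"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        U, V, B = self.input_size
        minimum = 32 if self.variant == "tiny" else 64
        if U < minimum or V < minimum:
            raise ValueError(f"{self.variant} requires input >= "
                             f"{minimum}x{minimum}, got {U}x{V}")
        if B != 3:
            raise ValueError("inputs must have 3 channels")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 15
    batch_size: int = 16
    learning_rate: float = 3e-3
    optimizer_name: str = "adam"
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")


# -- layers ----------------------------------------------------------------

class _Conv:
    def __init__(self, rng, cin, cout, k, stride, pad):
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, padding=self.pad)

    def params(self):
        return [self.w, self.b]


class _Linear:
    def __init__(self, rng, din, dout):
        std = np.sqrt(2.0 / din)
        self.w = Tensor(rng.normal(0.0, std, size=(din, dout)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(dout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.linear(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class _ReLU:
    def __call__(self, x):
        return ad.relu(x)

    def params(self):
        return []


class _MaxPool:
    def __init__(self, k, stride):
        self.k, self.stride = k, stride

    def __call__(self, x):
        return ad.maxpool2d(x, self.k, self.stride)

    def params(self):
        return []


class _GAP:
    def __call__(self, x):
        return ad.global_avg_pool(x)

    def params(self):
        return []


class _InputNorm:
    """Fixed affine map of [0, 1] images to [-1, 1]; improves conditioning."""

    def __call__(self, x):
        return ad.mul(ad.sub(x, Tensor(np.float32(0.5))), Tensor(np.float32(2.0)))

    def params(self):
        return []


class Model:
    """A feed-forward classifier plus its training provenance.

    ``feature_index`` marks the layer whose output is the last convolutional
    feature map (post-ReLU) used by Grad-CAM.
    """

    def __init__(self, spec: NetworkSpec, layers, feature_index: int, seed: int):
        self.spec = spec
        self.layers = layers
        self.feature_index = feature_index
        self.seed = seed
        self.epochs_trained = 0
        self.loss_descriptor = "untrained"

    def params(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x) -> Tensor:
        """Logits (pre-softmax) for an NCHW batch (array or Tensor)."""
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        for layer in self.layers:
            h = layer(h)
        return h

    def forward_with_features(self, x):
        """Return (feature maps, logits); features keep graph connectivity."""
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        feats = None
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i == self.feature_index:
                feats = h
        return feats, h

    def head_from_features(self, feats) -> Tensor:
        """Apply the layers after the feature stage (used by oracles)."""
        h = feats if isinstance(feats, Tensor) else Tensor(np.asarray(feats, dtype=np.float32))
        for layer in self.layers[self.feature_index + 1:]:
            h = layer(h)
        return h

    def predict_proba(self, x) -> np.ndarray:
        return ad.softmax(self.forward(x)).data

    def predict(self, x) -> np.ndarray:
        return self.forward(x).data.argmax(axis=-1)


def build_network(spec: NetworkSpec, seed: int) -> Model:
    """Seed-deterministic randomly initialized network (He-normal weights)."""
    spec.validate()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 23])
    if spec.variant == "tiny":
        layers = [
            _InputNorm(),
            _Conv(rng, 3, 8, 3, 2, 1), _ReLU(),
            _Conv(rng, 8, 16, 3, 2, 1), _ReLU(),
            _Conv(rng, 16, 32, 3, 2, 1), _ReLU(),  # feature stage
            _GAP(),
            _Linear(rng, 32, spec.n_classes),
        ]
        feature_index = 6
    else:
        layers = [
            _InputNorm(),
            _Conv(rng, 3, 64, 11, 4, 2), _ReLU(), _MaxPool(3, 2),
            _Conv(rng, 64, 192, 5, 1, 2), _ReLU(), _MaxPool(3, 2),
            _Conv(rng, 192, 384, 3, 1, 1), _ReLU(),
            _Conv(rng, 384, 256, 3, 1, 1), _ReLU(),
            _Conv(rng, 256, 256, 3, 1, 1), _ReLU(),  # feature stage
            _MaxPool(3, 2),
            _GAP(),
            _Linear(rng, 256, 4096), _ReLU(),
            _Linear(rng, 4096, 4096), _ReLU(),
            _Linear(rng, 4096, spec.n_classes),
        ]
        feature_index = 12  # ReLU after the fifth convolution
    return Model(spec, layers, feature_index, seed)


# -- optimizers -------------------------------------------------------------

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g.data
            v *= self.b2
            v += (1 - self.b2) * g.data ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _SGD:
    def __init__(self, params, lr):
        self.params, self.lr = params, lr

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p.data -= self.lr * g.data


def _batch_loss(model: Model, xb: np.ndarray, yb: np.ndarray,
                ann: np.ndarray | None, loss: LossSpec,
                scale: float | None):
    """One batch's (total loss Tensor, closs value, rloss value, scale).

    ``scale`` is the multiplier turning the raw penalty into its balanced
    value; ``None`` means "compute it from this batch" (per-batch mode, or
    the one-time calibration of the default mode).
    """
    use_rrr = (loss.lambda_weight > 0.0 and ann is not None
               and float(ann.sum()) > 0.0)
    if not use_rrr:
        xt = Tensor(xb)
        closs = ad.cross_entropy(model.forward(xt), yb)
        return closs, float(closs.data), 0.0, scale

    xt = Tensor(xb, requires_grad=True)
    logits = model.forward(xt)
    closs = ad.cross_entropy(logits, yb)
    probs = ad.softmax(logits)
    s = ad.tsum(ad.log(probs + Tensor(np.float32(1.0))))
    (gx,) = ad.grad(s, [xt], create_graph=True)
    rloss = rrr_mod.rrr_penalty(gx, ann, variant=loss.rloss_variant)
    rval = float(rloss.data)
    cval = float(closs.data)
    if scale is None:
        if rval <= rrr_mod.BALANCE_EPS or cval <= 0.0:
            # guard: the order-of-magnitude ratio is undefined for this batch
            return closs, cval, rval, None
        scale = rrr_mod.balance(rval, cval) / rval  # piecewise-constant factor
    total = ad.add(closs, ad.mul(Tensor(np.float32(loss.lambda_weight * scale)),
                                 rloss))
    return total, cval, rval, scale


def train(model: Model, data: LabeledDataset, loss: LossSpec,
          cfg: TrainConfig):
    """Train in place; returns ``(model, history)``.

    ``history`` is a list of per-epoch dicts with keys ``epoch``, ``nloss``,
    ``closs``, ``rloss`` and ``val_accuracy`` (NaN when the dataset has no
    validation split).  Deterministic given the seeds and configuration.
    With ``lambda_weight = 0`` or all-zero annotation matrices the trajectory
    is bit-identical to plain cross-entropy training.
    """
    cfg.validate()
    xs, ys, anns, _ = data.split_arrays("train")
    params = model.params()
    opt = (_Adam(params, cfg.learning_rate) if cfg.optimizer_name == "adam"
           else _SGD(params, cfg.learning_rate))
    rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, 29])
    has_val = len(data.splits.get("validation", ())) > 0

    calibrated = loss.balance_mode == "calibrated"
    warm_epochs = int(np.ceil(cfg.epochs * loss.warmup_frac)) if calibrated else 0
    fixed_scale: float | None = None

    history = []
    n = len(ys)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_n, tot_c, tot_r, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            in_warmup = loss.lambda_weight > 0.0 and epoch < warm_epochs
            if in_warmup:
                xt = Tensor(xs[idx])
                total = ad.cross_entropy(model.forward(xt), ys[idx])
                cval, rval = float(total.data), 0.0
            else:
                total, cval, rval, new_scale = _batch_loss(
                    model, xs[idx], ys[idx], anns[idx], loss,
                    fixed_scale if calibrated else None)
                if calibrated and fixed_scale is None:
                    fixed_scale = new_scale
            nval = float(total.data)
            if not np.isfinite(nval):
                bad = "RLoss" if not np.isfinite(rval) else "CLoss"
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {bad} diverged "
                    f"(CLoss={cval}, RLoss={rval})")
            grads = ad.grad(total, params)
            opt.step(grads)
            tot_n += nval
            tot_c += cval
            tot_r += rval
            nb += 1
        val_acc = evaluate_accuracy(model, data, "validation") if has_val \
            else float("nan")
        history.append({"epoch": epoch, "nloss": tot_n / nb, "closs": tot_c / nb,
                        "rloss": tot_r / nb, "val_accuracy": val_acc})
    model.epochs_trained += cfg.epochs
    model.loss_descriptor = loss.describe()
    return model, history


def evaluate_accuracy(model: Model, data: LabeledDataset, split: str,
                      batch_size: int = 64) -> float:
    """Fraction of split samples whose argmax probability matches the label."""
    xs, ys, _, _ = data.split_arrays(split)
    correct = 0
    for start in range(0, len(ys), batch_size):
        pred = model.predict(xs[start:start + batch_size])
        correct += int((pred == ys[start:start + batch_size]).sum())
    return correct / len(ys)


# -- persistence -------------------------------------------------------------

def save_model(model: Model, path: str | Path) -> None:
    """Checkpoint: parameter arrays plus an embedded JSON provenance block."""
    prov = {
        "variant": model.spec.variant,
        "n_classes": model.spec.n_classes,
        "input_size": list(model.spec.input_size),
        "seed": model.seed,
        "epochs_trained": model.epochs_trained,
        "loss_descriptor": model.loss_descriptor,
    }
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    arrays["provenance"] = np.frombuffer(json.dumps(prov).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path) -> Model:
    with np.load(path) as z:
        prov = json.loads(bytes(z["provenance"]).decode())
        spec = NetworkSpec(variant=prov["variant"], n_classes=prov["n_classes"],
                           input_size=tuple(prov["input_size"]))
        model = build_network(spec, seed=prov["seed"])
        for i, p in enumerate(model.params()):
            arr = z[f"param_{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint parameter {i} has shape "
                                 f"{arr.shape}, expected {p.data.shape}")
            p.data = arr.astype(np.float32)
    model.epochs_trained = prov["epochs_trained"]
    model.loss_descriptor = prov["loss_descriptor"]
    return model
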