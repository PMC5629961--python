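"""The two sliding-window pixel classifiers.

Both classifiers share a LeNet-style layout of K = 7 weighted layers: four
valid convolutions (each followed by ReLU, the first three also by 2x2
max-pooling) and three fully connected layers ending in a softmax.  They
read a 101 x 101 single-channel patch and classify its *center* pixel:

* Object-Net  — four classes: benign background, benign gland, malignant
  background, malignant gland (conv 80@11, 96@7, 128@5, 160@3; FC 1024,
  512, 4);
* Separator-Net — two classes: gland-separating structure vs. not
  (conv 64@9, 96@7, 128@5, 160@3; FC 1024, 512, 2).

Training is minibatch SGD with momentum, weight decay and dropout on the
fully connected layers, with early stopping on a held-out validation set.
Inference slides the window with stride 1 (mirror padding at the borders)
and writes one probability distribution per pixel into class probability
maps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .dataset import PatchDataset
from .preprocess import StructureChannel, resample_to

logger = logging.getLogger(__name__)

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainConfig",
    "ClassProbabilityMaps",
    "SeparatorMap",
    "Network",
    "TrainResult",
    "build_network",
    "spatial_size_chain",
    "train_network",
    "predict_maps",
]


@dataclass(frozen=True)
class LayerSpec:
    """One weighted or pooling layer: kind 'conv', 'pool' or 'fc'."""

    kind: str
    units: int = 0      # output channels (conv) or units (fc)
    kernel: int = 0     # conv kernel size


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of a pixel classifier."""

    variant: str
    layers: tuple[LayerSpec, ...]
    patch_size: int = 101
    in_channels: int = 1

    def __post_init__(self):
        kinds = [l.kind for l in self.layers]
        if any(k not in ("conv", "pool", "fc") for k in kinds):
            raise ValueError("layer kinds must be conv/pool/fc")
        if kinds and kinds[-1] != "fc":
            raise ValueError("final layer must be fully connected")

    @property
    def n_conv(self) -> int:
        return sum(l.kind == "conv" for l in self.layers)

    @property
    def n_fc(self) -> int:
        return sum(l.kind == "fc" for l in self.layers)

    @property
    def weighted_layers(self) -> int:
        """K: number of layers carrying learnable weights."""
        return self.n_conv + self.n_fc

    @property
    def output_units(self) -> int:
        return self.layers[-1].units


#: Canonical architectures.  Pooling follows the first three convolutions
#: only; the fourth convolution feeds the fully connected stack directly.
_CANONICAL: dict[str, tuple[LayerSpec, ...]] = {
    "object": (
        LayerSpec("conv", 80, 11), LayerSpec("pool"),
        LayerSpec("conv", 96, 7), LayerSpec("pool"),
        LayerSpec("conv", 128, 5), LayerSpec("pool"),
        LayerSpec("conv", 160, 3),
        LayerSpec("fc", 1024), LayerSpec("fc", 512), LayerSpec("fc", 4),
    ),
    "separator": (
        LayerSpec("conv", 64, 9), LayerSpec("pool"),
        LayerSpec("conv", 96, 7), LayerSpec("pool"),
        LayerSpec("conv", 128, 5), LayerSpec("pool"),
        LayerSpec("conv", 160, 3),
        LayerSpec("fc", 1024), LayerSpec("fc", 512), LayerSpec("fc", 2),
    ),
}


def build_network(variant: str) -> NetworkSpec:
    """Canonical spec of the ``object`` (4-class) or ``separator`` (2-class) net."""
    if variant not in _CANONICAL:
        raise ValueError(f"unknown network variant {variant!r}")
    spec = NetworkSpec(variant=variant, layers=_CANONICAL[variant])
    assert spec.weighted_layers == 7 and spec.n_conv == 4 and spec.n_fc == 3
    return spec


def spatial_size_chain(spec: NetworkSpec) -> list[int]:
    """Spatial size after each conv/pool layer, starting from the patch size.

    Valid convolution shrinks by ``kernel - 1``; pooling halves with floor.
    """
    sizes = [spec.patch_size]
    s = spec.patch_size
    for layer in spec.layers:
        if layer.kind == "conv":
            s = s - layer.kernel + 1
        elif layer.kind == "pool":
            s = s // 2
        else:
            break
        if s < 1:
            raise ValueError("patch too small for this architecture")
        sizes.append(s)
    return sizes


@dataclass
class TrainConfig:
    """Optimization schedule for both networks.

    The learning rate decays linearly from ``eta0`` to ``0.2 * eta0`` over
    the first 100 epochs and stays constant afterwards; momentum rises
    linearly from 0.8 to 0.99 over the first 50 epochs.  Training stops when
    the validation error has not improved for ``patience_epochs`` epochs (or
    cannot improve further because it reached zero).
    """

    eta0: float = 0.0025
    momentum_start: float = 0.8
    momentum_end: float = 0.99
    momentum_saturation_epoch: int = 50
    lr_saturation_epoch: int = 100
    lr_final_fraction: float = 0.2
    weight_decay: float = 0.005
    dropout: float = 0.5
    batch_size: int = 200
    patience_epochs: int = 20
    max_epochs: int = 200
    train_error_subset: int = 20_000
    seed: int | None = None

    def __post_init__(self):
        if self.eta0 <= 0 or self.weight_decay < 0 or self.batch_size < 1:
            raise ValueError("rates must be positive and batch size >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    def learning_rate(self, epoch: int) -> float:
        t = min(epoch, self.lr_saturation_epoch) / self.lr_saturation_epoch
        return self.eta0 * (1.0 - (1.0 - self.lr_final_fraction) * t)

    def momentum(self, epoch: int) -> float:
        t = min(epoch, self.momentum_saturation_epoch) / self.momentum_saturation_epoch
        return self.momentum_start + (self.momentum_end - self.momentum_start) * t


@dataclass
class ClassProbabilityMaps:
    """Four per-pixel class probability maps I_C0..I_C3 (stacked first axis)."""

    maps: np.ndarray  # (4, H, W)
    scale: float = 1.0

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 3 or self.maps.shape[0] != 4:
            raise ValueError("expected four stacked probability maps")
        if self.maps.min() < -1e-9 or self.maps.max() > 1 + 1e-9:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.maps.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("per-pixel class probabilities must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]


@dataclass
class SeparatorMap:
    """Per-pixel probability of a gland-separating structure, S(x)."""

    map: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.map = np.asarray(self.map, dtype=float)
        if self.map.ndim != 2:
            raise ValueError("separator map must be 2-D")
        if self.map.min() < -1e-9 or self.map.max() > 1 + 1e-9:
            raise ValueError("separator probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.map.shape


class Network:
    """A pixel classifier instantiated from a `NetworkSpec`.

    Weights use a scaled-uniform fan-in initialization drawn from the given
    seed, so two networks built from the same spec and seed are identical.
    """

    def __init__(self, spec: NetworkSpec, seed: int | None = None,
                 dropout: float = 0.5):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list[_nn.Layer] = []
        channels = spec.in_channels
        size = spec.patch_size
        flattened = False
        n_fc_seen = 0
        for layer in spec.layers:
            if layer.kind == "conv":
                self.layers.append(_nn.Conv2D(
                    channels, layer.units, layer.kernel, rng,
                    needs_input_grad=bool(self.layers),
                ))
                self.layers.append(_nn.ReLU())
                channels = layer.units
                size = size - layer.kernel + 1
            elif layer.kind == "pool":
                self.layers.append(_nn.MaxPool2())
                size = size // 2
            else:
                if not flattened:
                    self.layers.append(_nn.Flatten())
                    flattened = True
                    in_units = channels * size * size
                n_fc_seen += 1
                if n_fc_seen > 1 and dropout > 0:
                    self.layers.append(_nn.Dropout(dropout))
                self.layers.append(_nn.Dense(in_units, layer.units, rng))
                if n_fc_seen < spec.n_fc:
                    self.layers.append(_nn.ReLU())
                in_units = layer.units
            if size < 1:
                raise ValueError("patch too small for this architecture")
        #: class values (raster labels) in map order; set during training
        self.class_values: np.ndarray = np.arange(spec.output_units)
        self.trained = False

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch of patches of shape (N, patch, patch)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)
            if d is None:  # the input layer does not propagate further
                break

    def predict_proba(self, patches: np.ndarray, batch: int = 64) -> np.ndarray:
        """Softmax class probabilities (float64, rows sum to 1)."""
        out = []
        for i in range(0, len(patches), batch):
            out.append(_nn.softmax(self.forward(patches[i:i + batch])))
        return np.concatenate(out)

    def predict(self, patches: np.ndarray, batch: int = 64) -> np.ndarray:
        return self.predict_proba(patches, batch=batch).argmax(axis=1)

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "variant": self.spec.variant,
            "layers": [[l.kind, l.units, l.kernel] for l in self.spec.layers],
            "patch_size": self.spec.patch_size,
            "in_channels": self.spec.in_channels,
            "class_values": [int(c) for c in self.class_values],
            "trained": self.trained,
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.params)}
        np.savez_compressed(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            spec = NetworkSpec(
                variant=meta["variant"],
                layers=tuple(LayerSpec(k, u, s) for k, u, s in meta["layers"]),
                patch_size=meta["patch_size"],
                in_channels=meta["in_channels"],
            )
            net = cls(spec, seed=0)
            for i, p in enumerate(net.params):
                p[...] = z[f"param_{i}"]
        net.class_values = np.asarray(meta["class_values"])
        net.trained = meta["trained"]
        return net


@dataclass
class TrainResult:
    network: Network
    history: pd.DataFrame  # epoch, train_error, valid_error, loss
    best_epoch: int
    best_valid_error: float
    stop_reason: str

    def save_history(self, path: str | Path) -> None:
        self.history.to_csv(path, index=False)


def _error_rate(net: Network, patches: np.ndarray, targets: np.ndarray,
                batch: int) -> float:
    pred = net.predict(patches, batch=batch)
    return float(np.mean(pred != targets))


def _micro_batch(spec: NetworkSpec, limit_bytes: float = 2.5e8) -> int:
    """Largest sub-batch whose biggest im2col buffer stays under the limit."""
    worst = 1.0
    size = spec.patch_size
    channels = spec.in_channels
    for layer in spec.layers:
        if layer.kind == "conv":
            out = size - layer.kernel + 1
            worst = max(worst, out * out * channels * layer.kernel ** 2 * 4.0)
            channels, size = layer.units, out
        elif layer.kind == "pool":
            size //= 2
        else:
            break
    return max(1, int(limit_bytes / worst))


def train_network(
    spec: NetworkSpec | Network,
    train: PatchDataset,
    valid: PatchDataset,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train a pixel classifier with early stopping on the validation set.

    Returns the network holding the parameters of the best-validation epoch
    together with the per-epoch error history.  Raises if the dataset's
    class count does not match the spec's output units, or if the loss
    becomes non-finite.
    """
    config = config or TrainConfig()
    net = spec if isinstance(spec, Network) else Network(
        spec, seed=config.seed, dropout=config.dropout
    )
    class_values = np.unique(train.labels)
    if len(class_values) != net.spec.output_units:
        raise ValueError(
            f"dataset has {len(class_values)} classes but the "
            f"{net.spec.variant} network outputs {net.spec.output_units}"
        )
    remap = {int(c): i for i, c in enumerate(class_values)}
    y_train = np.array([remap[int(l)] for l in train.labels])
    y_valid = np.array([remap[int(l)] for l in valid.labels])
    net.class_values = class_values

    rng = np.random.default_rng(config.seed)
    opt = _nn.SGDMomentum(net.params, weight_decay=config.weight_decay)
    micro = _micro_batch(net.spec)
    n = len(train)
    sub = min(n, config.train_error_subset)
    train_eval_idx = rng.choice(n, size=sub, replace=False) if sub < n else np.arange(n)

    best_valid = np.inf
    best_params = [p.copy() for p in net.params]
    best_epoch = -1
    rows = []
    stop_reason = "max_epochs"
    for epoch in range(config.max_epochs):
        lr = config.learning_rate(epoch)
        mom = config.momentum(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            # accumulate gradients over micro-batches, then one update
            acc = [np.zeros_like(p) for p in net.params]
            loss_sum = 0.0
            for ms in range(0, len(idx), micro):
                mi = idx[ms:ms + micro]
                logits = net.forward(train.patches[mi], train=True, rng=rng)
                loss, dlogits = _nn.softmax_cross_entropy(logits, y_train[mi])
                net.backward(dlogits * (len(mi) / len(idx)))
                for a, g in zip(acc, net.grads):
                    a += g
                loss_sum += loss * len(mi)
            if not np.isfinite(loss_sum):
                raise FloatingPointError("training loss diverged (non-finite)")
            opt.step(acc, lr=lr, momentum=mom)
            epoch_loss += loss_sum / len(idx)
            n_batches += 1

        train_err = _error_rate(net, train.patches[train_eval_idx],
                                y_train[train_eval_idx], batch=micro)
        valid_err = _error_rate(net, valid.patches, y_valid, batch=micro)
        rows.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
                     "train_error": train_err, "valid_error": valid_err})
        logger.info("epoch %d: loss %.4f train %.4f valid %.4f",
                    epoch, rows[-1]["loss"], train_err, valid_err)
        if valid_err < best_valid:
            best_valid = valid_err
            best_epoch = epoch
            best_params = [p.copy() for p in net.params]
        if best_valid == 0.0:
            stop_reason = "validation_error_zero"
            break
        if epoch - best_epoch >= config.patience_epochs:
            stop_reason = "patience"
            break

    for p, bp in zip(net.params, best_params):
        p[...] = bp
    net.trained = True
    return TrainResult(
        network=net,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        best_valid_error=float(best_valid),
        stop_reason=stop_reason,
    )


def predict_maps(
    net: Network,
    channel: StructureChannel | np.ndarray,
    stride: int = 1,
    batch: int = 64,
) -> ClassProbabilityMaps | SeparatorMap:
    """Pixel-wise class probability maps by sliding the patch window.

    Every ``stride``-th pixel is classified from the patch centered on it
    (mirror padding at the borders); for ``stride > 1`` the coarse grid is
    bilinearly interpolated back to the full raster and renormalized.  The
    output has the spatial size of the input channel: a `ClassProbabilityMaps`
    for a four-class net, a `SeparatorMap` for a two-class net.
    """
    if not net.trained:
        raise RuntimeError("network has not been trained")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    scale = getattr(channel, "scale", 1.0)
    pixels = np.asarray(getattr(channel, "pixels", channel), dtype=np.float32) / 255.0
    h, w = pixels.shape
    half = net.spec.patch_size // 2
    padded = np.pad(pixels, half, mode="reflect")
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    probs = np.empty((len(rows), len(cols), net.spec.output_units))
    patch = net.spec.patch_size
    buf = np.empty((len(cols), patch, patch), dtype=np.float32)
    for ri, r in enumerate(rows):
        for ci, c in enumerate(cols):
            buf[ci] = padded[r:r + patch, c:c + patch]
        probs[ri] = net.predict_proba(buf, batch=batch)
    if stride > 1:
        full = np.stack(
            [resample_to(probs[:, :, k], (h, w), mode="bilinear")
             for k in range(probs.shape[2])], axis=0)
        full = np.clip(full, 0, None)
        full /= full.sum(axis=0, keepdims=True)
    else:
        full = probs.transpose(2, 0, 1)
    if net.spec.output_units == 4:
        return ClassProbabilityMaps(maps=full, scale=scale)
    if net.spec.output_units == 2:
        # class order follows the trained class values: index 1 = separator
        return SeparatorMap(map=full[1], scale=scale)
    raise ValueError("expected a 4-class object net or 2-class separator net")
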