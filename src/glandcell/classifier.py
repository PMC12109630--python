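"""The GlandNet classifier family: topology, augmentation, training, prediction.

GlandNet is a VGG16-lineage network: five convolution blocks (13 conv
layers, 3x3, ReLU) each followed by max pooling, then global average
pooling, dense -> Gaussian noise -> dense -> Gaussian noise -> dense(2)
and a softmax prediction layer — 24 layers of which 16 carry weights
(13 conv + 3 dense).  A ``width_scale`` multiplier shrinks every width
for desk-scale runs on synthetic scenes; the layer sequence is invariant
to scaling.

Patches are standardized with per-dataset mean/std computed on the
training cohort (stored on the model for reproducible prediction).
A nucleus is called glandular when its predicted gland probability is
strictly greater than the decision threshold (default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .cmg import BiopsyContainer
from .nn import softmax, weighted_cross_entropy

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "AugmentPolicy",
    "GlandNet",
    "build_model",
    "augment",
    "train",
    "predict_proba",
    "classify",
    "softmax",
    "weighted_cross_entropy",
    "stack_container_data",
]

VGG_CONV_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))


@dataclass(frozen=True)
class ModelSpec:
    """Topology parameters.  The defaults reproduce the full-size network."""

    conv_blocks: tuple[tuple[int, ...], ...] = VGG_CONV_BLOCKS
    head_widths: tuple[int, int] = (256, 64)
    noise_sigma: float = 1.0
    width_scale: float = 1.0
    input_size: int = 256
    channels: int = 1
    pretrained_init: bool = False
    pretrained_weights: str | None = None
    allow_any_input_size: bool = False

    def validate(self) -> None:
        if not 0 < self.width_scale <= 1:
            raise ValueError(f"width_scale must be in (0, 1], got {self.width_scale}")
        if self.input_size not in (128, 256) and not self.allow_any_input_size:
            raise ValueError(
                f"input_size {self.input_size} not in {{128, 256}} "
                "(set allow_any_input_size for scaled runs)"
            )
        n_pools = len(self.conv_blocks)
        if self.input_size % (2**n_pools) or self.input_size < 2**n_pools:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{n_pools} pooling stages"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")

    def scaled_widths(self) -> tuple[tuple[int, ...], ...]:
        return tuple(
            tuple(max(1, int(round(w * self.width_scale))) for w in blk)
            for blk in self.conv_blocks
        )

    def scaled_head(self) -> tuple[int, int]:
        return tuple(max(1, int(round(w * self.width_scale))) for w in self.head_widths)

    @property
    def n_conv_layers(self) -> int:
        return sum(len(b) for b in self.conv_blocks)

    @property
    def n_weight_layers(self) -> int:
        return self.n_conv_layers + 3  # three dense layers in the head

    @property
    def n_layers(self) -> int:
        # conv + pool-per-block + GAP + two noise layers + three dense layers
        return self.n_conv_layers + len(self.conv_blocks) + 1 + 2 + 3


@dataclass
class AugmentPolicy:
    """Stochastic patch augmentation; composition order flip->rotate->zoom->shift.

    Pixels exposed by rotation/zoom/shift are mirror-filled, consistent
    with the patching border policy.
    """

    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotation_degrees: float = 45.0
    zoom_fraction: float = 0.2
    width_shift_fraction: float = 0.2
    height_shift_fraction: float = 0.2

    def __post_init__(self):
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must be in [0, 1]")
        for f in (self.zoom_fraction, self.width_shift_fraction, self.height_shift_fraction):
            if not 0 <= f < 1:
                raise ValueError("zoom/shift fractions must be in [0, 1)")
        if self.rotation_degrees < 0:
            raise ValueError("rotation_degrees must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentPolicy":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    @classmethod
    def flips_only(cls) -> "AugmentPolicy":
        return cls(0.5, 0.5, 0.0, 0.0, 0.0, 0.0)


@dataclass
class TrainConfig:
    """Optimization settings; defaults are the full-scale study settings.

    Adam with beta1=0.9 / beta2=0.999 and a deliberately low initial
    learning rate (1e-5, searched down from 1e-2); batch 128 (searched
    32..128); 100 epochs (searched 50..100); head-noise sigma around
    1.0-1.5 (searched 0.5..3.5).  ``class_weights=None`` means inverse
    class frequency computed on the training data.
    """

    learning_rate: float = 1e-5
    batch_size: int = 128
    epochs: int = 100
    beta1: float = 0.9
    beta2: float = 0.999
    class_weights: tuple[float, float] | None = None
    decision_threshold: float = 0.5
    augment: AugmentPolicy | None = field(default_factory=AugmentPolicy.flips_only)
    epoch_selection: str = "final"  # or "best_val"
    lr_schedule: str = "constant"  # or "cosine"
    grad_clip: float | None = None  # global gradient norm cap
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.class_weights is not None and any(w <= 0 for w in self.class_weights):
            raise ValueError("class_weights must be positive")
        if self.epoch_selection not in ("final", "best_val"):
            raise ValueError("epoch_selection must be 'final' or 'best_val'")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if self.grad_clip is not None and self.grad_clip <= 0:
            raise ValueError("grad_clip must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0, epochs: int = 14) -> "TrainConfig":
        """Settings for scaled synthetic runs (small model, hundreds of patches).

        Training a 13-conv stack from random init on a few hundred
        patches needs a hotter but damped optimizer than the full-scale
        recipe: cosine-decayed lr with gradient-norm clipping.
        """
        return cls(
            learning_rate=4e-4,
            batch_size=32,
            epochs=epochs,
            augment=AugmentPolicy.flips_only(),
            lr_schedule="cosine",
            grad_clip=5.0,
            seed=seed,
        )


class GlandNet:
    """A built network plus its normalization statistics and metadata."""

    def __init__(self, spec: ModelSpec, net: nn.Sequential, seed: int):
        self.spec = spec
        self.net = net
        self.seed = seed
        self.norm_mean = 0.5  # of pixels rescaled to [0, 1]
        self.norm_std = 0.25
        self.class_weights = np.array([1.0, 1.0])
        self.history: dict[str, list[float]] | None = None

    # -- topology ---------------------------------------------------------
    @property
    def layer_kinds(self) -> list[str]:
        return self.net.layer_kinds

    @property
    def n_weight_layers(self) -> int:
        return len(self.net.weight_layers)

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def conv_param_count(self) -> int:
        return sum(l.n_params for l in self.net.layers if isinstance(l, nn.Conv3x3))

    # -- inference --------------------------------------------------------
    def normalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32) / 255.0
        return (x - self.norm_mean) / self.norm_std

    def predict_proba_array(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Gland probability for a raw (N, H, W[, C]) uint8/float patch stack."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[..., None]
        xn = self.normalize(x)
        out = np.empty(len(xn), dtype=np.float64)
        for i in range(0, len(xn), batch_size):
            logits = self.net.forward(xn[i : i + batch_size], training=False)
            out[i : i + batch_size] = softmax(logits)[:, 1]
        return out

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Checkpoint weights (.npz) plus a JSON topology descriptor (.json)."""
        path = Path(path)
        meta = dict(
            spec=asdict(self.spec),
            seed=self.seed,
            norm_mean=self.norm_mean,
            norm_std=self.norm_std,
            class_weights=self.class_weights.tolist(),
        )
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.net.state_arrays())
        path.with_suffix(path.suffix + ".topology.json").write_text(self.net.topology_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "GlandNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec_dict = meta["spec"]
            spec_dict["conv_blocks"] = tuple(tuple(b) for b in spec_dict["conv_blocks"])
            spec_dict["head_widths"] = tuple(spec_dict["head_widths"])
            spec = ModelSpec(**spec_dict)
            model = build_model(spec, seed=meta["seed"])
            model.net.load_state_arrays({k: data[k] for k in data.files if k != "__meta__"})
        model.norm_mean = meta["norm_mean"]
        model.norm_std = meta["norm_std"]
        model.class_weights = np.asarray(meta["class_weights"])
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> GlandNet:
    """Instantiate the network described by ``spec`` with seeded random init."""
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = spec.channels
    for block in spec.scaled_widths():
        for width in block:
            layers.append(nn.Conv3x3(c_in, width, rng))
            c_in = width
        layers.append(nn.MaxPool2())
    layers.append(nn.GlobalAvgPool())
    d1, d2 = spec.scaled_head()
    layers.append(nn.Dense(c_in, d1, rng, relu=True))
    layers.append(nn.GaussianNoise(spec.noise_sigma))
    layers.append(nn.Dense(d1, d2, rng, relu=True))
    layers.append(nn.GaussianNoise(spec.noise_sigma))
    layers.append(nn.Dense(d2, 2, rng, relu=False))
    model = GlandNet(spec, nn.Sequential(layers), seed)
    if spec.pretrained_init:
        if not spec.pretrained_weights:
            raise ValueError(
                "pretrained_init requires a pretrained_weights checkpoint path; "
                "no weight source ships with the package"
            )
        with np.load(spec.pretrained_weights) as data:
            model.net.load_state_arrays(dict(data))
    return model


def augment(patch: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator) -> np.ndarray:
    """Apply the augmentation policy to one square patch.

    Deterministic under the generator state; operations whose parameter
    is zero are skipped exactly (bit-identical pass-through).
    """
    if patch.shape[0] != patch.shape[1]:
        raise ValueError("augment expects a square patch")
    out = patch
    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        out = out[:, ::-1]
    if policy.vflip_prob > 0 and rng.random() < policy.vflip_prob:
        out = out[::-1, :]
    if policy.rotation_degrees > 0:
        angle = rng.uniform(0.0, policy.rotation_degrees)
        out = ndimage.rotate(
            out, angle, axes=(0, 1), reshape=False, order=1, mode="mirror"
        )
    if policy.zoom_fraction > 0:
        factor = 1.0 + rng.uniform(-policy.zoom_fraction, policy.zoom_fraction)
        size = out.shape[0]
        center = (size - 1) / 2.0
        matrix = np.eye(out.ndim)
        matrix[0, 0] = matrix[1, 1] = 1.0 / factor
        offset = np.zeros(out.ndim)
        offset[:2] = center - center / factor
        out = ndimage.affine_transform(out, matrix, offset=offset, order=1, mode="mirror")
    if policy.width_shift_fraction > 0 or policy.height_shift_fraction > 0:
        size = out.shape[0]
        dr = rng.uniform(-policy.height_shift_fraction, policy.height_shift_fraction) * size
        dc = rng.uniform(-policy.width_shift_fraction, policy.width_shift_fraction) * size
        shift = [dr, dc] + [0.0] * (out.ndim - 2)
        out = ndimage.shift(out, shift, order=1, mode="mirror")
    return np.ascontiguousarray(out)


def stack_container_data(
    containers: list[BiopsyContainer],
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Stack labeled records of one or more containers into training arrays.

    Returns ``(X, y, ids)`` with X raw ``(N, size, size, C)`` float32,
    y in {0: stroma, 1: gland} and ids as (biopsy_id, nucleus_id) pairs.
    Records labeled ``unknown`` are skipped.
    """
    xs, ys, ids = [], [], []
    for cont in containers:
        for rec in cont.records:
            if rec.label == "unknown":
                continue
            pix = rec.pixels
            if pix.ndim == 2:
                pix = pix[..., None]
            xs.append(pix.astype(np.float32))
            ys.append(1 if rec.label == "gland" else 0)
            ids.append((cont.biopsy_id, rec.nucleus_id))
    if not xs:
        raise ValueError("no labeled records in the given containers")
    return np.stack(xs), np.asarray(ys, dtype=np.int64), ids


def _epoch_metrics(model: GlandNet, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = np.empty((len(x), 2))
    xn = model.normalize(x)
    for i in range(0, len(x), 128):
        probs[i : i + 128] = softmax(model.net.forward(xn[i : i + 128], training=False))
    onehot = np.eye(2)[y]
    loss = weighted_cross_entropy(onehot, probs, model.class_weights)
    acc = float((probs.argmax(1) == y).mean())
    return loss, acc


def train(
    model: GlandNet,
    data: list[BiopsyContainer] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    val_data: list[BiopsyContainer] | tuple[np.ndarray, np.ndarray] | None = None,
    sample_weights: np.ndarray | None = None,
) -> dict[str, list[float]]:
    """Train in place; returns the per-epoch history.

    ``data`` is either a list of labeled containers or an ``(X, y)``
    pair.  ``sample_weights`` (aligned with the samples) scale each
    sample's loss contribution — used for soft pseudo-labels.  History
    keys: ``loss``, ``accuracy`` and, when validation data is given,
    ``val_loss``, ``val_accuracy`` — one entry per epoch.
    """
    config.validate()
    if isinstance(data, tuple):
        x, y = data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[..., None]
        y = np.asarray(y, dtype=np.int64)
    else:
        x, y, _ = stack_container_data(data)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if sample_weights is not None:
        sample_weights = np.asarray(sample_weights, dtype=np.float64)
        if sample_weights.shape != (len(y),):
            raise ValueError("sample_weights must align with the training samples")
    if val_data is not None:
        if isinstance(val_data, tuple):
            xv, yv = val_data
            xv = np.asarray(xv, dtype=np.float32)
            if xv.ndim == 3:
                xv = xv[..., None]
            yv = np.asarray(yv, dtype=np.int64)
        else:
            xv, yv, _ = stack_container_data(val_data)

    # per-dataset standardization, recorded on the model
    x01 = x / 255.0
    model.norm_mean = float(x01.mean())
    model.norm_std = float(x01.std()) or 1.0

    if config.class_weights is not None:
        weights = np.asarray(config.class_weights, dtype=np.float64)
    else:  # inverse class frequency, normalized to mean 1
        counts = np.bincount(y, minlength=2).astype(np.float64)
        weights = len(y) / (2.0 * counts)
    model.class_weights = weights

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(
        model.net.params(), lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2
    )
    history: dict[str, list[float]] = {"loss": [], "accuracy": []}
    if val_data is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    best_val, best_state = -np.inf, None
    onehot = np.eye(2, dtype=np.float32)

    for _epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * _epoch / config.epochs)
            )
        order = rng.permutation(len(x))
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = x[idx]
            if config.augment is not None:
                batch = np.stack([augment(p, config.augment, rng) for p in batch])
            xb = model.normalize(batch)
            yb = onehot[y[idx]]
            logits = model.net.forward(xb, training=True, rng=rng)
            sw = sample_weights[idx] if sample_weights is not None else None
            loss, grad = nn.softmax_ce_grad(logits, yb, weights, sample_weights=sw)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {_epoch}; try a lower learning rate"
                )
            model.net.backward(grad)
            grads = model.net.grads()
            if config.grad_clip is not None:
                norm = np.sqrt(sum(float(np.square(g).sum()) for g in grads))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    for g in grads:
                        g *= scale
            opt.step(grads)
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(1) == y[idx]).sum())
        history["loss"].append(epoch_loss / len(x))
        history["accuracy"].append(epoch_correct / len(x))
        if val_data is not None:
            vl, va = _epoch_metrics(model, xv, yv)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            if config.epoch_selection == "best_val" and va > best_val:
                best_val = va
                best_state = {k: v.copy() for k, v in model.net.state_arrays().items()}

    if config.epoch_selection == "best_val" and best_state is not None:
        model.net.load_state_arrays(best_state)
    model.history = history
    return history


def predict_proba(model: GlandNet, container: BiopsyContainer) -> np.ndarray:
    """Per-nucleus gland probabilities, order-aligned with the records.

    Probabilities are also stored into each record's ``prediction`` field.
    """
    if container.patch_size != model.spec.input_size:
        raise ValueError(
            f"model expects {model.spec.input_size}-px patches, "
            f"container holds {container.patch_size}-px patches"
        )
    if not container.records:
        return np.empty(0)
    x = np.stack(
        [
            (r.pixels if r.pixels.ndim == 3 else r.pixels[..., None]).astype(np.float32)
            for r in container.records
        ]
    )
    probs = model.predict_proba_array(x)
    for rec, p in zip(container.records, probs):
        rec.prediction = float(p)
    return probs


def classify(p: float | np.ndarray, threshold: float = 0.5):
    """``gland`` iff probability strictly greater than the threshold."""
    arr = np.asarray(p, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("probabilities must be in [0, 1]")
    out = np.where(arr > threshold, "gland", "stroma")
    return str(out) if np.isscalar(p) or arr.ndim == 0 else out
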