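"""Spectral-spatial CNN topology, focal loss and the training loop.

The classifier is a compact four-block network: each block is a 'same'-padded
convolution (3x3x3 kernels in the 3D variant, 3x3 in the 2D variant) with
ReLU and filter counts doubling 4 -> 8 -> 16 -> 32, followed by stride-2
'same' max-pooling and batch normalization.  Global average pooling feeds a
512-unit ReLU dense layer with 10% dropout and a single sigmoid output whose
probability refers to the positive (unhealthy/tumor) class.

The 3D variant treats a calibrated cube as single-channel volumetric input so
kernels slide along both spatial axes and the spectral axis; the 2D variant
folds the bands into input channels so kernels slide over space only.

Training minimizes the class-balanced focal loss

    FL(p_t) = -alpha_t * (1 - p_t)**gamma * log(p_t)

where ``p_t`` is the probability assigned to the true class and ``alpha_t``
is ``alpha`` for positives and ``1 - alpha`` for negatives.  ``gamma = 0``
recovers balanced cross-entropy; ``gamma = 0, alpha_t = 1`` is plain
cross-entropy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .errors import LeakageError, ParameterError, ShapeError, TopologyError
from .metrics import compute_metrics, confusion_from_labels
from .preprocess import PatchSet

__all__ = [
    "TopologySpec",
    "FocalLossParams",
    "TrainConfig",
    "propagate_shapes",
    "conv3d_reference",
    "focal_loss",
    "focal_loss_grad",
    "build_classifier",
    "train_classifier",
    "predict_patches",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS_P = 1e-7  # probability clamp inside the loss


@dataclass(frozen=True)
class TopologySpec:
    """Declarative description of the four-block CNN.

    ``pool_stride`` may differ per axis; the RGB-input 3D variant caps the
    spectral kernel/pool extent at the 3-band axis and uses spectral stride 1.
    """

    variant: str = "3d"  # "3d" | "2d"
    filters: tuple[int, ...] = (4, 8, 16, 32)
    kernel: tuple[int, ...] = (3, 3, 3)
    pool_size: tuple[int, ...] = (3, 3, 3)
    pool_stride: tuple[int, ...] = (2, 2, 2)
    dense_units: int = 512
    dropout: float = 0.1

    def __post_init__(self) -> None:
        nd = 3 if self.variant == "3d" else 2
        if len(self.kernel) != nd or len(self.pool_size) != nd or len(self.pool_stride) != nd:
            raise TopologyError(f"{self.variant} topology needs {nd}-axis kernel/pool specs")
        if len(self.filters) != 4:
            raise TopologyError("the topology has exactly 4 conv/pool/BN blocks")
        for a, b in zip(self.filters, self.filters[1:]):
            if b != 2 * a:
                raise TopologyError("filter counts must double block to block")

    @classmethod
    def default_3d(cls, spectral_extent: int | None = None) -> "TopologySpec":
        """The standard 3D topology; for <=3-band input (synthesized RGB) the
        spectral kernel/pool depth is capped at the band axis and the spectral
        pooling stride drops to 1 so four pooling halvings remain valid."""
        if spectral_extent is not None and spectral_extent <= 3:
            d = max(1, spectral_extent)
            return cls(
                variant="3d",
                kernel=(3, 3, d),
                pool_size=(3, 3, d),
                pool_stride=(2, 2, 1),
            )
        return cls(variant="3d")

    @classmethod
    def default_2d(cls) -> "TopologySpec":
        return cls(variant="2d", kernel=(3, 3), pool_size=(3, 3), pool_stride=(2, 2))


@dataclass(frozen=True)
class FocalLossParams:
    """Focusing parameter gamma >= 0 and class weight alpha in [0, 1]."""

    gamma: float = 2.0
    alpha: float = 0.5
    balanced: bool = True  # False: alpha_t == 1 (plain cross-entropy when gamma == 0)

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ParameterError(f"gamma must be >= 0, got {self.gamma}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ParameterError(f"alpha must lie in [0, 1], got {self.alpha}")

    @classmethod
    def cross_entropy(cls) -> "FocalLossParams":
        return cls(gamma=0.0, alpha=0.5, balanced=False)

    @classmethod
    def balanced_cross_entropy(cls, alpha: float) -> "FocalLossParams":
        return cls(gamma=0.0, alpha=alpha)


@dataclass(frozen=True)
class TrainConfig:
    """Adam/optimization settings, with a scaled-down desk profile.

    The reference profile mirrors the full-scale protocol (batch 128, 100
    epochs, lr 1e-3, 100 px patches, 270 bands); the desk profile trades
    size for CPU-feasible runtimes (16 px patches, 30 bands, 20 epochs,
    batch 32, lr 5e-3 decayed on a cosine schedule).  The raised, decayed
    learning rate compensates for the short schedule and small sample count.
    """

    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 128
    epochs: int = 100
    dropout: float = 0.1
    seed: int = 0
    patch_size: int = 100
    n_bands: int = 270
    lr_schedule: str = "constant"  # "constant" | "cosine"

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ParameterError("learning rate, batch size and epochs must be positive")

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "TrainConfig":
        cfg = cls(
            learning_rate=5e-3,
            batch_size=32,
            epochs=20,
            patch_size=16,
            n_bands=30,
            lr_schedule="cosine",
            seed=seed,
        )
        return replace(cfg, **overrides)


def propagate_shapes(
    spec: TopologySpec, input_dims: tuple[int, int, int]
) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes of the topology applied to an (H, W, B) input.

    'Same' convolution preserves extents; stride-s 'same' pooling maps an
    extent d to ceil(d/s).  Shapes are channels-last, e.g. the first 3D block
    of a (100, 100, 270) input pools to (50, 50, 135, 4).
    """
    h, w, b = input_dims
    if min(h, w, b) <= 0:
        raise TopologyError(f"non-positive input dimension {input_dims}")
    if spec.variant == "3d":
        dims = [h, w, b]
    else:
        dims = [h, w]
    shapes: list[tuple[str, tuple[int, ...]]] = [("input", tuple(input_dims))]
    for i, f in enumerate(spec.filters, start=1):
        shapes.append((f"conv{i}", (*dims, f)))
        dims = [nn.same_pool_output(d, s) for d, s in zip(dims, spec.pool_stride)]
        if min(dims) <= 0:
            raise TopologyError(f"pooling produced non-positive extent at block {i}")
        shapes.append((f"pool{i}", (*dims, f)))
        shapes.append((f"batchnorm{i}", (*dims, f)))
    shapes.append(("global_average_pool", (spec.filters[-1],)))
    shapes.append(("dense", (spec.dense_units,)))
    shapes.append(("dropout", (spec.dense_units,)))
    shapes.append(("output", (1,)))
    return shapes


def conv3d_reference(
    x: np.ndarray,
    kernels: np.ndarray,
    biases: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """Direct sextuple-sum 3D convolution with 'same' padding — a slow oracle.

    ``x`` is (X, Y, Z, C_in); ``kernels`` is (C_in, P, Q, R, F).  Each output
    voxel is the literal sum over input channels and kernel offsets,
    optionally passed through ``max(0, v)``.  Intended only for verifying the
    vectorised backend on tiny tensors.
    """
    x = np.asarray(x, dtype=np.float64)
    kernels = np.asarray(kernels, dtype=np.float64)
    if x.ndim != 4 or kernels.ndim != 5 or kernels.shape[0] != x.shape[-1]:
        raise ShapeError(f"incompatible shapes {x.shape} and {kernels.shape}")
    cin, P, Q, R, F = kernels.shape
    if any(k > d + 2 * ((k - 1) // 2) for k, d in zip((P, Q, R), x.shape[:3])):
        raise ShapeError("kernel larger than the padded input")
    pads = [((k - 1) // 2, k // 2) for k in (P, Q, R)]
    xp = np.pad(x, pads + [(0, 0)])
    X, Y, Z = x.shape[:3]
    out = np.zeros((X, Y, Z, F))
    for j in range(F):
        for xx in range(X):
            for yy in range(Y):
                for zz in range(Z):
                    v = biases[j]
                    for m in range(cin):
                        for p in range(P):
                            for q in range(Q):
                                for r in range(R):
                                    v += kernels[m, p, q, r, j] * xp[xx + p, yy + q, zz + r, m]
                    out[xx, yy, zz, j] = v
    if activation == "relu":
        out = np.maximum(out, 0.0)
    return out


def _pt_at(p: np.ndarray, y: np.ndarray, params: FocalLossParams):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    positive = y == 1
    # clamp p_t from below only: a perfect prediction (p_t = 1) has exactly zero loss
    pt = np.clip(np.where(positive, p, 1.0 - p), _EPS_P, 1.0)
    if params.balanced:
        at = np.where(positive, params.alpha, 1.0 - params.alpha)
    else:
        at = np.ones_like(pt)
    return pt, at


def focal_loss(p, y, params: FocalLossParams):
    """Per-sample focal loss for probabilities ``p`` and labels ``y`` in {-1, 1}.

    Scalar inputs give a scalar; take the mean for a batch loss.
    """
    pt, at = _pt_at(p, y, params)
    loss = -at * (1.0 - pt) ** params.gamma * np.log(pt)
    return loss if loss.ndim else float(loss)


def focal_loss_grad(p, y, params: FocalLossParams):
    """d(loss)/dp, elementwise, consistent with :func:`focal_loss`."""
    pt, at = _pt_at(p, y, params)
    g = params.gamma
    one_m = 1.0 - pt
    if g == 0.0:
        d_pt = -at / pt
    else:
        d_pt = at * (g * one_m ** (g - 1.0) * np.log(pt) - one_m**g / pt)
    sign = np.where(np.asarray(y) == 1, 1.0, -1.0)
    return d_pt * sign


def build_classifier(
    spec: TopologySpec | None,
    variant: str,
    input_dims: tuple[int, int, int],
    seed: int = 0,
) -> nn.Network:
    """Instantiate the topology as a trainable network for (S, S, B) patches."""
    h, w, b = input_dims
    if spec is None:
        spec = TopologySpec.default_3d(b) if variant == "3d" else TopologySpec.default_2d()
    if spec.variant != variant:
        raise TopologyError(f"spec variant {spec.variant!r} does not match {variant!r}")
    propagate_shapes(spec, input_dims)  # raises TopologyError on bad dims
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    in_ch = 1 if variant == "3d" else b
    for f in spec.filters:
        layers.append(nn.ConvND(spec.kernel, in_ch, f, rng))
        layers.append(nn.MaxPoolND(spec.pool_size, spec.pool_stride))
        layers.append(nn.BatchNorm(f))
        in_ch = f
    layers.append(nn.GlobalAveragePool())
    layers.append(nn.Dense(spec.filters[-1], spec.dense_units, rng, activation="relu"))
    layers.append(nn.Dropout(spec.dropout))
    layers.append(nn.Dense(spec.dense_units, 1, rng))
    layers.append(nn.Sigmoid())
    return nn.Network(layers, variant=variant, input_dims=input_dims)


def _as_network_input(values: np.ndarray, variant: str) -> np.ndarray:
    x = np.asarray(values, dtype=np.float32)
    if variant == "3d":
        return x[:, None]  # (N, 1, S, S, B): single volumetric channel
    return np.ascontiguousarray(np.moveaxis(x, -1, 1))  # (N, B, S, S): bands as channels


def _check_input_dims(network: nn.Network, values: np.ndarray) -> None:
    if network.input_dims is not None and tuple(values.shape[1:4]) != tuple(network.input_dims):
        raise ShapeError(
            f"patches of shape {values.shape[1:4]} do not match the model input "
            f"{network.input_dims}"
        )


def train_classifier(
    network: nn.Network,
    train: PatchSet,
    val: PatchSet | None,
    loss: FocalLossParams,
    cfg: TrainConfig,
) -> tuple[nn.Network, pd.DataFrame]:
    """Minimize the mean focal loss with Adam; returns the per-epoch history.

    Train and validation sets must be case-disjoint; any shared case id is a
    hard :class:`LeakageError`.  With identical seed and configuration the
    history is bit-identical between runs.
    """
    if val is not None:
        overlap = train.cases() & val.cases()
        if overlap:
            raise LeakageError(f"cases {sorted(overlap)} appear in both train and val")
    _check_input_dims(network, train.values)
    rng = np.random.default_rng(cfg.seed)
    optimizer = nn.Adam(network, lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2)
    x_all = _as_network_input(train.values, network.variant)
    y_all = train.y
    n = len(train)
    rows = []
    for epoch in range(cfg.epochs):
        if cfg.lr_schedule == "cosine":
            optimizer.lr = cfg.learning_rate * 0.5 * (
                1.0 + math.cos(math.pi * epoch / cfg.epochs)
            )
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            p = network.forward(xb, train=True, rng=rng)[:, 0]
            y_pm = 2 * yb - 1
            dldp = focal_loss_grad(p, y_pm, loss) / len(idx)
            network.backward(dldp.astype(np.float32)[:, None])
            optimizer.step()
        row = {"epoch": epoch}
        for name, split in (("train", train), ("val", val)):
            if split is None:
                continue
            probs = predict_probabilities(network, split)
            y_pm = 2 * split.y - 1
            report = compute_metrics(
                confusion_from_labels(split.labels, np.where(probs > 0.5, "unhealthy", "healthy"))
            )
            row[f"{name}_loss"] = float(np.mean(focal_loss(probs, y_pm, loss)))
            row[f"{name}_accuracy"] = report.accuracy
            row[f"{name}_mcc"] = report.mcc
        rows.append(row)
    return network, pd.DataFrame(rows)


def predict_probabilities(
    network: nn.Network, patches: PatchSet, batch_size: int = 64
) -> np.ndarray:
    """Positive-class probabilities in evaluation mode (no dropout, running BN)."""
    _check_input_dims(network, patches.values)
    x = _as_network_input(patches.values, network.variant)
    outs = [network.forward(x[i : i + batch_size], train=False) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs)[:, 0].astype(float)


def predict_patches(
    network: nn.Network, patches: PatchSet, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and probabilities; unhealthy iff ``p > threshold`` (strict)."""
    probs = predict_probabilities(network, patches)
    labels = np.where(probs > threshold, "unhealthy", "healthy")
    return labels, probs


def save_checkpoint(
    network: nn.Network,
    path: str | Path,
    spec: TopologySpec | None = None,
    loss: FocalLossParams | None = None,
    cfg: TrainConfig | None = None,
) -> Path:
    """Serialize weights as .npz with a JSON sidecar describing the run."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **network.state_dict())
    sidecar = {
        "variant": network.variant,
        "input_dims": network.input_dims,
        "topology": None if spec is None else spec.__dict__,
        "loss": None if loss is None else loss.__dict__,
        "train_config": None if cfg is None else cfg.__dict__,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def load_checkpoint(network: nn.Network, path: str | Path) -> nn.Network:
    with np.load(Path(path), allow_pickle=False) as state:
        network.load_state_dict(dict(state))
    return network
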