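"""Two-layer stacked sparse autoencoder for dimensionality reduction.

Each layer is a single-hidden-layer autoencoder with logistic units,
trained by full-batch gradient descent on

    J = (1/N) sum_n ||x_n - x'_n||^2  +  lambda ||W'||^2
        + beta sum_j KL(rho || rho_hat_j)

where rho_hat_j is the mean activation of hidden unit j over the batch and
KL is the Bernoulli Kullback-Leibler divergence.  The weight-decay term
applies to the decode weights by default (optionally also the encode
weights).  The two layers are pretrained greedily: layer 2 trains on the
hidden codes of layer 1, and ``reduce`` maps features through both
encoders.  Inputs are expected on [0, 1] (the sigmoid output range), i.e.
normalized feature rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .io_core import FeatureMatrix, InvariantError

RHO_EPS = 1e-8  # clamp on mean activations so the KL term stays finite


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AeLayer:
    """One autoencoder layer: encode/decode weights and biases."""

    W: np.ndarray       # n_h x n_x
    W_dec: np.ndarray   # n_x x n_h
    b: np.ndarray       # n_h
    a_bias: np.ndarray  # n_x

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.W_dec = np.asarray(self.W_dec, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.a_bias = np.asarray(self.a_bias, dtype=float)
        n_h, n_x = self.W.shape
        if self.W_dec.shape != (n_x, n_h) or self.b.shape != (n_h,) \
                or self.a_bias.shape != (n_x,):
            raise InvariantError("inconsistent layer shapes")
        for arr in (self.W, self.W_dec, self.b, self.a_bias):
            if not np.all(np.isfinite(arr)):
                raise InvariantError("non-finite layer parameter")

    @property
    def n_x(self) -> int:
        return self.W.shape[1]

    @property
    def n_h(self) -> int:
        return self.W.shape[0]


@dataclass
class SaeHyper:
    weight_decay: float = 1e-4     # lambda
    sparsity_weight: float = 0.1   # beta
    sparsity_target: float = 0.05  # rho
    epochs: int = 500
    learning_rate: float = 0.1
    decay_encode_weights: bool = False


@dataclass
class AutoencoderStack:
    layer1: AeLayer
    layer2: AeLayer
    hyper: SaeHyper
    seed: int
    final_loss: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if self.layer2.n_x != self.layer1.n_h:
            raise InvariantError("layer2 input must equal layer1 hidden size")


def encode(x: np.ndarray, layer: AeLayer) -> np.ndarray:
    """h = sigm(b + W x); accepts a vector or a batch of rows."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.n_x:
        raise InvariantError(
            f"input length {x.shape[-1]} != layer n_x {layer.n_x}"
        )
    return sigmoid(x @ layer.W.T + layer.b)


def decode(h: np.ndarray, layer: AeLayer) -> np.ndarray:
    """x' = sigm(a + W' h); accepts a vector or a batch of rows."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != layer.n_h:
        raise InvariantError(
            f"code length {h.shape[-1]} != layer n_h {layer.n_h}"
        )
    return sigmoid(h @ layer.W_dec.T + layer.a_bias)


def _kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    rho_hat = np.clip(rho_hat, RHO_EPS, 1.0 - RHO_EPS)
    return (rho * np.log(rho / rho_hat)
            + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat)))


def ae_objective(batch: np.ndarray, layer: AeLayer,
                 weight_decay: float, sparsity_weight: float,
                 sparsity_target: float,
                 decay_encode_weights: bool = False
                 ) -> tuple[float, float, float, float]:
    """(total J, reconstruction mse, weight term, sparsity term).

    mse is the mean over the batch of the squared reconstruction error
    norm; the weight term is lambda * ||W'||^2 (plus ||W||^2 when encode
    decay is enabled); the sparsity term is beta * sum_j KL(rho||rho_hat_j)
    with rho_hat clamped away from {0, 1}.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    if X.shape[0] == 0:
        raise InvariantError("empty batch")
    if not 0 < sparsity_target < 1:
        raise InvariantError("sparsity target must be in (0, 1)")
    H = encode(X, layer)
    Xr = decode(H, layer)
    mse = float(np.sum((X - Xr) ** 2) / X.shape[0])
    wterm = float(np.sum(layer.W_dec ** 2))
    if decay_encode_weights:
        wterm += float(np.sum(layer.W ** 2))
    wterm *= weight_decay
    rho_hat = H.mean(axis=0)
    sterm = float(sparsity_weight * np.sum(_kl_bernoulli(sparsity_target,
                                                         rho_hat)))
    return mse + wterm + sterm, mse, wterm, sterm


def ae_gradient(batch: np.ndarray, layer: AeLayer,
                weight_decay: float, sparsity_weight: float,
                sparsity_target: float,
                decay_encode_weights: bool = False
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradient of the objective w.r.t. (W, W_dec, b, a_bias)."""
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    N = X.shape[0]
    H = encode(X, layer)                      # N x n_h
    Xr = decode(H, layer)                     # N x n_x
    # reconstruction path
    delta_out = (2.0 / N) * (Xr - X) * Xr * (1.0 - Xr)        # N x n_x
    gW_dec = delta_out.T @ H + 2.0 * weight_decay * layer.W_dec
    ga = delta_out.sum(axis=0)
    dH = delta_out @ layer.W_dec                               # N x n_h
    # sparsity path (through rho_hat = mean of H)
    rho_hat = np.clip(H.mean(axis=0), RHO_EPS, 1.0 - RHO_EPS)
    dkl = (-sparsity_target / rho_hat
           + (1.0 - sparsity_target) / (1.0 - rho_hat))
    dH = dH + sparsity_weight * dkl / N
    delta_hid = dH * H * (1.0 - H)                             # N x n_h
    gW = delta_hid.T @ X
    if decay_encode_weights:
        gW = gW + 2.0 * weight_decay * layer.W
    gb = delta_hid.sum(axis=0)
    return gW, gW_dec, gb, ga


def init_layer(n_x: int, n_h: int, seed: int) -> AeLayer:
    """Small symmetric uniform init (Glorot-style scale), zero biases."""
    rng = np.random.default_rng(seed)
    r = np.sqrt(6.0 / (n_x + n_h))
    return AeLayer(
        W=rng.uniform(-r, r, size=(n_h, n_x)),
        W_dec=rng.uniform(-r, r, size=(n_x, n_h)),
        b=np.zeros(n_h),
        a_bias=np.zeros(n_x),
    )


def train_layer(data: np.ndarray, n_hidden: int,
                hyper: SaeHyper | None = None, seed: int = 0
                ) -> tuple[AeLayer, list[float]]:
    """Full-batch gradient descent on one layer; returns (layer, loss curve).

    Raises if the loss ever becomes non-finite, naming the epoch.
    """
    hyper = hyper or SaeHyper()
    X = np.atleast_2d(np.asarray(data, dtype=float))
    if n_hidden < 1:
        raise InvariantError("n_hidden must be >= 1")
    layer = init_layer(X.shape[1], n_hidden, seed)
    args = (hyper.weight_decay, hyper.sparsity_weight, hyper.sparsity_target,
            hyper.decay_encode_weights)
    losses = [ae_objective(X, layer, *args)[0]]
    lr = hyper.learning_rate
    for epoch in range(hyper.epochs):
        gW, gWd, gb, ga = ae_gradient(X, layer, *args)
        layer = AeLayer(
            W=layer.W - lr * gW,
            W_dec=layer.W_dec - lr * gWd,
            b=layer.b - lr * gb,
            a_bias=layer.a_bias - lr * ga,
        )
        loss = ae_objective(X, layer, *args)[0]
        if not np.isfinite(loss):
            raise InvariantError(
                f"training diverged (non-finite loss) at epoch {epoch + 1}"
            )
        losses.append(loss)
    return layer, losses


def fit_stack(fm: FeatureMatrix | np.ndarray, h1: int, h2: int,
              hyper: SaeHyper | None = None, seed: int = 0
              ) -> AutoencoderStack:
    """Greedy pretraining: layer 1 on the features, layer 2 on its codes."""
    hyper = hyper or SaeHyper()
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, float)
    layer1, losses1 = train_layer(X, h1, hyper, seed)
    codes = encode(X, layer1)
    layer2, losses2 = train_layer(codes, h2, hyper, seed + 1)
    return AutoencoderStack(
        layer1=layer1, layer2=layer2, hyper=hyper, seed=seed,
        final_loss=(losses1[-1], losses2[-1]),
    )


def reduce(fm: FeatureMatrix, stack: AutoencoderStack) -> FeatureMatrix:
    """Map rows through both encoders; output dimension is layer2.n_h."""
    if fm.n_features != stack.layer1.n_x:
        raise InvariantError(
            f"feature dimension {fm.n_features} != stack input "
            f"{stack.layer1.n_x}"
        )
    Z = encode(encode(fm.values, stack.layer1), stack.layer2)
    return FeatureMatrix(
        values=Z,
        feature_names=[f"z{j:02d}" for j in range(stack.layer2.n_h)],
        epoch_ids=list(fm.epoch_ids),
        labels=fm.labels,
    )


def reduce_rows(X: np.ndarray, stack: AutoencoderStack) -> np.ndarray:
    """Array-in/array-out variant of :func:`reduce`."""
    return encode(encode(np.atleast_2d(X), stack.layer1), stack.layer2)


# ---------------------------------------------------------------------------
# persistence: JSON header + plain-text matrices


def save_stack(stack: AutoencoderStack, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "hyper": vars(stack.hyper),
        "seed": stack.seed,
        "final_loss": list(stack.final_loss),
        "shapes": {
            "layer1": [stack.layer1.n_h, stack.layer1.n_x],
            "layer2": [stack.layer2.n_h, stack.layer2.n_x],
        },
    }
    (path / "stack.json").write_text(json.dumps(header, indent=1))
    for name, layer in (("layer1", stack.layer1), ("layer2", stack.layer2)):
        for part in ("W", "W_dec", "b", "a_bias"):
            np.savetxt(path / f"{name}.{part}.txt",
                       np.atleast_2d(getattr(layer, part)), fmt="%.17g")


def load_stack(path: str | Path) -> AutoencoderStack:
    path = Path(path)
    header = json.loads((path / "stack.json").read_text())

    def _layer(name: str) -> AeLayer:
        return AeLayer(
            W=np.loadtxt(path / f"{name}.W.txt", ndmin=2),
            W_dec=np.loadtxt(path / f"{name}.W_dec.txt", ndmin=2),
            b=np.loadtxt(path / f"{name}.b.txt", ndmin=2).ravel(),
            a_bias=np.loadtxt(path / f"{name}.a_bias.txt", ndmin=2).ravel(),
        )

    return AutoencoderStack(
        layer1=_layer("layer1"),
        layer2=_layer("layer2"),
        hyper=SaeHyper(**header["hyper"]),
        seed=header["seed"],
        final_loss=tuple(header["final_loss"]),
    )
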