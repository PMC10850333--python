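"""1D convolutional regression network for full-spectrum impurity prediction.

Architecture: three stride-1 same-padded 1D convolutions with channel counts
(16, 64, 48), an activation after every conv stage, one average-pooling
stage (window 2, stride 2), then a single-node linear head on the flattened
feature map.  Implemented directly on NumPy with hand-written backprop so
training is deterministic, dependency-light, and finite-difference checkable.

Training uses mini-batch Adam (lr 1e-3, 200 epochs, batch size 8 by
default) with a log-of-MSE loss by default; a standard MSLE and plain MSE
variant are selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import evaluate_split
from .preprocess import PreprocessConfig, apply_preprocess

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainingHistory",
    "CottonNet",
    "build_cotton_net",
    "msle_loss",
    "train_cotton_net",
    "predict_cotton_net",
    "run_activation_ablation",
    "ABLATION_PREPROCESSORS",
    "ABLATION_ACTIVATIONS",
]

LOSS_VARIANTS = ("log_mse", "standard_msle", "mse")
ACTIVATIONS = ("selu", "relu", "sigmoid")

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


@dataclass(frozen=True)
class NetworkSpec:
    input_length: int = 125
    conv_channels: tuple[int, int, int] = (16, 64, 48)
    kernel_size: int = 3
    pool_window: int = 2
    pool_stride: int = 2
    activation: str = "selu"

    def __post_init__(self) -> None:
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three conv stages are required")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.input_length < max(self.kernel_size, self.pool_window):
            raise ValueError(
                f"input_length {self.input_length} below receptive-field minimum "
                f"{max(self.kernel_size, self.pool_window)}"
            )

    @property
    def pooled_length(self) -> int:
        return (self.input_length - self.pool_window) // self.pool_stride + 1


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    max_epochs: int = 200
    batch_size: int = 8
    loss_variant: str = "log_mse"
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")
        if self.loss_variant not in LOSS_VARIANTS:
            raise ValueError(f"loss_variant must be one of {LOSS_VARIANTS}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)


# ---------------------------------------------------------------------------
# activations

def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "selu":
        return _SELU_LAMBDA * np.where(z > 0, z, _SELU_ALPHA * (np.exp(np.minimum(z, 0.0)) - 1.0))
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(name)


def _dact(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Derivative w.r.t. pre-activation z, given activation output a."""
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "selu":
        return np.where(z > 0, _SELU_LAMBDA, a + _SELU_LAMBDA * _SELU_ALPHA)
    if name == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(name)


def _init_std(activation: str, fan_in: int, fan_out: int) -> float:
    if activation == "selu":  # LeCun normal
        return float(np.sqrt(1.0 / fan_in))
    if activation == "relu":  # Kaiming normal
        return float(np.sqrt(2.0 / fan_in))
    return float(np.sqrt(2.0 / (fan_in + fan_out)))  # Xavier normal for sigmoid


# ---------------------------------------------------------------------------
# conv primitives

def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded stride-1 conv. x (B,C,L), W (O,C,k) -> out (B,O,L)."""
    k = W.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    sw = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
    out = np.einsum("bclt,oct->bol", sw, W, optimize=True) + b[None, :, None]
    return out, (xp, sw)


def _conv1d_backward(gout: np.ndarray, cache, W: np.ndarray, x_shape):
    xp, sw = cache
    k = W.shape[2]
    pad = k // 2
    L = x_shape[2]
    dW = np.einsum("bol,bclt->oct", gout, sw, optimize=True)
    db = gout.sum(axis=(0, 2))
    dxp = np.zeros_like(xp)
    for t in range(k):
        dxp[:, :, t : t + L] += np.einsum("bol,oc->bcl", gout, W[:, :, t], optimize=True)
    dx = dxp[:, :, pad : pad + L]
    return dx, dW, db


class CottonNet:
    """The network with explicit parameter arrays and hand-written backprop."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        c1, c2, c3 = spec.conv_channels
        k = spec.kernel_size
        flat = c3 * spec.pooled_length
        rng = np.random.default_rng(seed)

        def w(shape, fan_in, fan_out):
            return rng.normal(0.0, _init_std(spec.activation, fan_in, fan_out), size=shape)

        self.params = {
            "W1": w((c1, 1, k), 1 * k, c1 * k),
            "b1": np.zeros(c1),
            "W2": w((c2, c1, k), c1 * k, c2 * k),
            "b2": np.zeros(c2),
            "W3": w((c3, c2, k), c2 * k, c3 * k),
            "b3": np.zeros(c3),
            "Wf": w((1, flat), flat, 1),
            "bf": np.zeros(1),
        }

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward ----------------------------------------------------------
    def forward(self, X: np.ndarray, cache: bool = False):
        spec = self.spec
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != spec.input_length:
            raise ValueError(
                f"expected spectra of length {spec.input_length}, got {X.shape[1]}"
            )
        act = spec.activation
        x0 = X[:, None, :]  # (B,1,L)
        z1, c1 = _conv1d_forward(x0, self.params["W1"], self.params["b1"])
        a1 = _act(act, z1)
        z2, c2 = _conv1d_forward(a1, self.params["W2"], self.params["b2"])
        a2 = _act(act, z2)
        z3, c3 = _conv1d_forward(a2, self.params["W3"], self.params["b3"])
        a3 = _act(act, z3)
        # average pool window/stride from spec (window 2, stride 2 default)
        wdw, st = spec.pool_window, spec.pool_stride
        Lo = spec.pooled_length
        idx = np.arange(Lo) * st
        pooled = np.mean(
            np.stack([a3[:, :, idx + t] for t in range(wdw)], axis=0), axis=0
        )  # (B,C3,Lo)
        flat = pooled.reshape(X.shape[0], -1)
        yhat = flat @ self.params["Wf"].T + self.params["bf"]  # (B,1)
        if not cache:
            return yhat.ravel()
        caches = {
            "x0": x0, "z1": z1, "a1": a1, "c1": c1,
            "z2": z2, "a2": a2, "c2": c2,
            "z3": z3, "a3": a3, "c3": c3,
            "flat": flat, "idx": idx,
        }
        return yhat.ravel(), caches

    # -- backward ---------------------------------------------------------
    def backward(self, dyhat: np.ndarray, caches) -> dict[str, np.ndarray]:
        """Gradients of the loss given d loss / d yhat (shape (B,))."""
        spec = self.spec
        act = spec.activation
        g = np.asarray(dyhat, dtype=float).reshape(-1, 1)  # (B,1)
        grads = {}
        grads["Wf"] = g.T @ caches["flat"]
        grads["bf"] = g.sum(axis=0)
        dflat = g @ self.params["Wf"]  # (B, flat)
        B = g.shape[0]
        c3n = spec.conv_channels[2]
        Lo = spec.pooled_length
        dpooled = dflat.reshape(B, c3n, Lo)
        da3 = np.zeros_like(caches["a3"])
        idx = caches["idx"]
        for t in range(spec.pool_window):
            np.add.at(da3, (slice(None), slice(None), idx + t), dpooled / spec.pool_window)
        dz3 = da3 * _dact(act, caches["z3"], caches["a3"])
        da2, grads["W3"], grads["b3"] = _conv1d_backward(
            dz3, caches["c3"], self.params["W3"], caches["a2"].shape
        )
        dz2 = da2 * _dact(act, caches["z2"], caches["a2"])
        da1, grads["W2"], grads["b2"] = _conv1d_backward(
            dz2, caches["c2"], self.params["W2"], caches["a1"].shape
        )
        dz1 = da1 * _dact(act, caches["z1"], caches["a1"])
        _, grads["W1"], grads["b1"] = _conv1d_backward(
            dz1, caches["c1"], self.params["W1"], caches["x0"].shape
        )
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig):
        yhat, caches = self.forward(X, cache=True)
        loss, dyhat = msle_loss(
            yhat, y, variant=cfg.loss_variant, epsilon=cfg.epsilon, with_grad=True
        )
        return loss, self.backward(dyhat, caches)


def build_cotton_net(spec: NetworkSpec = NetworkSpec(), seed: int = 0) -> CottonNet:
    """Construct a seeded, activation-appropriately initialized network."""
    return CottonNet(spec, seed=seed)


def msle_loss(
    yhat: np.ndarray,
    y: np.ndarray,
    variant: str = "log_mse",
    epsilon: float = 1e-8,
    with_grad: bool = False,
):
    """Training loss.  ``log_mse`` is log(mean squared error + epsilon);
    ``standard_msle`` is mean((log1p(yhat) - log1p(y))^2); ``mse`` is plain MSE.
    Natural logarithms throughout."""
    yhat = np.asarray(yhat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if yhat.size == 0 or yhat.size != y.size:
        raise ValueError("inputs must be equal-length and non-empty")
    n = yhat.size
    r = yhat - y
    if variant == "mse":
        loss = float(np.mean(r**2))
        grad = 2.0 * r / n
    elif variant == "log_mse":
        mse = float(np.mean(r**2))
        loss = float(np.log(mse + epsilon))
        grad = 2.0 * r / (n * (mse + epsilon))
    elif variant == "standard_msle":
        if np.any(yhat <= -1) or np.any(y <= -1):
            raise ValueError("standard_msle requires y and yhat > -1")
        d = np.log1p(yhat) - np.log1p(y)
        loss = float(np.mean(d**2))
        grad = 2.0 * d / ((1.0 + yhat) * n)
    else:
        raise ValueError(f"unknown loss variant {variant!r}")
    return (loss, grad) if with_grad else loss


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_cotton_net(
    X_train: np.ndarray,
    y_train: np.ndarray,
    spec: NetworkSpec = NetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[CottonNet, TrainingHistory]:
    """Mini-batch Adam training; deterministic given ``cfg.seed``.

    The per-epoch training loss recorded in the history is the loss over the
    full training block under the current weights at epoch end.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X_train and y_train disagree on sample count")
    net = build_cotton_net(spec, seed=cfg.seed)
    opt = _Adam(net.params, cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history = TrainingHistory()
    n = y.size
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            batch = order[lo : lo + cfg.batch_size]
            loss, grads = net.loss_and_grads(X[batch], y[batch], cfg)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            opt.step(net.params, grads)
        epoch_loss = msle_loss(
            net.forward(X), y, variant=cfg.loss_variant, epsilon=cfg.epsilon
        )
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(f"non-finite training loss at epoch {epoch + 1}")
        history.train_loss.append(float(epoch_loss))
        if X_val is not None:
            history.val_loss.append(
                float(
                    msle_loss(
                        net.forward(X_val),
                        y_val,
                        variant=cfg.loss_variant,
                        epsilon=cfg.epsilon,
                    )
                )
            )
    return net, history


def predict_cotton_net(model: CottonNet, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass."""
    return model.forward(np.atleast_2d(np.asarray(X, dtype=float)))


# ---------------------------------------------------------------------------
# activation/preprocessing ablation

ABLATION_PREPROCESSORS = ("sg", "normalization", "snv")
ABLATION_ACTIVATIONS = ("selu", "relu", "sigmoid")
_PRETTY = {
    "sg": "SG",
    "normalization": "Normalization",
    "snv": "SNV",
    "selu": "SELU",
    "relu": "ReLU",
    "sigmoid": "Sigmoid",
}


def run_activation_ablation(
    data,
    split,
    cfg: TrainConfig = TrainConfig(),
    spec: NetworkSpec | None = None,
    preprocessors=ABLATION_PREPROCESSORS,
    activations=ABLATION_ACTIVATIONS,
) -> list[dict]:
    """Preprocessing x activation grid on full-spectrum input.

    Returns one row per combination with calibration/prediction R and RMSE
    (columns ``model``, ``R_C``, ``RMSE_C``, ``R_P``, ``RMSE_P``).
    """
    X = data.reflectance
    y = data.target
    tr = list(split.train)
    te = list(split.test)
    if spec is None:
        spec = NetworkSpec(input_length=data.n_channels)
    rows = []
    for prep in preprocessors:
        Xtr, Xte = apply_preprocess(PreprocessConfig(method=prep), X[tr], X[te])
        for act in activations:
            net, history = train_cotton_net(
                Xtr, y[tr], spec=replace(spec, activation=act), cfg=cfg
            )
            cal = evaluate_split(y[tr], net.forward(Xtr), "train")
            prd = evaluate_split(y[te], net.forward(Xte), "test")
            rows.append(
                {
                    "model": f"{_PRETTY[prep]} + {_PRETTY[act]}",
                    "preprocess": prep,
                    "activation": act,
                    "R_C": cal.r,
                    "RMSE_C": cal.rmse,
                    "R_P": prd.r,
                    "RMSE_P": prd.rmse,
                    "epochs": history.epochs_run,
                    "final_train_loss": history.train_loss[-1],
                }
            )
    return rows
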