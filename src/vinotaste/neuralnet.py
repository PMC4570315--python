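"""From-scratch feed-forward network engine for taste regression.

A deliberately small, fully inspectable implementation of the classic
back-propagation family used by the FANN library: per-sample
(incremental) gradient descent, batch gradient descent, iRPROP− with the
standard Riedmiller constants, and Fahlman's QuickProp.  Five activation
functions are supported on any layer: sigmoid, linear, gaussian
``exp(-x^2)``, sin, and cos.

Targets are min-max scaled into a guard band inside the output
activation's range (e.g. sigmoid -> (0.1, 0.9)) before training and
inverse-scaled on prediction, so bounded activations can represent the
extremes of the target without requiring saturated pre-activations.

Losses and gradients use the per-sample error ``E_n = 1/2 (o_n - t_n)^2``;
the batch gradient is the exact sum of the per-sample gradients (an
identity exercised by the test suite), with trainers applying their own
normalisation convention on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "ACTIVATION_KINDS",
    "ALGORITHMS",
    "AnnConfig",
    "AnnModel",
    "TrainingDivergedError",
    "activation",
    "activation_derivative",
    "init_model",
    "forward",
    "predict",
    "gradients",
    "train",
    "fit_regressor",
    "scale_targets",
    "unscale_outputs",
]

ACTIVATION_KINDS = ("sigmoid", "linear", "gaussian", "sin", "cos")
ALGORITHMS = ("incremental", "batch", "rprop", "quickprop")

#: Target guard band inside each output activation's reachable range.
OUTPUT_BANDS: dict[str, tuple[float, float]] = {
    "sigmoid": (0.1, 0.9),
    "gaussian": (0.1, 0.9),
    "linear": (-0.9, 0.9),
    "sin": (-0.9, 0.9),
    "cos": (-0.9, 0.9),
}

# iRPROP− constants (Riedmiller; FANN defaults)
RPROP_ETA_PLUS = 1.2
RPROP_ETA_MINUS = 0.5
RPROP_DELTA_ZERO = 0.1
RPROP_DELTA_MAX = 50.0
RPROP_DELTA_MIN = 1e-6

# QuickProp constants (Fahlman; FANN-style defaults)
QUICKPROP_MU = 1.75
QUICKPROP_DECAY = 1e-4


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def _act(kind: str, x):
    if kind == "sigmoid":
        return expit(x)
    if kind == "linear":
        return np.asarray(x, dtype=float) + 0.0
    if kind == "gaussian":
        return np.exp(-np.square(x))
    if kind == "sin":
        return np.sin(x)
    if kind == "cos":
        return np.cos(x)
    raise ValueError(f"unknown activation kind {kind!r}")


def _dact(kind: str, x):
    if kind == "sigmoid":
        s = expit(x)
        return s * (1.0 - s)
    if kind == "linear":
        return np.ones_like(np.asarray(x, dtype=float))
    if kind == "gaussian":
        return -2.0 * x * np.exp(-np.square(x))
    if kind == "sin":
        return np.cos(x)
    if kind == "cos":
        return -np.sin(x)
    raise ValueError(f"unknown activation kind {kind!r}")


def activation(kind: str, x: float) -> float:
    """Evaluate one activation function at ``x``."""
    return float(_act(kind, np.asarray(x, dtype=float)))


def activation_derivative(kind: str, x: float) -> float:
    """Analytic derivative of :func:`activation` at ``x``."""
    return float(_dact(kind, np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class AnnConfig:
    """One training configuration from the sweep grid."""

    algorithm: str = "rprop"
    learning_rate: float = 0.7
    hidden1_size: int = 9
    hidden1_activation: str = "sigmoid"
    hidden2_size: int = 0  # 0 = single hidden layer
    hidden2_activation: str = "sigmoid"
    output_activation: str = "sigmoid"
    max_epochs: int = 1000
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        for kind in (
            self.hidden1_activation,
            self.hidden2_activation,
            self.output_activation,
        ):
            if kind not in ACTIVATION_KINDS:
                raise ValueError(f"unknown activation {kind!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.hidden1_size < 1:
            raise ValueError("hidden1_size must be >= 1")
        if self.hidden2_size < 0:
            raise ValueError("hidden2_size must be >= 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")

    def layer_sizes(self, n_inputs: int, n_outputs: int = 1) -> list[int]:
        sizes = [n_inputs, self.hidden1_size]
        if self.hidden2_size:
            sizes.append(self.hidden2_size)
        sizes.append(n_outputs)
        return sizes

    def layer_activations(self) -> list[str]:
        acts = [self.hidden1_activation]
        if self.hidden2_size:
            acts.append(self.hidden2_activation)
        acts.append(self.output_activation)
        return acts

    def describe(self) -> str:
        h2 = (
            f"-{self.hidden2_size}({self.hidden2_activation})"
            if self.hidden2_size
            else ""
        )
        return (
            f"{self.algorithm}/lr{self.learning_rate:g}/"
            f"{self.hidden1_size}({self.hidden1_activation}){h2}/"
            f"out({self.output_activation})"
        )


@dataclass
class AnnModel:
    """Weights, per-layer activations, and target-scaling parameters."""

    sizes: list[int]
    weights: list[np.ndarray]  # layer l: (sizes[l+1], sizes[l])
    biases: list[np.ndarray]  # layer l: (sizes[l+1],)
    activations: list[str]
    y_min: float = 0.0
    y_max: float = 1.0
    out_lo: float = 0.0
    out_hi: float = 1.0
    # input standardisation (training-set statistics); identity by default
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None

    def copy(self) -> "AnnModel":
        return AnnModel(
            sizes=list(self.sizes),
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            activations=list(self.activations),
            y_min=self.y_min,
            y_max=self.y_max,
            out_lo=self.out_lo,
            out_hi=self.out_hi,
            x_mean=None if self.x_mean is None else self.x_mean.copy(),
            x_std=None if self.x_std is None else self.x_std.copy(),
        )

    def standardize_inputs(self, X: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return X
        return (X - self.x_mean) / self.x_std

    def to_dict(self) -> dict:
        return {
            "sizes": list(self.sizes),
            "activations": list(self.activations),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "target_scaling": {
                "y_min": self.y_min,
                "y_max": self.y_max,
                "out_lo": self.out_lo,
                "out_hi": self.out_hi,
            },
            "input_scaling": {
                "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
                "x_std": None if self.x_std is None else self.x_std.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AnnModel":
        ts = doc["target_scaling"]
        xs = doc.get("input_scaling", {})
        return cls(
            sizes=list(doc["sizes"]),
            weights=[np.array(w, dtype=float) for w in doc["weights"]],
            biases=[np.array(b, dtype=float) for b in doc["biases"]],
            activations=list(doc["activations"]),
            y_min=ts["y_min"],
            y_max=ts["y_max"],
            out_lo=ts["out_lo"],
            out_hi=ts["out_hi"],
            x_mean=None if xs.get("x_mean") is None else np.array(xs["x_mean"]),
            x_std=None if xs.get("x_std") is None else np.array(xs["x_std"]),
        )


def init_model(config: AnnConfig, n_inputs: int = 24, n_outputs: int = 1) -> AnnModel:
    """Seeded uniform(-0.5, 0.5) weight/bias initialisation."""
    rng = np.random.default_rng(config.seed)
    sizes = config.layer_sizes(n_inputs, n_outputs)
    weights = [
        rng.uniform(-0.5, 0.5, size=(sizes[l + 1], sizes[l]))
        for l in range(len(sizes) - 1)
    ]
    biases = [rng.uniform(-0.5, 0.5, size=sizes[l + 1]) for l in range(len(sizes) - 1)]
    lo, hi = OUTPUT_BANDS[config.output_activation]
    return AnnModel(
        sizes=sizes,
        weights=weights,
        biases=biases,
        activations=config.layer_activations(),
        out_lo=lo,
        out_hi=hi,
    )


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward_pass(model: AnnModel, X: np.ndarray):
    """Returns (pre-activations z per layer, activations a per layer incl. input)."""
    a = X
    zs, acts = [], [a]
    for W, b, kind in zip(model.weights, model.biases, model.activations):
        z = a @ W.T + b
        a = _act(kind, z)
        zs.append(z)
        acts.append(a)
    return zs, acts


def forward(model: AnnModel, x: np.ndarray) -> float | np.ndarray:
    """Raw network output(s) for one sample or a batch (scaled units)."""
    X = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input")
    single = X.ndim == 1
    X2 = model.standardize_inputs(np.atleast_2d(X))
    _, acts = _forward_pass(model, X2)
    out = acts[-1]
    return float(out[0, 0]) if single and out.shape[1] == 1 else out


def scale_targets(model: AnnModel, y: np.ndarray) -> np.ndarray:
    span = model.y_max - model.y_min
    if span == 0:
        return np.full_like(np.asarray(y, dtype=float), 0.5 * (model.out_lo + model.out_hi))
    frac = (np.asarray(y, dtype=float) - model.y_min) / span
    return model.out_lo + frac * (model.out_hi - model.out_lo)


def unscale_outputs(model: AnnModel, raw: np.ndarray) -> np.ndarray:
    frac = (np.asarray(raw, dtype=float) - model.out_lo) / (model.out_hi - model.out_lo)
    return model.y_min + frac * (model.y_max - model.y_min)


def predict(model: AnnModel, X: np.ndarray) -> np.ndarray:
    """Predictions in target units (inverse of the training scaling)."""
    X2 = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X2)):
        raise ValueError("non-finite input")
    _, acts = _forward_pass(model, model.standardize_inputs(X2))
    out = unscale_outputs(model, acts[-1][:, 0])
    return out if np.asarray(X).ndim > 1 else float(out[0])


def gradients(model: AnnModel, X: np.ndarray, t: np.ndarray):
    """Summed gradients of ``E = sum_n 1/2 (o_n - t_n)^2`` over the batch.

    Returns ``(dW, db)`` lists matching the model's weight/bias layout.
    Vectorised over samples; equals the sum of single-sample gradients.
    """
    X2 = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_2d(np.asarray(t, dtype=float).reshape(X2.shape[0], -1))
    zs, acts = _forward_pass(model, X2)
    delta = (acts[-1] - T) * _dact(model.activations[-1], zs[-1])
    dW = [np.empty_like(w) for w in model.weights]
    db = [np.empty_like(b) for b in model.biases]
    for l in range(len(model.weights) - 1, -1, -1):
        dW[l] = delta.T @ acts[l]
        db[l] = delta.sum(axis=0)
        if l > 0:
            delta = (delta @ model.weights[l]) * _dact(model.activations[l - 1], zs[l - 1])
    return dW, db


def _mse(model: AnnModel, X: np.ndarray, t: np.ndarray) -> float:
    _, acts = _forward_pass(model, np.atleast_2d(X))
    o = acts[-1][:, 0]
    return float(np.mean((o - np.asarray(t, dtype=float)) ** 2))


# ---------------------------------------------------------------------------
# trainers
# ---------------------------------------------------------------------------

def _params(model: AnnModel) -> list[np.ndarray]:
    return model.weights + model.biases


def _flat_grads(dW, db) -> list[np.ndarray]:
    return dW + db


def train(
    model: AnnModel,
    X: np.ndarray,
    y_scaled: np.ndarray,
    config: AnnConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[AnnModel, dict]:
    """Train in place on scaled targets; returns (model, trace).

    The trace dict holds per-epoch training MSE (scaled units) and, when
    a validation pair is supplied, validation MSE.  With validation, the
    weights giving the lowest validation MSE are restored at the end and
    training stops once no improvement is seen for ``config.patience``
    epochs (over-fitting guard).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_scaled, dtype=float).ravel()
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(config.seed + 1)

    params = _params(model)
    # per-weight trainer state
    step_state = [np.full_like(p, RPROP_DELTA_ZERO) for p in params]
    prev_grad = [np.zeros_like(p) for p in params]
    prev_step = [np.zeros_like(p) for p in params]
    n = X.shape[0]

    trace: dict = {"train_mse": [], "val_mse": []}
    best_val = math.inf
    best_epoch = -1
    best_state: list[np.ndarray] | None = None

    for epoch in range(config.max_epochs):
        if config.algorithm == "incremental":
            order = rng.permutation(n)
            for i in order:
                dW, db = gradients(model, X[i : i + 1], y[i : i + 1])
                for p, g in zip(params, _flat_grads(dW, db)):
                    p -= config.learning_rate * g
        else:
            dW, db = gradients(model, X, y)
            grads = _flat_grads(dW, db)
            if config.algorithm == "batch":
                # classic accumulated-slope update: the learning rate acts on
                # the summed (not mean) gradient, as in textbook batch backprop
                for p, g in zip(params, grads):
                    p -= config.learning_rate * g
            elif config.algorithm == "rprop":
                for p, g, delta, gp in zip(params, grads, step_state, prev_grad):
                    sign_change = g * gp
                    delta[sign_change > 0] = np.minimum(
                        delta[sign_change > 0] * RPROP_ETA_PLUS, RPROP_DELTA_MAX
                    )
                    delta[sign_change < 0] = np.maximum(
                        delta[sign_change < 0] * RPROP_ETA_MINUS, RPROP_DELTA_MIN
                    )
                    g = g.copy()
                    g[sign_change < 0] = 0.0  # iRPROP−: skip reversed weights
                    p -= np.sign(g) * delta
                    gp[:] = g
            else:  # quickprop
                for p, g, sp, ps in zip(params, grads, prev_grad, prev_step):
                    s = -g / n - QUICKPROP_DECAY * p  # descent slope
                    moving = np.abs(ps) > 1e-12
                    denom = sp - s
                    safe = np.where(np.abs(denom) > 1e-12, denom, 1.0)
                    quad = ps * s / safe
                    limit = QUICKPROP_MU * np.abs(ps)
                    quad = np.clip(quad, -limit, limit)
                    step = np.where(moving, quad, 0.0)
                    use_grad = (~moving) | (s * ps > 0)
                    step = step + np.where(use_grad, config.learning_rate * s, 0.0)
                    p += step
                    sp[:] = s
                    ps[:] = step

        mse = _mse(model, X, y)
        if not math.isfinite(mse):
            raise TrainingDivergedError(
                f"training MSE became non-finite at epoch {epoch} "
                f"({config.describe()})"
            )
        trace["train_mse"].append(mse)
        if validation is not None:
            vmse = _mse(model, validation[0], validation[1])
            trace["val_mse"].append(vmse)
            if vmse < best_val - 1e-12:
                best_val = vmse
                best_epoch = epoch
                best_state = [p.copy() for p in params]
            elif epoch - best_epoch > config.patience:
                break

    if best_state is not None:
        for p, b in zip(params, best_state):
            p[:] = b
    for p in params:
        if not np.all(np.isfinite(p)):
            raise TrainingDivergedError(f"non-finite weights ({config.describe()})")
    return model, trace


def fit_regressor(
    X: np.ndarray,
    y: np.ndarray,
    config: AnnConfig,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[AnnModel, dict]:
    """Standardise inputs, scale targets to the output band, and train.

    Inputs are z-scored with training-set statistics (bounded activations
    need pre-activations of order one to train at all); validation data
    are transformed with the same training statistics so early stopping
    sees the units the network is fitted in.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    model = init_model(config, n_inputs=X.shape[1])
    model.x_mean = X.mean(axis=0)
    std = X.std(axis=0)
    model.x_std = np.where(std > 0, std, 1.0)
    model.y_min = float(y.min())
    model.y_max = float(y.max())
    Xs = model.standardize_inputs(X)
    ys = scale_targets(model, y)
    val = None
    if validation is not None:
        Xv, yv = validation
        val = (
            model.standardize_inputs(np.atleast_2d(np.asarray(Xv, dtype=float))),
            scale_targets(model, np.asarray(yv, dtype=float).ravel()),
        )
    model, trace = train(model, Xs, ys, config, validation=val)
    return model, trace
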