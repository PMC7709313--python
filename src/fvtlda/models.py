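"""Regression heads mapping pair feature vectors to association scores.

Two interchangeable models: an ordinary multiple linear regression fitted by
least squares on the intercept-augmented features, and a single-hidden-layer
neural network (tanh hidden units, linear output) trained by full-batch
gradient descent with an adaptive step, a validation-based early stop and
best-weight restoration.  Scores are used only for ranking, so neither model
clamps its output to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AnnConfig


@dataclass
class MlrModel:
    """Least-squares linear model; ``weights[0]`` is the intercept."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()

    @property
    def n_features(self) -> int:
        return self.weights.size - 1

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"format": "fvtlda-mlr-1", "weights": self.weights.tolist()}))

    @classmethod
    def load(cls, path: str | Path) -> "MlrModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "fvtlda-mlr-1":
            raise ValueError("not an MLR model file")
        return cls(np.array(blob["weights"]))


def fit_mlr(features: np.ndarray, targets: np.ndarray) -> MlrModel:
    """Fit W on intercept-augmented features by least squares.

    Uses the minimum-norm pseudo-inverse solution, which coincides with the
    normal-equation solution (X^T X)^{-1} X^T y when the design has full
    column rank and stays finite under collinearity.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if x.shape[0] == 0:
        raise ValueError("fit_mlr needs at least one training sample")
    if x.shape[0] != y.size:
        raise ValueError("features and targets disagree in length")
    design = np.hstack([np.ones((x.shape[0], 1)), x])
    weights, *_ = np.linalg.lstsq(design, y, rcond=None)
    return MlrModel(weights)


def predict_mlr(model: MlrModel, features: np.ndarray) -> np.ndarray | float:
    """Score one feature vector or a stack of them."""
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[1]}")
    scores = model.weights[0] + x @ model.weights[1:]
    return float(scores[0]) if single else scores


def hidden_activation(x):
    """Hidden-layer sigmoid 2 / (1 + exp(-2x)) - 1, algebraically tanh."""
    return np.tanh(x)


@dataclass
class AnnModel:
    """Single-hidden-layer network with a linear output neuron."""

    weights_in: np.ndarray   # (n_features, hidden)
    bias_hidden: np.ndarray  # (hidden,)
    weights_out: np.ndarray  # (hidden,)
    bias_out: float
    seed: int = 0
    train_cfg: AnnConfig = field(default_factory=AnnConfig)
    history: dict = field(default_factory=dict, repr=False)

    def save(self, path: str | Path) -> None:
        blob = {
            "format": "fvtlda-ann-1",
            "weights_in": self.weights_in.tolist(),
            "bias_hidden": self.bias_hidden.tolist(),
            "weights_out": self.weights_out.tolist(),
            "bias_out": self.bias_out,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "AnnModel":
        blob = json.loads(Path(path).read_text())
        if blob.get("format") != "fvtlda-ann-1":
            raise ValueError("not an ANN model file")
        return cls(
            np.array(blob["weights_in"]),
            np.array(blob["bias_hidden"]),
            np.array(blob["weights_out"]),
            float(blob["bias_out"]),
            seed=int(blob["seed"]),
        )


def predict_ann(model: AnnModel, features: np.ndarray) -> np.ndarray | float:
    x = np.asarray(features, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.weights_in.shape[0]:
        raise ValueError(
            f"expected {model.weights_in.shape[0]} features, got {x.shape[1]}"
        )
    hidden = hidden_activation(x @ model.weights_in + model.bias_hidden)
    scores = hidden @ model.weights_out + model.bias_out
    return float(scores[0]) if single else scores


def _mse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2))


def _pack(w_in, b_h, w_out, b_o):
    return np.concatenate([w_in.ravel(), b_h, w_out, [b_o]])


def _unpack(theta, d, h):
    w_in = theta[: d * h].reshape(d, h)
    b_h = theta[d * h: d * h + h]
    w_out = theta[d * h + h: d * h + 2 * h]
    b_o = float(theta[-1])
    return w_in, b_h, w_out, b_o


def fit_ann(
    features: np.ndarray,
    targets: np.ndarray,
    cfg: AnnConfig | None = None,
    seed: int = 0,
) -> AnnModel:
    """Train the network on a seeded 3:1:1 train/validation/test split.

    Full-batch Levenberg-Marquardt damping: each epoch solves
    (J^T J + mu I) step = J^T residual on the training portion, accepting the
    step and lowering ``mu`` when the training MSE improves, raising ``mu``
    and retrying otherwise.  Training stops at ``max_epochs``, when the
    training MSE reaches ``mse_goal``, or when validation MSE has not
    improved for ``patience`` consecutive epochs; the best-validation weights
    are restored.  The test portion is held out for reporting only.  Fixed
    seeds give bit-identical models.
    """
    cfg = cfg or AnnConfig()
    x = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    n = x.shape[0]
    if n < 5:
        raise ValueError("fit_ann needs at least 5 samples for the 3:1:1 split")
    rng = np.random.default_rng(seed)

    perm = rng.permutation(n)
    parts = np.array(cfg.split, dtype=float)
    bounds = np.floor(np.cumsum(parts) / parts.sum() * n).astype(int)
    tr, va, te = perm[: bounds[0]], perm[bounds[0]: bounds[1]], perm[bounds[1]:]
    x_tr, y_tr = x[tr], y[tr]
    x_va, y_va = x[va], y[va]

    d, h = x.shape[1], cfg.hidden_size
    theta = _pack(
        rng.uniform(-0.5, 0.5, size=(d, h)),
        rng.uniform(-0.5, 0.5, size=h),
        rng.uniform(-0.5, 0.5, size=h),
        float(rng.uniform(-0.5, 0.5)),
    )

    def forward(xx, th):
        w_in, b_h, w_out, b_o = _unpack(th, d, h)
        hidden = hidden_activation(xx @ w_in + b_h)
        return hidden, hidden @ w_out + b_o

    def jacobian(hidden, th):
        # d residual / d theta, row per training sample
        _, _, w_out, _ = _unpack(th, d, h)
        sech2 = 1.0 - hidden ** 2                      # (m, h)
        back = sech2 * w_out[None, :]                  # (m, h)
        j_in = back[:, None, :] * x_tr[:, :, None]     # (m, d, h)
        return np.hstack([
            j_in.reshape(len(x_tr), d * h),
            back,
            hidden,
            np.ones((len(x_tr), 1)),
        ])

    mu = 1e-3
    hidden, pred = forward(x_tr, theta)
    train_mse = _mse(pred, y_tr)
    best_theta = theta.copy()
    best_val = _mse(forward(x_va, theta)[1], y_va) if len(va) else np.inf
    stall = 0
    trace: list[dict] = []
    p = theta.size

    for epoch in range(cfg.max_epochs):
        residual = pred - y_tr
        jac = jacobian(hidden, theta)
        jtj = jac.T @ jac
        jtr = jac.T @ residual
        accepted = False
        while mu <= 1e10:
            try:
                step = np.linalg.solve(jtj + mu * np.eye(p), jtr)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta - step
            hid_c, pred_c = forward(x_tr, cand)
            cand_mse = _mse(pred_c, y_tr)
            if cand_mse < train_mse:
                theta, hidden, pred, train_mse = cand, hid_c, pred_c, cand_mse
                mu = max(mu * 0.1, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break  # damping exhausted: a local minimum to working precision

        val = _mse(forward(x_va, theta)[1], y_va) if len(va) else train_mse
        trace.append({"epoch": epoch, "train_mse": train_mse, "val_mse": val, "mu": mu})
        if val < best_val - 1e-15:
            best_val = val
            best_theta = theta.copy()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
        if train_mse <= cfg.mse_goal:
            if val <= best_val:
                best_val = val
                best_theta = theta.copy()
            break

    w_in, b_h, w_out, b_o = _unpack(best_theta, d, h)
    model = AnnModel(w_in, b_h, w_out, b_o, seed=seed, train_cfg=cfg)
    test_mse = _mse(predict_ann(model, x[te]), y[te]) if len(te) else None
    model.history = {
        "trace": trace,
        "best_val_mse": None if np.isinf(best_val) else best_val,
        "test_mse": test_mse,
        "split_sizes": (len(tr), len(va), len(te)),
    }
    return model
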