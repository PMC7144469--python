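"""Dropout MLP regressor with Monte-Carlo-dropout uncertainty estimation.

The model is a feed-forward regression network — three ReLU hidden layers of
500, 500 and 200 units by default, a single linear output — trained on
squared error with Adam (learning rate 0.001, mini-batches of 100, 200
epochs) and dropout p = 0.5 after every hidden layer.  No other
regularization is applied.

Uncertainty comes from keeping dropout *active at inference*: each test
compound is pushed through the network T times, each pass with an
independent dropout mask.  The mean over passes is the MC prediction ŷ_i
(a committee average, typically slightly more accurate than the single
deterministic pass) and the standard deviation over passes is the
uncertainty u_i, on the same scale as the prediction.  With dropout rate 0
every mask is the identity, so ŷ_i equals the deterministic prediction and
u_i is exactly 0.

Dropout uses the inverted convention (activations divided by the keep
probability while training / sampling), so the deterministic pass needs no
weight rescaling and train/eval expectations match.

Implementation is plain NumPy in float32; given a seed, training and MC
prediction are fully reproducible.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MLPConfig",
    "TrainedModel",
    "PredictionSet",
    "EvalSummary",
    "train",
    "predict_mc",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass
class MLPConfig:
    hidden_sizes: list[int] = field(default_factory=lambda: [500, 500, 200])
    dropout_rate: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 100
    mc_passes: int = 50  # T
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.mc_passes < 2:
            raise ValueError("mc_passes must be >= 2 (std over passes undefined)")


@dataclass
class TrainedModel:
    """Weights, biases and the config that produced them."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MLPConfig
    loss_history: list[float]

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]


@dataclass
class PredictionSet:
    """Deterministic and MC predictions with per-compound uncertainty.

    ``y_det``: single pass, dropout off.  ``y_mc``: mean over T dropout
    passes.  ``uncertainty``: sample std (ddof=1) over the same passes.
    ``samples``: the raw T×n pass matrix (kept for diagnostics).
    """

    compound_ids: list[str]
    y_det: np.ndarray
    y_mc: np.ndarray
    uncertainty: np.ndarray
    samples: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.compound_ids)
        for name in ("y_det", "y_mc", "uncertainty"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, v)
        if (self.uncertainty < 0).any():
            raise ValueError("uncertainty must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "y_det": self.y_det,
                "y_mc": self.y_mc,
                "uncertainty": self.uncertainty,
            }
        )


@dataclass
class EvalSummary:
    mse: float  # deterministic predictions
    dropout_mse: float  # MC-mean predictions
    mean_uncertainty: float


def _init_params(n_features: int, hidden: Sequence[int], rng: np.random.Generator):
    """He-normal initialization, zero biases, float32."""
    sizes = [n_features, *hidden, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / fan_in)
        weights.append((rng.standard_normal((fan_in, fan_out)) * scale).astype(np.float32))
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return weights, biases


def _forward_train(x, weights, biases, keep, rng):
    """Forward pass with dropout masks; returns output, activations, masks."""
    acts = [x]
    masks = []
    h = x
    n_hidden = len(weights) - 1
    for layer in range(n_hidden):
        h = np.maximum(h @ weights[layer] + biases[layer], 0.0)
        if keep < 1.0:
            mask = (rng.random(h.shape, dtype=np.float32) < keep).astype(np.float32)
            h = h * mask / keep
        else:
            mask = None
        masks.append(mask)
        acts.append(h)
    out = h @ weights[-1] + biases[-1]
    return out, acts, masks


def _forward_det(x, weights, biases):
    h = x
    for layer in range(len(weights) - 1):
        h = np.maximum(h @ weights[layer] + biases[layer], 0.0)
    return (h @ weights[-1] + biases[-1]).ravel()


def train(
    features,
    labels,
    config: MLPConfig | None = None,
) -> TrainedModel:
    """Fit the dropout MLP by mini-batch Adam on squared error.

    ``features`` is an (n × d) binary/real matrix or a FingerprintMatrix;
    ``labels`` the length-n real target vector (log-activities).  A NaN
    training loss aborts with a diagnostic rather than returning garbage.
    """
    config = config or MLPConfig()
    x = np.asarray(getattr(features, "bits", features), dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32).reshape(-1, 1)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError(
            f"feature rows ({x.shape[0] if x.ndim == 2 else '?'}) must match "
            f"label length ({y.shape[0]})"
        )
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(x.shape[1], config.hidden_sizes, rng)
    keep = 1.0 - config.dropout_rate

    # Adam state
    b1, b2, eps = 0.9, 0.999, 1e-8
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]
    step = 0

    loss_history = []
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            out, acts, masks = _forward_train(xb, weights, biases, keep, rng)
            resid = out - yb
            loss = float(np.mean(resid**2))
            epoch_loss += loss * idx.size

            # backprop of mean squared error
            grad = (2.0 / idx.size) * resid.astype(np.float32)
            g_w = [None] * len(weights)
            g_b = [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                g_w[layer] = acts[layer].T @ grad
                g_b[layer] = grad.sum(axis=0)
                if layer > 0:
                    grad = grad @ weights[layer].T
                    if masks[layer - 1] is not None:
                        grad = grad * masks[layer - 1] / keep
                    grad = grad * (acts[layer] > 0)

            step += 1
            corr1 = 1.0 - b1**step
            corr2 = 1.0 - b2**step
            lr = config.learning_rate
            for layer in range(len(weights)):
                m_w[layer] = b1 * m_w[layer] + (1 - b1) * g_w[layer]
                v_w[layer] = b2 * v_w[layer] + (1 - b2) * g_w[layer] ** 2
                weights[layer] -= lr * (m_w[layer] / corr1) / (
                    np.sqrt(v_w[layer] / corr2) + eps
                )
                m_b[layer] = b1 * m_b[layer] + (1 - b1) * g_b[layer]
                v_b[layer] = b2 * v_b[layer] + (1 - b2) * g_b[layer] ** 2
                biases[layer] -= lr * (m_b[layer] / corr1) / (
                    np.sqrt(v_b[layer] / corr2) + eps
                )
        epoch_loss /= n
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                f"training loss became non-finite ({epoch_loss}) at epoch "
                f"{len(loss_history) + 1}; reduce the learning rate or check labels"
            )
        loss_history.append(epoch_loss)

    return TrainedModel(weights, biases, config, loss_history)


def predict_det(model: TrainedModel, features) -> np.ndarray:
    """Single forward pass with dropout off (inverted dropout: no rescaling)."""
    x = np.asarray(getattr(features, "bits", features), dtype=np.float32)
    return _forward_det(x, model.weights, model.biases).astype(np.float64)


def predict_mc(
    model: TrainedModel,
    features,
    T: int | None = None,
    seed: int | None = None,
    compound_ids: list[str] | None = None,
    keep_samples: bool = True,
) -> PredictionSet:
    """T stochastic forward passes with independent dropout masks.

    Returns per-compound MC mean ŷ_i, uncertainty u_i (sample std over the T
    passes) and the deterministic single-pass prediction for comparison.
    """
    T = T if T is not None else model.config.mc_passes
    if T < 2:
        raise ValueError("T must be >= 2 (std over passes undefined)")
    seed = seed if seed is not None else model.config.seed
    x = np.asarray(getattr(features, "bits", features), dtype=np.float32)
    n = x.shape[0]
    if compound_ids is None:
        compound_ids = list(getattr(features, "compound_ids", [str(i) for i in range(n)]))

    keep = 1.0 - model.config.dropout_rate
    rng = np.random.default_rng(seed)
    samples = np.empty((T, n), dtype=np.float64)
    for t in range(T):
        out, _, _ = _forward_train(x, model.weights, model.biases, keep, rng)
        samples[t] = out.ravel()

    y_det = _forward_det(x, model.weights, model.biases).astype(np.float64)
    y_mc = samples.mean(axis=0)
    unc = samples.std(axis=0, ddof=1) if keep < 1.0 else np.zeros(n)
    if keep == 1.0:
        # every mask is the identity: MC mean is exactly the deterministic pass
        y_mc = y_det.copy()
        samples = np.tile(y_det, (T, 1))
    return PredictionSet(
        compound_ids=compound_ids,
        y_det=y_det,
        y_mc=y_mc,
        uncertainty=unc,
        samples=samples if keep_samples else None,
    )


def evaluate(pred: PredictionSet, labels, compound_ids: list[str] | None = None) -> EvalSummary:
    """MSE of the deterministic and MC-mean predictions plus mean uncertainty."""
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != pred.y_det.shape:
        raise ValueError("label length must match prediction length")
    if compound_ids is not None and list(compound_ids) != list(pred.compound_ids):
        raise ValueError("compound id mismatch between predictions and labels")
    return EvalSummary(
        mse=float(np.mean((pred.y_det - y) ** 2)),
        dropout_mse=float(np.mean((pred.y_mc - y) ** 2)),
        mean_uncertainty=float(np.mean(pred.uncertainty)),
    )


def save_model(model: TrainedModel, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedModel:
    with open(path, "rb") as fh:
        return pickle.load(fh)
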