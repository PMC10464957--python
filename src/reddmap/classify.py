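"""Supervised per-pixel classifiers: Gaussian maximum likelihood and a
one-hidden-layer logistic neural network.

Maximum likelihood assigns each pixel x to the class c maximizing the
Gaussian discriminant

    g_c(x) = ln(prior_c) - 1/2 ln|Sigma_c| - 1/2 (x - mu_c)^T Sigma_c^-1 (x - mu_c)

built from the training mean vectors and covariance matrices. With no
probability threshold every pixel is classified; with a threshold, pixels
whose best-class posterior falls below it are left unclassified (label 0).

The neural network is a multilayer perceptron with three inputs (the RGB
bands in [0, 1]), one logistic hidden layer and K logistic outputs, trained
by full-batch gradient descent on the sum-of-squares error with momentum.
Default hyperparameters: logistic activation, training rate 0.2, momentum
0.9, training threshold contribution 0.9, RMS exit criterion 0.1, one
hidden layer, 1000 training iterations. "Training threshold contribution"
is interpreted here as a multiplier on the bias-weight updates — see
docs/methods.md; the value, not the mechanism, is the established setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import ClassMap, ClassScheme, RGBImage, ROISet
from .training import ClassStatistics

log = logging.getLogger(__name__)


@dataclass
class MLCConfig:
    """Maximum-likelihood settings.

    ``priors`` default to equal; ``probability_threshold`` of ``None``
    classifies every pixel (the recommended setting); ``cov_regularization_eps``
    scales the ridge added to singular covariances.
    """

    priors: dict[int, float] | None = None
    probability_threshold: float | None = None
    cov_regularization_eps: float = 1e-6

    def __post_init__(self):
        if self.priors is not None:
            total = sum(self.priors.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"priors must sum to 1, got {total}")
        if self.probability_threshold is not None and not (
                0 < self.probability_threshold < 1):
            raise ValueError("probability threshold must lie in (0, 1)")
        if self.cov_regularization_eps <= 0:
            raise ValueError("cov_regularization_eps must be positive")


def _regularized_cov(cov: np.ndarray, eps: float) -> np.ndarray:
    """Add eps * trace(cov)/3 to the diagonal; floor at eps for zero matrices."""
    ridge = eps * np.trace(cov) / 3.0
    if ridge <= 0:
        ridge = eps
    return cov + ridge * np.eye(3)


def _discriminants(flat: np.ndarray, stats: ClassStatistics,
                   config: MLCConfig, class_ids: list[int]) -> np.ndarray:
    """Gaussian log-discriminant per pixel per class; shape (n_pixels, K)."""
    k = len(class_ids)
    priors = (np.full(k, 1.0 / k) if config.priors is None
              else np.array([config.priors[c] for c in class_ids]))
    g = np.empty((flat.shape[0], k))
    for j, cid in enumerate(class_ids):
        cov = stats.cov[cid]
        if cid in stats.singular or np.linalg.matrix_rank(cov) < 3:
            cov = _regularized_cov(cov, config.cov_regularization_eps)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            cov = _regularized_cov(cov, config.cov_regularization_eps)
            sign, logdet = np.linalg.slogdet(cov)
        diff = flat - stats.mean[cid]
        maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
        g[:, j] = np.log(priors[j]) - 0.5 * logdet - 0.5 * maha
    if not np.isfinite(g).all():
        raise ValueError("non-finite discriminant encountered")
    return g


def classify_maximum_likelihood(image: RGBImage, stats: ClassStatistics,
                                scheme: ClassScheme,
                                config: MLCConfig | None = None) -> ClassMap:
    """Classify every pixel by the Gaussian maximum-likelihood rule.

    Requires statistics for every class in the scheme. Ties in the
    discriminant break toward the lowest class id.
    """
    config = config or MLCConfig()
    class_ids = scheme.ids
    missing = [c for c in class_ids if c not in stats.n]
    if missing:
        raise ValueError(f"missing statistics for classes {missing}")
    flat = image.as_unit_float().reshape(-1, 3)
    g = _discriminants(flat, stats, config, class_ids)
    best = g.argmax(axis=1)  # argmax takes the first (lowest-id) maximum
    labels = np.asarray(class_ids, dtype=np.int64)[best]
    if config.probability_threshold is not None:
        # posterior of the best class from the log-discriminants
        shifted = g - g.max(axis=1, keepdims=True)
        post = np.exp(shifted)
        post /= post.sum(axis=1, keepdims=True)
        labels[post.max(axis=1) < config.probability_threshold] = 0
    return ClassMap(labels.reshape(image.shape), scheme)


# ---------------------------------------------------------------------------
# neural network

@dataclass
class NNConfig:
    """One-hidden-layer logistic perceptron hyperparameters (field defaults
    are the recommended settings for redd mapping)."""

    hidden_units: int | None = None  # default: number of classes
    training_rate: float = 0.2
    momentum: float = 0.9
    threshold_contribution: float = 0.9
    rms_exit: float = 0.1
    max_iterations: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("training_rate", "momentum", "threshold_contribution"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if not 0 < self.rms_exit <= 1:
            raise ValueError("rms_exit must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.hidden_units is not None and self.hidden_units < 1:
            raise ValueError("hidden_units must be positive")


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class NNModel:
    """Trained perceptron: weights, biases, training history and config."""

    w_hidden: np.ndarray   # (3, H)
    b_hidden: np.ndarray   # (H,)
    w_output: np.ndarray   # (H, K)
    b_output: np.ndarray   # (K,)
    class_ids: list[int]
    config: NNConfig
    rms_history: list[float] = field(default_factory=list)
    converged: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Output activations for inputs x of shape (n, 3)."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.w_hidden.shape[0]:
            raise ValueError(
                f"model expects {self.w_hidden.shape[0]} bands, got "
                f"{x.shape[1]}")
        h = _logistic(x @ self.w_hidden + self.b_hidden)
        return _logistic(h @ self.w_output + self.b_output)

    def save(self, path) -> None:
        import json
        from pathlib import Path
        payload = {
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_output": self.w_output.tolist(),
            "b_output": self.b_output.tolist(),
            "class_ids": self.class_ids,
            "config": vars(self.config),
            "rms_history": self.rms_history,
            "converged": self.converged,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "NNModel":
        import json
        from pathlib import Path
        d = json.loads(Path(path).read_text())
        return cls(
            w_hidden=np.array(d["w_hidden"]),
            b_hidden=np.array(d["b_hidden"]),
            w_output=np.array(d["w_output"]),
            b_output=np.array(d["b_output"]),
            class_ids=list(d["class_ids"]),
            config=NNConfig(**d["config"]),
            rms_history=list(d["rms_history"]),
            converged=bool(d["converged"]),
        )


def train_neural_net(image: RGBImage, training_rois: ROISet,
                     config: NNConfig | None = None) -> NNModel:
    """Train the perceptron on training-ROI pixels with one-hot targets.

    Full-batch gradient descent on the sum-of-squares error:
    ``dw(t) = -rate * grad + momentum * dw(t-1)``; bias updates are
    additionally scaled by ``threshold_contribution``. Training stops when
    the RMS output error drops to ``rms_exit`` or after ``max_iterations``
    (returning the model with a warning). Deterministic given ``rng_seed``.
    """
    config = config or NNConfig()
    class_ids = training_rois.class_ids()
    if not class_ids:
        raise ValueError("empty training ROISet")
    for cid in class_ids:
        if training_rois.count(cid) == 0:
            raise ValueError(f"class {cid} has no training pixels")
    unit = image.as_unit_float()
    xs, ys = [], []
    k = len(class_ids)
    for j, cid in enumerate(class_ids):
        coords = training_rois.pixels[cid]
        xs.append(unit[coords[:, 0], coords[:, 1]])
        onehot = np.zeros((len(coords), k))
        onehot[:, j] = 1.0
        ys.append(onehot)
    x = np.vstack(xs)
    y = np.vstack(ys)

    hidden = config.hidden_units or k
    rng = np.random.default_rng(config.rng_seed)
    w1 = rng.uniform(-0.05, 0.05, size=(3, hidden))
    b1 = rng.uniform(-0.05, 0.05, size=hidden)
    w2 = rng.uniform(-0.05, 0.05, size=(hidden, k))
    b2 = rng.uniform(-0.05, 0.05, size=k)
    dw1 = np.zeros_like(w1); db1 = np.zeros_like(b1)
    dw2 = np.zeros_like(w2); db2 = np.zeros_like(b2)

    rate, mom, tc = (config.training_rate, config.momentum,
                     config.threshold_contribution)
    history: list[float] = []
    converged = False
    for _ in range(config.max_iterations):
        h = _logistic(x @ w1 + b1)
        out = _logistic(h @ w2 + b2)
        err = out - y
        rms = float(np.sqrt(np.mean(err ** 2)))
        history.append(rms)
        if rms <= config.rms_exit:
            converged = True
            break
        # backpropagation; gradients averaged over the batch so the step
        # size is independent of the training-set size
        n = len(x)
        delta_out = err * out * (1 - out)
        delta_hid = (delta_out @ w2.T) * h * (1 - h)
        dw2 = -rate * (h.T @ delta_out) / n + mom * dw2
        db2 = -rate * tc * delta_out.mean(axis=0) + mom * db2
        dw1 = -rate * (x.T @ delta_hid) / n + mom * dw1
        db1 = -rate * tc * delta_hid.mean(axis=0) + mom * db1
        w2 += dw2; b2 += db2; w1 += dw1; b1 += db1
    if not converged:
        log.warning("neural net did not reach RMS %.3g in %d iterations "
                    "(final RMS %.4g)", config.rms_exit,
                    config.max_iterations, history[-1])
    return NNModel(w_hidden=w1, b_hidden=b1, w_output=w2, b_output=b2,
                   class_ids=list(class_ids), config=config,
                   rms_history=history, converged=converged)


def classify_neural_net(model: NNModel, image: RGBImage,
                        scheme: ClassScheme) -> ClassMap:
    """Label each pixel with the argmax output class (lowest id on ties)."""
    flat = image.as_unit_float().reshape(-1, 3)
    out = model.forward(flat)
    labels = np.asarray(model.class_ids, dtype=np.int64)[out.argmax(axis=1)]
    return ClassMap(labels.reshape(image.shape), scheme)
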