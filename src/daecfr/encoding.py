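"""Feature views and deep-autoencoder compression.

Each of the four entity feature views (association rows and similarity rows
for miRNAs and diseases) is compressed to an L-dimensional code by its own
symmetric autoencoder with three hidden layers [hidden, L, hidden], trained
with mini-batch Adam on mean squared reconstruction error. The implementation
is plain NumPy: at these matrix sizes a framework buys nothing and exact
seed-reproducibility is easier to guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, PairSet, SimilarityMatrix

__all__ = [
    "FeatureView",
    "EncoderSpec",
    "DeepAutoencoder",
    "build_feature_views",
    "train_autoencoder",
    "encode_all",
    "combine_features",
    "VIEW_ORDER",
]

#: concatenation order of the latent blocks in the combined pair feature
VIEW_ORDER = ("IP_m", "LSM_m", "IP_d", "LSD_d")


@dataclass
class FeatureView:
    """Raw per-entity feature matrix (rows = entities)."""

    matrix: np.ndarray
    view: str

    def __post_init__(self) -> None:
        if self.view not in VIEW_ORDER:
            raise ValueError(f"unknown view tag {self.view!r}")
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("feature view must be a 2-d matrix")

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EncoderSpec:
    latent_dim: int = 8
    hidden: int = 256
    batch_size: int = 100
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.hidden < 1:
            raise ValueError("latent_dim and hidden must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")


def build_feature_views(
    A: AssociationMatrix, LSM: SimilarityMatrix, LSD: SimilarityMatrix
) -> dict[str, FeatureView]:
    """Assemble the four raw views from the association and similarity matrices."""
    if len(LSM) != A.n_mirnas or len(LSD) != A.n_diseases:
        raise ValueError("similarity matrices do not match association matrix shape")
    return {
        "IP_m": FeatureView(A.values.astype(np.float64), "IP_m"),
        "LSM_m": FeatureView(LSM.values, "LSM_m"),
        "IP_d": FeatureView(A.values.T.astype(np.float64), "IP_d"),
        "LSD_d": FeatureView(LSD.values, "LSD_d"),
    }


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class DeepAutoencoder:
    """Symmetric autoencoder [D, hidden, L, hidden, D].

    Hidden layers use rectifier activations, the output layer a sigmoid
    (inputs live in [0, 1]); loss is mean squared reconstruction error,
    optimized with Adam. Fully deterministic given the spec seed.
    """

    def __init__(self, input_dim: int, spec: EncoderSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        dims = [input_dim, spec.hidden, spec.latent_dim, spec.hidden, input_dim]
        self.weights = []
        self.biases = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He init for the rectifier layers, Glorot for the sigmoid output
            scale = np.sqrt(2.0 / d_in)
            if d_out == input_dim:
                scale = np.sqrt(2.0 / (d_in + d_out))
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self._rng = rng
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0
        self.loss_history: list[float] = []

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray):
        acts = [x]
        h = x
        for layer, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = _sigmoid(z) if layer == len(self.weights) - 1 else _relu(z)
            acts.append(h)
        return acts

    def _step(self, x: np.ndarray) -> float:
        acts = self._forward(x)
        out = acts[-1]
        diff = out - x
        loss = float(np.mean(diff * diff))
        n = diff.size
        # output layer: d(mse)/dz through the sigmoid
        delta = (2.0 / n) * diff * out * (1.0 - out)
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (acts[layer] > 0)
        self._adam_update(grads_w + grads_b)
        return loss

    def _adam_update(self, grads, beta1: float = 0.9, beta2: float = 0.999,
                     eps: float = 1e-8) -> None:
        self._adam_t += 1
        lr = self.spec.learning_rate
        params = self.weights + self.biases
        for k, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1 ** self._adam_t)
            v_hat = self._adam_v[k] / (1 - beta2 ** self._adam_t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- public API --------------------------------------------------------

    def fit(self, X: np.ndarray) -> "DeepAutoencoder":
        X = np.asarray(X, dtype=np.float64)
        n = len(X)
        bs = min(self.spec.batch_size, n)
        for epoch in range(self.spec.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                batch = X[order[start:start + bs]]
                losses.append(self._step(batch))
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(f"autoencoder loss diverged at epoch {epoch + 1}")
            self.loss_history.append(epoch_loss)
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=np.float64)
        for w, b in zip(self.weights[:2], self.biases[:2]):
            h = _relu(h @ w + b)
        return h

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64))[-1]


def train_autoencoder(view: FeatureView, spec: EncoderSpec) -> DeepAutoencoder:
    """Fit one autoencoder on a feature view's rows."""
    X = view.matrix
    if len(X) < 2:
        raise ValueError("feature view needs at least 2 rows")
    if not np.isfinite(X).all():
        raise ValueError("feature view contains non-finite values")
    if X.min() < -1e-9 or X.max() > 1 + 1e-9:
        raise ValueError("feature view values must lie in [0, 1]")
    return DeepAutoencoder(X.shape[1], spec).fit(X)


# per-view seed offsets so the four encoders do not share an init stream
_VIEW_SEED_OFFSET = {view: k for k, view in enumerate(VIEW_ORDER)}


def encode_all(
    views: dict[str, FeatureView], spec: EncoderSpec
) -> dict[str, np.ndarray]:
    """Train one encoder per view and return the four latent matrices."""
    missing = set(VIEW_ORDER) - set(views)
    if missing:
        raise ValueError(f"missing feature views: {sorted(missing)}")
    latents = {}
    for view_tag in VIEW_ORDER:
        view = views[view_tag]
        view_spec = EncoderSpec(
            latent_dim=spec.latent_dim, hidden=spec.hidden,
            batch_size=spec.batch_size, epochs=spec.epochs,
            learning_rate=spec.learning_rate,
            seed=spec.seed * 4 + _VIEW_SEED_OFFSET[view_tag],
        )
        latents[view_tag] = train_autoencoder(view, view_spec).encode(view.matrix)
    return latents


_MODE_BLOCKS = {
    "combined": ("IP_m", "LSM_m", "IP_d", "LSD_d"),
    "association-only": ("IP_m", "IP_d"),
    "similarity-only": ("LSM_m", "LSD_d"),
}


def combine_features(
    pairs: PairSet, latents: dict[str, np.ndarray], mode: str = "combined"
) -> np.ndarray:
    """Concatenate latent blocks per pair; width 4L (2L for ablation modes)."""
    blocks = _MODE_BLOCKS.get(mode)
    if blocks is None:
        raise ValueError(f"unknown feature mode {mode!r}")
    idx = pairs.pairs
    n_m = len(latents["IP_m"])
    n_d = len(latents["IP_d"])
    if len(idx) and (idx[:, 0].max() >= n_m or idx[:, 1].max() >= n_d):
        raise IndexError("pair index out of bounds for latent matrices")
    parts = []
    for tag in blocks:
        rows = idx[:, 0] if tag in ("IP_m", "LSM_m") else idx[:, 1]
        parts.append(latents[tag][rows])
    width = sum(latents[tag].shape[1] for tag in blocks)
    if not len(idx):
        return np.empty((0, width))
    return np.hstack(parts)
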