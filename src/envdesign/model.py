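"""The environment classifier: architecture, inference, training, checkpoints.

The classifier maps a K×46 environment feature matrix to a probability
distribution over the 20 canonical amino-acid types.  Architecture: a
dense input projection (46 → model_dim), a stack of transformer layers
(masked multi-head self-attention and a position-wise fully connected
sub-layer, each wrapped in a residual connection with post-layer
normalization), masked mean pooling over the K neighbor embeddings, and
a dense softmax head.  No positional encoding is added: sequence
information enters only through the 13 offset features, which keeps the
whole predictor permutation-invariant over neighbors.

Defaults follow the published recipe: 3 layers, 16 heads of 16
dimensions (model width 256), cross-entropy loss, Adam with
β1 = 0.9, β2 = 0.999, learning rate 1e-3, batch size 1000.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import alphabet, nn
from .featurize import FEATURE_DIM, EnvironmentFeatures

CHECKPOINT_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    layers: int = 3
    heads: int = 16
    head_dim: int = 16
    input_dim: int = FEATURE_DIM
    n_classes: int = alphabet.N_TYPES
    seed: int = 0

    @property
    def model_dim(self) -> int:
        return self.heads * self.head_dim

    def validate(self) -> None:
        if self.layers < 1 or self.heads < 1 or self.head_dim < 1:
            raise ValueError("layers, heads, head_dim must be positive")
        if self.n_classes != alphabet.N_TYPES:
            raise ValueError("the classifier head is fixed to the 20 canonical types")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 1000
    epochs: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class ClassifierModel:
    """Config plus the parameter dictionary (all float32 numpy arrays)."""

    config: ModelConfig
    params: dict[str, np.ndarray]

    def copy(self) -> "ClassifierModel":
        return ClassifierModel(
            config=self.config, params={k: v.copy() for k, v in self.params.items()}
        )


def init_model(config: ModelConfig) -> ClassifierModel:
    """Deterministically initialize a classifier from its config seed."""
    config.validate()
    params = nn.init_params(
        config.input_dim, config.model_dim, config.layers, config.n_classes,
        config.seed,
    )
    return ClassifierModel(config=config, params=params)


# ---------------------------------------------------------------------------
# inference


def _pack(batch: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pad a list of K_i×46 matrices into (B, Kmax, 46) plus a mask."""
    kmax = max(m.shape[0] for m in batch)
    X = np.zeros((len(batch), kmax, batch[0].shape[1]), dtype=nn.DTYPE)
    mask = np.zeros((len(batch), kmax), dtype=nn.DTYPE)
    for i, m in enumerate(batch):
        X[i, : m.shape[0]] = m
        mask[i, : m.shape[0]] = 1.0
    return X, mask


def predict_batch(
    model: ClassifierModel, batch: Sequence[EnvironmentFeatures | np.ndarray]
) -> np.ndarray:
    """(B, 20) probability rows for a batch of environments."""
    mats = [
        b.matrix if isinstance(b, EnvironmentFeatures) else np.asarray(b)
        for b in batch
    ]
    if not mats:
        raise ValueError("empty batch")
    for m in mats:
        if m.ndim != 2 or m.shape[1] != model.config.input_dim:
            raise ValueError(
                f"expected K×{model.config.input_dim} features, got {m.shape}"
            )
        if m.shape[0] < 1:
            raise ValueError("environment with zero neighbors")
    X, mask = _pack(mats)
    probs, _, _, _ = nn.forward(
        model.params, X, mask, model.config.layers, model.config.heads
    )
    return probs


def predict_distribution(
    model: ClassifierModel, features: EnvironmentFeatures | np.ndarray
) -> np.ndarray:
    """20-way distribution for a single environment."""
    return predict_batch(model, [features])[0]


def embed_environment(
    model: ClassifierModel, features: EnvironmentFeatures | np.ndarray
) -> np.ndarray:
    """K×model_dim transformer output (pre-pooling token embeddings)."""
    m = features.matrix if isinstance(features, EnvironmentFeatures) else features
    if m.shape[1] != model.config.input_dim:
        raise ValueError(f"expected K×{model.config.input_dim} features")
    X, mask = _pack([np.asarray(m)])
    _, _, tokens, _ = nn.forward(
        model.params, X, mask, model.config.layers, model.config.heads
    )
    return tokens[0]


def confidence_score(distribution: np.ndarray) -> float:
    """Negative Shannon entropy Σ p ln p (natural log; 0·ln 0 := 0).

    0 for a point mass; −ln 20 ≈ −2.9957 for the uniform distribution.
    """
    p = np.asarray(distribution, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("confidence_score expects a normalized distribution")
    nz = p[p > 0]
    return float(np.sum(nz * np.log(nz)))


# ---------------------------------------------------------------------------
# training


def train(
    model: ClassifierModel,
    features: Sequence[np.ndarray],
    labels: Sequence[int],
    config: TrainingConfig,
) -> tuple[ClassifierModel, list[float]]:
    """Minimize mean cross-entropy over labeled environments.

    ``features`` are K_i×46 matrices; ``labels`` canonical type indices
    (0–19).  Returns a trained copy of the model and the per-epoch mean
    training loss.  Shuffling, and hence the whole run, is seeded.
    """
    config.validate()
    labels = np.asarray(labels, dtype=int)
    if len(features) == 0:
        raise ValueError("empty training set")
    if labels.min() < 0 or labels.max() >= alphabet.N_TYPES:
        raise ValueError("labels must be canonical type indices 0..19")
    if any(f.shape[0] < 1 for f in features):
        raise ValueError("every training environment needs at least one neighbor")

    model = model.copy()
    if config.epochs == 0:
        return model, []
    opt = nn.Adam(
        model.params,
        lr=config.learning_rate,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
    )
    rng = np.random.default_rng(config.seed)
    n = len(features)
    # Bucket by K so each minibatch pads as little as possible.
    order0 = sorted(range(n), key=lambda i: features[i].shape[0])
    trace: list[float] = []
    for _ in range(config.epochs):
        # batches of K-sorted indices (minimal padding); batch order shuffled
        batches = [
            order0[s : s + config.batch_size]
            for s in range(0, n, config.batch_size)
        ]
        batch_order = rng.permutation(len(batches))
        epoch_loss = 0.0
        seen = 0
        for bi in batch_order:
            idx = batches[bi]
            # within-batch shuffle for optimizer symmetry-breaking only
            idx = [idx[j] for j in rng.permutation(len(idx))]
            X, mask = _pack([features[i] for i in idx])
            y = labels[idx]
            probs, _, _, cache = nn.forward(
                model.params, X, mask, model.config.layers, model.config.heads,
                want_cache=True,
            )
            loss, dlogits = nn.cross_entropy(probs, y)
            grads = nn.backward(
                model.params, cache, dlogits, model.config.layers,
                model.config.heads,
            )
            opt.step(model.params, grads)
            epoch_loss += loss * len(idx)
            seen += len(idx)
        trace.append(epoch_loss / seen)
    return model, trace


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: ClassifierModel, path: str | Path) -> None:
    """Serialize config + parameters + alphabet + format version (.npz)."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "alphabet": list(alphabet.ONE_LETTER),
        "input_dim": model.config.input_dim,
    }
    arrays = dict(model.params)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> ClassifierModel:
    """Load a checkpoint; refuses incompatible format or alphabet."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"checkpoint format {meta['format_version']} unsupported"
            )
        if meta["alphabet"] != list(alphabet.ONE_LETTER):
            raise ValueError("checkpoint alphabet does not match this build")
        config = ModelConfig(**meta["config"])
        params = {k: data[k].copy() for k in data.files if k != "__meta__"}
    return ClassifierModel(config=config, params=params)
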