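"""Per-omics supervised GCN feature learning.

One model per omics view: two graph-convolution layers (ELU) followed by a
linear output layer. Training is transductive — the Laplacian covers all
aligned samples but the cross-entropy loss is masked to training rows.
Latent embeddings are read from the first convolution layer by default.

The networks are small enough that forward and backward passes are written
directly in NumPy; gradients are exact (verified against numerical
differentiation in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._nn import Adam, cross_entropy, dropout_mask, elu, elu_grad, softmax

__all__ = [
    "GCNConfig",
    "GCNModel",
    "LatentEmbedding",
    "gcn_forward",
    "train_gcn",
    "extract_latent",
    "select_omics",
    "concatenate_latents",
]


@dataclass
class GCNConfig:
    hidden: int = 100
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 300
    patience: int = 30
    val_fraction: float = 0.1
    elu_alpha: float = 1.0
    seed: int = 0


@dataclass
class GCNModel:
    """Two graph convolutions (d->h, h->h) plus a linear head (h->c)."""

    W0: np.ndarray
    b0: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    config: GCNConfig = field(default_factory=GCNConfig)

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W0": self.W0, "b0": self.b0, "W1": self.W1,
                "b1": self.b1, "W2": self.W2, "b2": self.b2}

    @property
    def hidden_size(self) -> int:
        return self.W0.shape[1]

    @property
    def n_classes(self) -> int:
        return self.W2.shape[1]


@dataclass
class LatentEmbedding:
    """Activations of one GCN layer used as learned features."""

    values: np.ndarray
    source_omics: str
    layer: int | str  # 1, 2, or "output"


def _init_model(d: int, h: int, c: int, config: GCNConfig,
                rng: np.random.Generator) -> GCNModel:
    # uniform fan-in scaled init
    def u(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    return GCNModel(
        W0=u(d, (d, h)), b0=u(d, (h,)),
        W1=u(h, (h, h)), b1=u(h, (h,)),
        W2=u(h, (h, c)), b2=u(h, (c,)),
        config=replace(config),
    )


def _check_dims(H0: np.ndarray, L: np.ndarray, model: GCNModel) -> None:
    if H0.shape[1] != model.W0.shape[0]:
        raise ValueError(
            f"layer 0: input has {H0.shape[1]} features, "
            f"W0 expects {model.W0.shape[0]}")
    if L.shape[0] != L.shape[1] or L.shape[0] != H0.shape[0]:
        raise ValueError(
            f"Laplacian shape {L.shape} incompatible with "
            f"{H0.shape[0]} samples")


def gcn_forward(H0: np.ndarray, L: np.ndarray, model: GCNModel,
                training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward pass: H1 = elu(L H0 W0 + b0), H2 = elu(L H1 W1 + b1),
    Y = H2 W2 + b2 (logits). Dropout is applied between layers only when
    ``training`` is set."""
    out = _forward_cache(H0, L, model, training=training, rng=rng)
    return out["H1"], out["H2"], out["Y"]


def _forward_cache(H0: np.ndarray, L: np.ndarray, model: GCNModel,
                   training: bool = False,
                   rng: np.random.Generator | None = None) -> dict:
    _check_dims(H0, L, model)
    cfg = model.config
    a = cfg.elu_alpha
    rate = cfg.dropout if training else 0.0
    if rate > 0 and rng is None:
        raise ValueError("training forward pass requires an rng for dropout")

    Z0 = L @ H0 @ model.W0 + model.b0
    H1 = elu(Z0, a)
    M1 = dropout_mask(H1.shape, rate, rng) if rate > 0 else 1.0
    D1 = H1 * M1
    Z1 = L @ D1 @ model.W1 + model.b1
    H2 = elu(Z1, a)
    M2 = dropout_mask(H2.shape, rate, rng) if rate > 0 else 1.0
    D2 = H2 * M2
    Y = D2 @ model.W2 + model.b2
    return {"Z0": Z0, "H1": H1, "M1": M1, "D1": D1,
            "Z1": Z1, "H2": H2, "M2": M2, "D2": D2, "Y": Y}


def _backward(H0: np.ndarray, L: np.ndarray, model: GCNModel, cache: dict,
              dY: np.ndarray) -> dict[str, np.ndarray]:
    a = model.config.elu_alpha
    grads: dict[str, np.ndarray] = {}
    grads["W2"] = cache["D2"].T @ dY
    grads["b2"] = dY.sum(axis=0)
    dD2 = dY @ model.W2.T
    dH2 = dD2 * cache["M2"]
    dZ1 = dH2 * elu_grad(cache["Z1"], a)
    LD1 = L @ cache["D1"]
    grads["W1"] = LD1.T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    dD1 = L.T @ dZ1 @ model.W1.T
    dH1 = dD1 * cache["M1"]
    dZ0 = dH1 * elu_grad(cache["Z0"], a)
    LH0 = L @ H0
    grads["W0"] = LH0.T @ dZ0
    grads["b0"] = dZ0.sum(axis=0)
    return grads


def train_gcn(H0: np.ndarray, L: np.ndarray, labels: np.ndarray,
              train_indices: np.ndarray, config: GCNConfig | None = None
              ) -> tuple[GCNModel, dict]:
    """Train a GCN transductively with masked cross-entropy.

    A ``val_fraction`` slice of ``train_indices`` is held out for early
    stopping (patience on validation loss) and reported as
    ``history['val_accuracy']`` for downstream omics selection; the loss
    is computed on the remaining training rows only.

    Returns the trained model and a history dict with loss traces.
    """
    config = config or GCNConfig()
    H0 = np.asarray(H0, dtype=float)
    labels = np.asarray(labels, dtype=int)
    train_indices = np.asarray(train_indices, dtype=int)
    n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(config.seed)

    perm = rng.permutation(train_indices)
    n_val = int(np.floor(config.val_fraction * len(perm)))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if len(fit_idx) == 0:
        raise ValueError("no training rows left after validation split")

    model = _init_model(H0.shape[1], config.hidden, n_classes, config, rng)
    opt = Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)

    history: dict = {"train_loss": [], "val_loss": [], "val_accuracy": None}
    best_val = np.inf
    best_params = None
    best_val_acc = None
    stall = 0
    for epoch in range(config.epochs):
        cache = _forward_cache(H0, L, model, training=True, rng=rng)
        loss, dY = cross_entropy(cache["Y"], labels, fit_idx)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {loss}")
        history["train_loss"].append(loss)
        grads = _backward(H0, L, model, cache, dY)
        opt.step(grads)

        if n_val:
            _, _, Y = gcn_forward(H0, L, model, training=False)
            val_loss, _ = cross_entropy(Y, labels, val_idx)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                pred = Y[val_idx].argmax(axis=1)
                best_val_acc = float(np.mean(pred == labels[val_idx]))
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break

    if best_params is not None:
        for k, v in best_params.items():
            model.params[k][...] = v
    _, _, Y = gcn_forward(H0, L, model, training=False)
    if n_val:
        history["val_accuracy"] = best_val_acc
    else:  # fall back to training accuracy
        pred = Y[fit_idx].argmax(axis=1)
        history["val_accuracy"] = float(np.mean(pred == labels[fit_idx]))
    history["train_accuracy"] = float(
        np.mean(Y[train_indices].argmax(axis=1) == labels[train_indices]))
    return model, history


def extract_latent(H0: np.ndarray, L: np.ndarray, model: GCNModel,
                   layer: int | str = 1,
                   source_omics: str = "omics") -> LatentEmbedding:
    """Deterministic forward pass (dropout off) returning one layer's
    activations: 1 or 2 for the convolution layers, "output" for the
    class-probability logits of the linear head."""
    H1, H2, Y = gcn_forward(H0, L, model, training=False)
    if layer == 1:
        values = H1
    elif layer == 2:
        values = H2
    elif layer == "output":
        values = Y
    else:
        raise ValueError("layer must be 1, 2 or 'output'")
    return LatentEmbedding(values=values, source_omics=source_omics,
                           layer=layer)


def predict_proba(H0: np.ndarray, L: np.ndarray,
                  model: GCNModel) -> np.ndarray:
    """Class probabilities from the trained model (softmax of the head)."""
    _, _, Y = gcn_forward(H0, L, model, training=False)
    return softmax(Y, axis=1)


def select_omics(per_omics_val_accuracy: dict[str, float],
                 rule: str = "margin", margin: float = 0.15,
                 top_k: int | None = None) -> list[str]:
    """Choose which omics views feed the fusion stage.

    Rules: ``margin`` keeps every view whose validation accuracy is within
    ``margin`` of the best; ``all`` keeps everything; ``top_k`` keeps the
    ``top_k`` best (ties broken by declaration order).
    """
    if not per_omics_val_accuracy:
        raise ValueError("no omics scores provided")
    names = list(per_omics_val_accuracy)
    if rule == "all":
        return names
    scores = per_omics_val_accuracy
    if rule == "margin":
        best = max(scores.values())
        selected = [o for o in names if scores[o] >= best - margin]
    elif rule == "top_k":
        if top_k is None:
            raise ValueError("top_k rule requires top_k")
        ranked = sorted(names, key=lambda o: -scores[o])
        selected = [o for o in names if o in set(ranked[:top_k])]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    if not selected:
        best_name = max(names, key=lambda o: scores[o])
        warnings.warn("omics selection came back empty; "
                      f"falling back to best single view {best_name!r}")
        selected = [best_name]
    return selected


def concatenate_latents(latents: list[LatentEmbedding]) -> np.ndarray:
    """Column-wise concatenation of latent matrices in declared order."""
    if not latents:
        raise ValueError("no latent embeddings to concatenate")
    n = latents[0].values.shape[0]
    for lat in latents[1:]:
        if lat.values.shape[0] != n:
            raise ValueError(
                f"latent from {lat.source_omics!r} has "
                f"{lat.values.shape[0]} rows, expected {n}")
    return np.hstack([lat.values for lat in latents])
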