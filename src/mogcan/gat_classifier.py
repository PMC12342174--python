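"""Graph-attention subtype classifier on the fused patient network.

A single two-head graph attention layer (per-head linear projection,
LeakyReLU attention scores soft-maxed over each node's neighborhood, ELU
output, heads concatenated) followed by a linear softmax head. The fused
network's non-zero pattern defines neighborhoods; self-loops count because
the fused similarity keeps a positive diagonal.

Backpropagation is hand-derived NumPy (validated against numerical
gradients in the tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from ._nn import (Adam, cross_entropy, dropout_mask, elu, elu_grad,
                  leaky_relu, leaky_relu_grad, softmax)

__all__ = [
    "GATConfig",
    "GATModel",
    "SubtypePrediction",
    "attention_coefficients",
    "gat_forward",
    "train_gat",
    "evaluate",
]


@dataclass
class GATConfig:
    n_heads: int = 2
    head_dim: int = 100
    leaky_slope: float = 0.2
    dropout: float = 0.5
    lr: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 300
    patience: int = 30
    val_fraction: float = 0.1
    elu_alpha: float = 1.0
    seed: int = 0


@dataclass
class GATModel:
    """Per-head projection W and attention vector a (split into the source
    and target halves), plus the linear classifier head."""

    W_att: list[np.ndarray]   # per head: (d_in, d_head)
    a_att: list[np.ndarray]   # per head: (2 * d_head,)
    Wcls: np.ndarray          # (n_heads * d_head, n_classes)
    bcls: np.ndarray
    config: GATConfig = field(default_factory=GATConfig)

    @property
    def n_heads(self) -> int:
        return len(self.W_att)

    @property
    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for h in range(self.n_heads):
            out[f"W{h}"] = self.W_att[h]
            out[f"a{h}"] = self.a_att[h]
        out["Wcls"] = self.Wcls
        out["bcls"] = self.bcls
        return out


@dataclass
class SubtypePrediction:
    """Per-sample class probabilities, hard labels and evaluation output."""

    probabilities: np.ndarray
    hard_labels: np.ndarray
    metrics: dict = field(default_factory=dict)
    confusion: np.ndarray | None = None


def _neighbor_mask(P: np.ndarray) -> np.ndarray:
    if (P < 0).any():
        raise ValueError("fused network must be non-negative")
    mask = P > 0
    isolated = np.flatnonzero(~mask.any(axis=1))
    if isolated.size:
        raise ValueError(
            f"nodes {isolated.tolist()} have no neighbors; rerun threshold "
            "selection with a larger retention fraction")
    return mask


def attention_coefficients(H: np.ndarray, P: np.ndarray, W_att: np.ndarray,
                           a: np.ndarray, leaky_slope: float = 0.2
                           ) -> np.ndarray:
    """Attention matrix alpha for one head.

    alpha(i,j) = softmax over j in {r : P(i,r) > 0} of
    LeakyReLU(a^T [W h_i || W h_j]); exactly zero off-neighborhood, rows
    sum to 1 over each neighborhood.
    """
    mask = _neighbor_mask(P)
    G = H @ W_att
    d = G.shape[1]
    s = G @ a[:d]          # source (center node) contribution
    t = G @ a[d:]          # target (neighbor) contribution
    E = leaky_relu(s[:, None] + t[None, :], leaky_slope)
    E = np.where(mask, E, -np.inf)
    E -= E.max(axis=1, keepdims=True)
    expE = np.where(mask, np.exp(E), 0.0)
    return expE / expE.sum(axis=1, keepdims=True)


def _forward_cache(H: np.ndarray, P: np.ndarray, model: GATModel,
                   training: bool = False,
                   rng: np.random.Generator | None = None) -> dict:
    cfg = model.config
    mask = _neighbor_mask(P)
    rate = cfg.dropout if training else 0.0
    if rate > 0 and rng is None:
        raise ValueError("training forward pass requires an rng for dropout")

    Min = dropout_mask(H.shape, rate, rng) if rate > 0 else 1.0
    Hd = H * Min

    heads = []
    for h in range(model.n_heads):
        W, a = model.W_att[h], model.a_att[h]
        if H.shape[1] != W.shape[0]:
            raise ValueError(
                f"attention head {h}: input width {H.shape[1]} != "
                f"{W.shape[0]}")
        G = Hd @ W
        d = G.shape[1]
        s = G @ a[:d]
        t = G @ a[d:]
        S = s[:, None] + t[None, :]
        E = leaky_relu(S, cfg.leaky_slope)
        Em = np.where(mask, E, -np.inf)
        Em = Em - Em.max(axis=1, keepdims=True)
        expE = np.where(mask, np.exp(Em), 0.0)
        alpha = expE / expE.sum(axis=1, keepdims=True)
        pre = alpha @ G
        out = elu(pre, cfg.elu_alpha)
        heads.append({"G": G, "S": S, "alpha": alpha, "pre": pre,
                      "out": out})

    H_att = np.hstack([hd["out"] for hd in heads])
    Matt = dropout_mask(H_att.shape, rate, rng) if rate > 0 else 1.0
    H_att_d = H_att * Matt
    logits = H_att_d @ model.Wcls + model.bcls
    H_cls = softmax(logits, axis=1)
    return {"mask": mask, "Min": Min, "Hd": Hd, "heads": heads,
            "H_att": H_att, "Matt": Matt, "H_att_d": H_att_d,
            "logits": logits, "H_cls": H_cls}


def gat_forward(H: np.ndarray, P: np.ndarray, model: GATModel,
                training: bool = False,
                rng: np.random.Generator | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass returning the concatenated head outputs ``H_att`` and
    the row-stochastic class probabilities ``H_cls``."""
    cache = _forward_cache(H, P, model, training=training, rng=rng)
    return cache["H_att"], cache["H_cls"]


def _backward(H: np.ndarray, model: GATModel, cache: dict,
              dlogits: np.ndarray) -> dict[str, np.ndarray]:
    cfg = model.config
    grads: dict[str, np.ndarray] = {}
    grads["Wcls"] = cache["H_att_d"].T @ dlogits
    grads["bcls"] = dlogits.sum(axis=0)
    dH_att = (dlogits @ model.Wcls.T) * cache["Matt"]

    dHd = np.zeros_like(cache["Hd"])
    col = 0
    for h in range(model.n_heads):
        hd = cache["heads"][h]
        W, a = model.W_att[h], model.a_att[h]
        dk = W.shape[1]
        dout = dH_att[:, col:col + dk]
        col += dk
        dpre = dout * elu_grad(hd["pre"], cfg.elu_alpha)
        alpha, G = hd["alpha"], hd["G"]
        # pre = alpha @ G
        dalpha = dpre @ G.T
        dG = alpha.T @ dpre
        # softmax over neighborhoods (alpha is 0 off-neighborhood, so the
        # standard row-softmax jacobian applies unchanged)
        dE = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        dS = dE * leaky_relu_grad(hd["S"], cfg.leaky_slope)
        rs = dS.sum(axis=1)   # d/d s_i
        cs = dS.sum(axis=0)   # d/d t_j
        a_s, a_t = a[:dk], a[dk:]
        da = np.concatenate([G.T @ rs, G.T @ cs])
        dG += np.outer(rs, a_s) + np.outer(cs, a_t)
        grads[f"W{h}"] = cache["Hd"].T @ dG
        grads[f"a{h}"] = da
        dHd += dG @ W.T
    # input dropout (gradient w.r.t. H not needed: H is data)
    return grads


def _init_model(d_in: int, n_classes: int, config: GATConfig,
                rng: np.random.Generator) -> GATModel:
    def u(fan_in: int, shape: tuple[int, ...]) -> np.ndarray:
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    W_att = [u(d_in, (d_in, config.head_dim)) for _ in range(config.n_heads)]
    a_att = [u(2 * config.head_dim, (2 * config.head_dim,))
             for _ in range(config.n_heads)]
    width = config.n_heads * config.head_dim
    return GATModel(W_att=W_att, a_att=a_att,
                    Wcls=u(width, (width, n_classes)),
                    bcls=u(width, (n_classes,)),
                    config=replace(config))


def train_gat(H: np.ndarray, P: np.ndarray, labels: np.ndarray,
              train_indices: np.ndarray, config: GATConfig | None = None
              ) -> tuple[GATModel, dict]:
    """Train the attention classifier with masked cross-entropy.

    Mirrors the GCN trainer: Adam with L2 weight decay, an internal
    validation slice of the training rows for early stopping, loss on the
    remaining training rows only.
    """
    config = config or GATConfig()
    H = np.asarray(H, dtype=float)
    labels = np.asarray(labels, dtype=int)
    train_indices = np.asarray(train_indices, dtype=int)
    n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(config.seed)

    perm = rng.permutation(train_indices)
    n_val = int(np.floor(config.val_fraction * len(perm)))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    if len(fit_idx) == 0:
        raise ValueError("no training rows left after validation split")

    model = _init_model(H.shape[1], n_classes, config, rng)
    opt = Adam(model.params, lr=config.lr, weight_decay=config.weight_decay)

    history: dict = {"train_loss": [], "val_loss": [], "val_accuracy": None}
    best_val = np.inf
    best_params = None
    stall = 0
    for epoch in range(config.epochs):
        cache = _forward_cache(H, P, model, training=True, rng=rng)
        loss, dlogits = cross_entropy(cache["logits"], labels, fit_idx)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {loss}")
        history["train_loss"].append(loss)
        grads = _backward(H, model, cache, dlogits)
        opt.step(grads)

        if n_val:
            cache_eval = _forward_cache(H, P, model, training=False)
            val_loss, _ = cross_entropy(cache_eval["logits"], labels, val_idx)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in model.params.items()}
                pred = cache_eval["H_cls"][val_idx].argmax(axis=1)
                history["val_accuracy"] = float(
                    np.mean(pred == labels[val_idx]))
                stall = 0
            else:
                stall += 1
                if stall >= config.patience:
                    break

    if best_params is not None:
        for k, v in best_params.items():
            model.params[k][...] = v
    _, H_cls = gat_forward(H, P, model, training=False)
    history["train_accuracy"] = float(
        np.mean(H_cls[train_indices].argmax(axis=1) == labels[train_indices]))
    if history["val_accuracy"] is None:
        history["val_accuracy"] = history["train_accuracy"]
    return model, history


def predict(H: np.ndarray, P: np.ndarray, model: GATModel
            ) -> SubtypePrediction:
    _, H_cls = gat_forward(H, P, model, training=False)
    return SubtypePrediction(probabilities=H_cls,
                             hard_labels=H_cls.argmax(axis=1))


def evaluate(pred: SubtypePrediction, truth: np.ndarray,
             eval_indices: np.ndarray,
             n_classes: int | None = None) -> dict:
    """Accuracy, macro precision/recall/F1 and confusion matrix on the
    evaluation rows; fills ``pred.metrics`` and ``pred.confusion``.

    Per-class precision/recall with no predicted/true instances resolve
    to 0 (with a warning), matching unweighted macro averaging over all
    known classes.
    """
    truth = np.asarray(truth, dtype=int)
    eval_indices = np.asarray(eval_indices, dtype=int)
    if eval_indices.size == 0:
        raise ValueError("eval_indices is empty")
    y_true = truth[eval_indices]
    y_pred = pred.hard_labels[eval_indices]
    if n_classes is None:
        n_classes = int(max(truth.max(), pred.hard_labels.max())) + 1
    labels = np.arange(n_classes)

    present = np.union1d(np.unique(y_true), np.unique(y_pred))
    absent = np.setdiff1d(labels, present)
    if absent.size:
        warnings.warn(
            f"classes {absent.tolist()} absent from both prediction and "
            "truth in the evaluation set; they contribute 0 to macro "
            "averages")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn zero-division chatter
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0)
    metrics = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "macro_precision": float(prec),
        "macro_recall": float(rec),
        "macro_f1": float(f1),
        "n_evaluated": int(eval_indices.size),
    }
    pred.metrics = metrics
    pred.confusion = confusion_matrix(y_true, y_pred, labels=labels)
    return metrics
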