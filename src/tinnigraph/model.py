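"""GCN-LSTM node classifier.

Architecture: L graph-convolution layers, each computing
``X_l = ReLU(D^-1/2 (A + I) D^-1/2 X_{l-1} W_l)`` over the
symmetric-normalized adjacency; the final node embedding of width F is
then reshaped into T contiguous pseudo-time steps of width F/T, run
through a single-layer LSTM, and the hidden state of the last step is
mapped to two class logits by a fully connected layer.

The pseudo-time reshape deserves emphasis: node embeddings carry no
temporal axis, so the "sequence" the LSTM consumes is a fixed chunking
of the embedding dimensions. It is implemented literally (contiguous
chunks, invertible) and its arbitrariness is documented rather than
hidden.

Training minimizes softmax cross-entropy on the training-mask nodes with
Adam, L2 weight decay, inter-layer dropout, and early stopping on
validation loss (best weights restored). Everything is seeded:
identical config, graph, and seed give bit-identical weights.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._autograd import Adam, Tensor, cross_entropy, spmm
from .graph import FeatureGraph, NormalizedAdjacency, normalize_adjacency

__all__ = [
    "ModelConfig",
    "GCNLSTM",
    "TrainedModel",
    "gcn_layer_forward",
    "reshape_to_sequence",
    "lstm_forward",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    gcn_dims: tuple[int, ...] = (64, 64, 32)
    lstm_steps: int = 4                 # T: pseudo-time steps for the reshape
    lstm_hidden: int = 32
    n_classes: int = 2
    learning_rate: float = 1e-3
    max_epochs: int = 1500
    patience: int = 50
    weight_decay: float = 5e-4
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.gcn_dims) < 1:
            raise ValueError("need at least one GCN layer")
        if self.gcn_dims[-1] % self.lstm_steps != 0:
            raise ValueError(
                f"final GCN width {self.gcn_dims[-1]} must be divisible by "
                f"lstm_steps={self.lstm_steps}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


# ---------------------------------------------------------------------------
# Functional pieces (each independently testable)
# ---------------------------------------------------------------------------

def gcn_layer_forward(x_prev: Tensor, norm_adj: NormalizedAdjacency,
                      w: Tensor) -> Tensor:
    """One graph convolution: ReLU(normA @ X @ W)."""
    if x_prev.shape[1] != w.shape[0]:
        raise ValueError(f"shape mismatch: X has {x_prev.shape[1]} features, "
                         f"W expects {w.shape[0]}")
    return spmm(norm_adj.matrix, x_prev @ w).relu()


def reshape_to_sequence(x: Tensor, n_steps: int) -> list[Tensor]:
    """Chunk the width-F embedding into n_steps contiguous steps of width F/T."""
    n, f = x.shape
    if f % n_steps != 0:
        raise ValueError(f"width {f} not divisible by {n_steps} steps")
    step = f // n_steps
    return [x[:, t * step:(t + 1) * step] for t in range(n_steps)]


def lstm_forward(steps: list[Tensor], w_x: Tensor, w_h: Tensor, b: Tensor,
                 hidden: int) -> tuple[list[Tensor], Tensor, Tensor]:
    """Standard LSTM recurrence over a list of (n, input) step tensors.

    Gate layout in the stacked weight matrices is [input, forget, cell, output].
    Initial hidden and cell states are zero. Returns (all hidden states,
    final hidden state, final cell state).
    """
    n = steps[0].shape[0]
    h = Tensor(np.zeros((n, hidden)))
    c = Tensor(np.zeros((n, hidden)))
    outputs: list[Tensor] = []
    for x_t in steps:
        gates = (x_t @ w_x) + (h @ w_h) + b
        i = gates[:, 0 * hidden:1 * hidden].sigmoid()
        f = gates[:, 1 * hidden:2 * hidden].sigmoid()
        g = gates[:, 2 * hidden:3 * hidden].tanh()
        o = gates[:, 3 * hidden:4 * hidden].sigmoid()
        c = (f * c) + (i * g)
        h = o * c.tanh()
        outputs.append(h)
    return outputs, h, c


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class GCNLSTM:
    """Parameter container plus forward pass; weights live in ``self.params``."""

    def __init__(self, in_dim: int, config: ModelConfig):
        self.config = config
        self.in_dim = in_dim
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, Tensor] = {}
        prev = in_dim
        for l, width in enumerate(config.gcn_dims):
            self.params[f"gcn_w{l}"] = Tensor(_glorot(rng, prev, width),
                                              requires_grad=True)
            prev = width
        step_in = config.gcn_dims[-1] // config.lstm_steps
        hid = config.lstm_hidden
        self.params["lstm_wx"] = Tensor(_glorot(rng, step_in, 4 * hid),
                                        requires_grad=True)
        self.params["lstm_wh"] = Tensor(_glorot(rng, hid, 4 * hid),
                                        requires_grad=True)
        self.params["lstm_b"] = Tensor(np.zeros(4 * hid), requires_grad=True)
        self.params["fc_w"] = Tensor(_glorot(rng, hid, config.n_classes),
                                     requires_grad=True)
        self.params["fc_b"] = Tensor(np.zeros(config.n_classes),
                                     requires_grad=True)

    def forward(self, x: np.ndarray, norm_adj: NormalizedAdjacency,
                dropout_rng: np.random.Generator | None = None
                ) -> tuple[Tensor, Tensor]:
        """Return (logits, penultimate H_T). Dropout only when a rng is given."""
        cfg = self.config
        h = Tensor(np.asarray(x, dtype=float))
        for l in range(len(cfg.gcn_dims)):
            h = gcn_layer_forward(h, norm_adj, self.params[f"gcn_w{l}"])
            if dropout_rng is not None and cfg.dropout > 0:
                keep = (dropout_rng.random(h.shape) >= cfg.dropout)
                h = h * (keep / (1.0 - cfg.dropout))
        steps = reshape_to_sequence(h, cfg.lstm_steps)
        _, h_last, _ = lstm_forward(steps, self.params["lstm_wx"],
                                    self.params["lstm_wh"],
                                    self.params["lstm_b"], cfg.lstm_hidden)
        logits = (h_last @ self.params["fc_w"]) + self.params["fc_b"]
        return logits, h_last

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.array(state[k], dtype=float)


@dataclass
class TrainedModel:
    model: GCNLSTM
    config: ModelConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    best_epoch: int = -1


def train(g: FeatureGraph, train_idx: np.ndarray, val_idx: np.ndarray,
          config: ModelConfig | None = None,
          norm_adj: NormalizedAdjacency | None = None) -> TrainedModel:
    """Fit the GCN-LSTM on the train-mask nodes of one graph.

    Early stopping monitors validation loss with the configured patience
    and restores the best weights. Raises on non-finite loss.
    """
    cfg = config or ModelConfig()
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if len(np.unique(g.y[train_idx])) < 2:
        raise ValueError("training mask must contain both classes")
    na = norm_adj or normalize_adjacency(g)
    model = GCNLSTM(g.X.shape[1], cfg)
    opt = Adam(model.params, lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    dropout_rng = np.random.default_rng(cfg.seed + 1)

    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    wait = 0
    for epoch in range(cfg.max_epochs):
        logits, _ = model.forward(g.X, na, dropout_rng=dropout_rng)
        loss = cross_entropy(logits[train_idx], g.y[train_idx])
        if not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged at epoch {epoch}: "
                               f"loss={loss.data}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        eval_logits, _ = model.forward(g.X, na)
        tr_loss = cross_entropy(eval_logits[train_idx], g.y[train_idx]).data
        va_loss = cross_entropy(eval_logits[val_idx], g.y[val_idx]).data
        pred = eval_logits.data.argmax(axis=1)
        history["train_loss"].append(float(tr_loss))
        history["val_loss"].append(float(va_loss))
        history["train_acc"].append(float((pred[train_idx] == g.y[train_idx]).mean()))
        history["val_acc"].append(float((pred[val_idx] == g.y[val_idx]).mean()))

        if va_loss < best_val - 1e-12:
            best_val = float(va_loss)
            best_state = model.state_dict()
            best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait > cfg.patience:
                break
    model.load_state_dict(best_state)
    return TrainedModel(model=model, config=cfg, history=history,
                        best_epoch=best_epoch)


def predict(tm: TrainedModel, g: FeatureGraph,
            mask: np.ndarray | None = None,
            norm_adj: NormalizedAdjacency | None = None
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(labels, class probabilities, penultimate activations) for masked nodes."""
    na = norm_adj or normalize_adjacency(g)
    logits, h_last = tm.model.forward(g.X, na)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    if mask is not None:
        mask = np.asarray(mask, dtype=int)
        probs = probs[mask]
        h = h_last.data[mask]
    else:
        h = h_last.data
    return probs.argmax(axis=1), probs, h


def save_model(tm: TrainedModel, path: str | Path) -> None:
    """Weights as npz plus a JSON config/history sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), in_dim=np.array(tm.model.in_dim),
             **tm.model.state_dict())
    sidecar = {"config": asdict(tm.config), "history": tm.history,
               "best_epoch": tm.best_epoch}
    path.with_suffix(".json").write_text(json.dumps(sidecar, sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    raw = dict(sidecar["config"])
    raw["gcn_dims"] = tuple(raw["gcn_dims"])
    cfg = ModelConfig(**raw)
    with np.load(path.with_suffix(".npz")) as z:
        state = {k: z[k] for k in z.files if k != "in_dim"}
        in_dim = int(z["in_dim"])
    model = GCNLSTM(in_dim, cfg)
    model.load_state_dict(state)
    return TrainedModel(model=model, config=cfg, history=sidecar["history"],
                        best_epoch=sidecar["best_epoch"])
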