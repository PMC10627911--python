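"""Slide-level age regression network.

Architecture (forward order):

1. **Graph module** — two GraphSAGE convolutions (mean aggregator with a
   separate self-path weight), each followed by ReLU, mapping the tile
   features ``X (M, F)`` to node representations ``G' (M, d)`` with
   hidden width ``d = 256`` by default.
2. **Attention pooling** — pooling by multi-head attention: a single
   learnable seed query attends over the nodes with 2 heads; the key and
   value projections are themselves GraphSAGE transforms over the same
   adjacency, so the pooler remains topology-aware. Per-head softmax
   weights over nodes are the tile-salience scores used in all
   downstream attention analyses (as their mean across heads). Head
   outputs are concatenated and linearly mixed into the slide
   representation ``Z (1, d)``.
3. **Head** — a fully connected layer ``d -> 1`` predicting age in
   years. Labels are not rescaled, so the MSE training loss is in
   years^2 and MAE is directly interpretable.

Two ablations reproduce the comparison lattice: ``ablate_graph``
replaces both convolutions (and the pooler's internal ones) with
per-node perceptron layers of identical widths — no message passing;
``ablate_attention`` replaces the pooler with an unweighted mean over
nodes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import sparse

from .autodiff import Tensor, concat, relu, softmax
from .graph import SlideGraph

__all__ = ["ModelConfig", "HistoAgeNet", "mse_loss", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    input_dim: int = 1024
    hidden_dim: int = 256
    n_graph_layers: int = 2
    n_heads: int = 2
    dropout: float = 0.30
    ablate_graph: bool = False
    ablate_attention: bool = False

    def __post_init__(self):
        if self.hidden_dim <= 0 or self.n_heads < 1:
            raise ValueError("hidden_dim must be positive and n_heads >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")


def _norm_adjacency(A: sparse.spmatrix) -> np.ndarray:
    """Row-normalised dense adjacency D^-1 A (zero rows stay zero)."""
    a = np.asarray(A.todense(), dtype=np.float64)
    deg = a.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        an = np.where(deg > 0, a / np.maximum(deg, 1.0), 0.0)
    return an


class _Sage:
    """One GraphSAGE (or, ablated, perceptron) layer: F_in -> F_out."""

    def __init__(self, rng, d_in: int, d_out: int, prefix: str,
                 params: dict, message_passing: bool):
        lim = np.sqrt(6.0 / (d_in + d_out))
        params[f"{prefix}.W_self"] = Tensor(rng.uniform(-lim, lim, (d_in, d_out)),
                                            requires_grad=True)
        if message_passing:
            params[f"{prefix}.W_nb"] = Tensor(rng.uniform(-lim, lim, (d_in, d_out)),
                                              requires_grad=True)
        params[f"{prefix}.b"] = Tensor(np.zeros((1, d_out)), requires_grad=True)
        self.prefix = prefix
        self.params = params
        self.message_passing = message_passing

    def __call__(self, h: Tensor, an: Tensor) -> Tensor:
        p = self.params
        out = h @ p[f"{self.prefix}.W_self"] + p[f"{self.prefix}.b"]
        if self.message_passing:
            out = out + (an @ h) @ p[f"{self.prefix}.W_nb"]
        return out


class HistoAgeNet:
    """Graph-convolutional attention-pooled multiple-instance regressor."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        mp = not cfg.ablate_graph
        d = cfg.hidden_dim
        self.graph_layers = [
            _Sage(rng, cfg.input_dim if i == 0 else d, d, f"graph{i}", self.params, mp)
            for i in range(cfg.n_graph_layers)
        ]
        if not cfg.ablate_attention:
            lim = np.sqrt(6.0 / (2 * d))
            self.params["pool.seed"] = Tensor(rng.uniform(-lim, lim, (1, d)),
                                              requires_grad=True)
            self.params["pool.Wq"] = Tensor(rng.uniform(-lim, lim, (d, d)),
                                            requires_grad=True)
            self.key_layer = _Sage(rng, d, d, "pool.key", self.params, mp)
            self.value_layer = _Sage(rng, d, d, "pool.value", self.params, mp)
            self.params["pool.Wo"] = Tensor(rng.uniform(-lim, lim, (d, d)),
                                            requires_grad=True)
        lim = np.sqrt(6.0 / (d + 1))
        self.params["head.w"] = Tensor(rng.uniform(-lim, lim, (d, 1)), requires_grad=True)
        self.params["head.b"] = Tensor(np.zeros((1, 1)), requires_grad=True)

    # ----------------------------------------------------------------- utils
    def parameters(self) -> dict[str, Tensor]:
        return self.params

    def set_head_bias(self, value: float) -> None:
        """Initialise the output bias (conventionally the train-set mean age)."""
        self.params["head.b"].data[...] = value

    def _dropout(self, h: Tensor, train: bool, rng) -> Tensor:
        p = self.cfg.dropout
        if not train or p == 0.0:
            return h
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (rng.uniform(size=h.shape) >= p) / (1.0 - p)
        return h * Tensor(mask)

    # --------------------------------------------------------------- forward
    def forward(self, graph: SlideGraph, train: bool = False, rng=None):
        """Return (predicted age Tensor, activations dict).

        The activations dict carries NumPy copies of ``G'`` (M, d), ``Z``
        (1, d) and per-head post-softmax attention weights (heads, M);
        under ``ablate_attention`` the weights are the implicit uniform
        1/M.
        """
        if graph.n_tiles < 1:
            raise ValueError("graph must contain at least one tile")
        if graph.X.shape[1] != self.cfg.input_dim:
            raise ValueError(
                f"feature dim {graph.X.shape[1]} != model input dim {self.cfg.input_dim}"
            )
        an = Tensor(_norm_adjacency(graph.A))
        h = Tensor(graph.X)
        for layer in self.graph_layers:
            h = relu(layer(h, an))
            h = self._dropout(h, train, rng)
        g_prime = h
        m = graph.n_tiles
        if self.cfg.ablate_attention:
            pool = Tensor(np.full((1, m), 1.0 / m))
            z = pool @ g_prime
            attn = np.full((self.cfg.n_heads, m), 1.0 / m)
        else:
            d = self.cfg.hidden_dim
            dh = d // self.cfg.n_heads
            q = self.params["pool.seed"] @ self.params["pool.Wq"]   # (1, d)
            k = self.key_layer(g_prime, an)                          # (M, d)
            v = self.value_layer(g_prime, an)
            heads = []
            attn_rows = []
            for hd in range(self.cfg.n_heads):
                sl = slice(hd * dh, (hd + 1) * dh)
                q_h = Tensor(np.eye(d)[:, sl]).T @ q.T               # (dh, 1)
                k_h = k @ Tensor(np.eye(d)[:, sl])                   # (M, dh)
                v_h = v @ Tensor(np.eye(d)[:, sl])
                logits = (k_h @ q_h).T / np.sqrt(dh)                 # (1, M)
                w = softmax(logits, axis=-1)
                attn_rows.append(w.data.ravel().copy())
                heads.append(w @ v_h)                                # (1, dh)
            z = concat(heads, axis=-1) @ self.params["pool.Wo"]
            attn = np.stack(attn_rows)
        z = self._dropout(z, train, rng)
        y_hat = z @ self.params["head.w"] + self.params["head.b"]
        acts = {"G_prime": g_prime.data.copy(), "Z": z.data.copy(), "attention": attn}
        return y_hat, acts

    def predict(self, graph: SlideGraph) -> float:
        y_hat, _ = self.forward(graph, train=False)
        return float(y_hat.data.squeeze())

    def attention_weights(self, graph: SlideGraph) -> np.ndarray:
        """Per-head post-softmax tile weights, shape (heads, M)."""
        _, acts = self.forward(graph, train=False)
        return acts["attention"]


def mse_loss(preds: list[Tensor], ages: list[float] | np.ndarray) -> Tensor:
    """Mean squared error over a batch of slide-level predictions."""
    if len(preds) == 0:
        raise ValueError("empty batch")
    if len(preds) != len(ages):
        raise ValueError("predictions and ages differ in length")
    total = None
    for p, y in zip(preds, ages):
        sq = (p - float(y)) ** 2
        total = sq if total is None else total + sq
    return total.reshape(1).sum() / len(preds)


def save_checkpoint(net: HistoAgeNet, path: str | Path) -> None:
    arrays = {k.replace(".", "__"): v.data for k, v in net.params.items()}
    cfg = json.dumps(asdict(net.cfg)).encode()
    np.savez_compressed(Path(path), __config__=np.frombuffer(cfg, dtype=np.uint8),
                        **arrays)


def load_checkpoint(path: str | Path) -> HistoAgeNet:
    with np.load(Path(path)) as z:
        cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
        net = HistoAgeNet(cfg)
        for k in net.params:
            net.params[k].data = z[k.replace(".", "__")].copy()
    return net
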