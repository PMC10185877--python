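"""Structural deep network embedding (SDNE) of weighted similarity graphs.

SDNE embeds each node of a weighted graph by training a deep autoencoder
on the rows of the adjacency matrix.  Two proximities are preserved
jointly:

* *second-order* (neighbourhood) proximity through the reconstruction
  loss, with nonzero adjacency entries up-weighted by ``beta > 1`` so
  that observed edges are reconstructed preferentially over the zeros
  of a sparse graph;
* *first-order* (neighbour) proximity through a Laplacian-eigenmap
  penalty ``alpha * sum_ij w_ij ||y_i - y_j||^2`` on the code layer,
  pulling embeddings of strongly connected nodes together.

The total objective is

    L = || (X_hat - X) ⊙ B ||_F^2  +  2 * alpha * tr(Yᵀ L Y)  +  nu * L_reg

with ``B_ij = beta`` where ``x_ij > 0`` else 1, ``L`` the graph
Laplacian, and ``L_reg`` the squared Frobenius norm of the weights.
Training is full-batch Adam with hand-derived gradients; node labels are
canonically sorted before seeding so the embedding is invariant to the
input node order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


class EmbeddingError(ValueError):
    pass


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weighted adjacency with no self-loops."""

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise EmbeddingError(f"adjacency shape {w.shape} does not match "
                                 f"{len(self.nodes)} nodes")
        if not np.allclose(w, w.T, atol=1e-12):
            raise EmbeddingError("adjacency must be symmetric")
        if (w < 0).any():
            raise EmbeddingError("adjacency must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @classmethod
    def from_similarity(cls, labels: list[str], values: np.ndarray) -> "WeightedGraph":
        """Use a dense similarity matrix directly as weighted adjacency."""
        w = np.array(values, dtype=float)
        np.fill_diagonal(w, 0.0)
        return cls(nodes=list(labels), weights=w)


@dataclass
class SDNEConfig:
    dim: int = 64                       # embedding dimension
    hidden_layers: tuple[int, ...] = (128,)
    alpha: float = 1e-2                 # first-order (Laplacian) loss weight
    beta: float = 5.0                   # reconstruction up-weight on edges
    nu: float = 1e-4                    # L2 weight decay
    epochs: int = 200
    learning_rate: float = 1e-2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.beta <= 1:
            raise ValueError("beta must be > 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class EmbeddingMatrix:
    """label × dim embedding; provenance records which network(s) fed each row."""

    labels: list[str]
    vectors: np.ndarray
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[0] != len(self.labels):
            raise EmbeddingError("one vector row per label required")
        if not np.all(np.isfinite(self.vectors)):
            raise EmbeddingError("embedding contains non-finite values")
        self._index = {l: i for i, l in enumerate(self.labels)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def row(self, label: str) -> np.ndarray:
        return self.vectors[self._index[label]]


def _init_layers(sizes: list[int], rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        layers.append({
            "W": rng.uniform(-scale, scale, size=(fan_in, fan_out)),
            "b": np.zeros(fan_out),
        })
    return layers


def _forward(x: np.ndarray, layers: list[dict[str, np.ndarray]],
             code_index: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Activations per layer; tanh on all but the code and output layers."""
    acts = [x]
    h = x
    for k, layer in enumerate(layers):
        z = h @ layer["W"] + layer["b"]
        h = z if k in (code_index, len(layers) - 1) else np.tanh(z)
        acts.append(h)
    return acts, acts[code_index + 1]


def sdne_embed(graph: WeightedGraph, config: SDNEConfig | None = None,
               log_path: str | None = None,
               return_losses: bool = False):
    """Train the SDNE autoencoder on a weighted graph and return code vectors.

    Deterministic for a fixed config seed; node labels are sorted before
    training so the result does not depend on input node order.  With
    ``return_losses=True`` the per-epoch total losses are returned
    alongside the embedding.
    """
    config = config or SDNEConfig()
    n = len(graph.nodes)
    if n < 2:
        raise EmbeddingError("need at least 2 nodes to embed")

    order = np.argsort(np.asarray(graph.nodes, dtype=object))
    labels = [graph.nodes[i] for i in order]
    x = graph.weights[np.ix_(order, order)]

    b = np.where(x > 0, config.beta, 1.0)
    deg = x.sum(axis=1)
    lap = np.diag(deg) - x  # graph Laplacian for the first-order term

    sizes = [n, *config.hidden_layers, config.dim, *reversed(config.hidden_layers), n]
    code_index = len(config.hidden_layers)  # layer index producing the code
    rng = np.random.default_rng(config.seed)
    layers = _init_layers(sizes, rng)

    # Adam state
    m = [{k: np.zeros_like(v) for k, v in l.items()} for l in layers]
    v = [{k: np.zeros_like(vv) for k, vv in l.items()} for l in layers]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses: list[float] = []

    for epoch in range(1, config.epochs + 1):
        acts, y = _forward(x, layers, code_index)
        x_hat = acts[-1]

        resid = (x_hat - x) * b
        loss_2nd = float((resid ** 2).sum())
        loss_1st = 2.0 * float(np.einsum("ij,ij->", y, lap @ y))
        loss_reg = sum(float((l["W"] ** 2).sum()) for l in layers)
        loss = loss_2nd + config.alpha * loss_1st + config.nu * loss_reg
        if not np.isfinite(loss):
            raise EmbeddingError(
                f"training diverged at epoch {epoch} (loss={loss}); "
                "reduce the learning rate or beta")
        losses.append(loss)

        # backprop: delta wrt each layer's post-activation output
        deltas: list[np.ndarray | None] = [None] * len(layers)
        deltas[-1] = 2.0 * resid * b
        for k in range(len(layers) - 2, -1, -1):
            d = deltas[k + 1] @ layers[k + 1]["W"].T
            if k != code_index and k != len(layers) - 1:
                d = d * (1.0 - acts[k + 1] ** 2)  # tanh'
            if k == code_index:
                d = d + config.alpha * 4.0 * (lap @ y)
            deltas[k] = d
        t = epoch
        for k, layer in enumerate(layers):
            d = deltas[k]
            grad_w = acts[k].T @ d + 2.0 * config.nu * layer["W"]
            grad_b = d.sum(axis=0)
            for key, grad in (("W", grad_w), ("b", grad_b)):
                m[k][key] = beta1 * m[k][key] + (1 - beta1) * grad
                v[k][key] = beta2 * v[k][key] + (1 - beta2) * grad ** 2
                m_hat = m[k][key] / (1 - beta1 ** t)
                v_hat = v[k][key] / (1 - beta2 ** t)
                layer[key] -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("epoch\tloss\n")
            for i, l in enumerate(losses, start=1):
                fh.write(f"{i}\t{l:.10g}\n")
    logger.info("SDNE: %d nodes, dim %d, loss %.4g -> %.4g over %d epochs",
                n, config.dim, losses[0], losses[-1], config.epochs)

    _, y = _forward(x, layers, code_index)
    emb = EmbeddingMatrix(labels=labels, vectors=y,
                          provenance={l: ("sdne",) for l in labels})
    return (emb, losses) if return_losses else emb


def merge_embeddings(emb_a: EmbeddingMatrix, emb_b: EmbeddingMatrix) -> EmbeddingMatrix:
    """Merge two embeddings over the label union.

    A label present in only one embedding keeps its row; a label present
    in both gets the elementwise mean of the two rows.
    """
    if emb_a.dim != emb_b.dim:
        raise EmbeddingError(f"dimension mismatch: {emb_a.dim} vs {emb_b.dim}")
    labels = sorted(set(emb_a.labels) | set(emb_b.labels))
    rows, provenance = [], {}
    for label in labels:
        in_a, in_b = label in emb_a._index, label in emb_b._index
        if in_a and in_b:
            rows.append((emb_a.row(label) + emb_b.row(label)) / 2.0)
            provenance[label] = ("merged",)
        elif in_a:
            rows.append(emb_a.row(label))
            provenance[label] = ("a_only",)
        else:
            rows.append(emb_b.row(label))
            provenance[label] = ("b_only",)
    return EmbeddingMatrix(labels=labels, vectors=np.array(rows), provenance=provenance)
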