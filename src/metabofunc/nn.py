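"""Neural-network building blocks for molecular graphs.

Implements the three message-passing layer families used by the package
(graph convolution, graph isomorphism, multi-head graph attention), plain
linear layers, sum-pooling readout, the Adam optimizer and binary
cross-entropy on logits.  Everything runs on the NumPy autodiff engine in
:mod:`metabofunc.autograd` and is deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, gather_rows, segment_sum

__all__ = [
    "Linear",
    "GCNConv",
    "GINConv",
    "GATConv",
    "sum_pool",
    "Adam",
    "bce_with_logits",
]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


def _add_self_loops(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    loops = np.arange(n_nodes, dtype=np.int64)
    return np.concatenate([edge_index, np.stack([loops, loops])], axis=1)


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GCNConv(Module):
    """Graph convolution with symmetric degree normalization and self-loops.

    Bond-type edge features are accepted but ignored: the operator has no
    mechanism to consume them (documented per-architecture behaviour).
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_glorot(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_attr=None) -> Tensor:
        n = h.shape[0]
        ei = _add_self_loops(edge_index, n)
        src, dst = ei[0], ei[1]
        deg = np.bincount(dst, minlength=n).astype(np.float64)
        coef = 1.0 / np.sqrt(deg[src] * deg[dst])
        z = h @ self.weight
        msg = gather_rows(z, src) * coef[:, None]
        return segment_sum(msg, dst, n) + self.bias


class GINConv(Module):
    """Graph isomorphism convolution: MLP((1+eps)·h_i + sum_j h_j), eps = 0."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.lin1 = Linear(in_dim, out_dim, rng)
        self.lin2 = Linear(out_dim, out_dim, rng)
        self.eps = 0.0

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_attr=None) -> Tensor:
        n = h.shape[0]
        src, dst = edge_index[0], edge_index[1]
        agg = h * (1.0 + self.eps) + segment_sum(gather_rows(h, src), dst, n)
        return self.lin2(self.lin1(agg).relu())


class GATConv(Module):
    """Multi-head graph attention with additive attention and self-loops.

    Bond-type features enter the attention score through a learned
    projection, so the attention an atom pays a neighbour can depend on the
    bond between them.  Self-loop edges carry an all-zero bond feature.
    Attention coefficients of the most recent forward pass are cached in
    ``last_alpha``/``last_edge_index`` for the attention explainer.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        heads: int,
        rng: np.random.Generator,
        concat_heads: bool = True,
        edge_dim: int | None = None,
        negative_slope: float = 0.2,
    ):
        self.heads = heads
        self.out_dim = out_dim
        self.concat_heads = concat_heads
        self.edge_dim = edge_dim
        self.negative_slope = negative_slope
        self.weight = Tensor(_glorot(rng, in_dim, heads * out_dim), requires_grad=True)
        self.att_src = Tensor(
            _glorot(rng, out_dim, out_dim, shape=(heads, out_dim)), requires_grad=True
        )
        self.att_dst = Tensor(
            _glorot(rng, out_dim, out_dim, shape=(heads, out_dim)), requires_grad=True
        )
        if edge_dim is not None:
            self.weight_edge = Tensor(
                _glorot(rng, edge_dim, heads * out_dim), requires_grad=True
            )
            self.att_edge = Tensor(
                _glorot(rng, out_dim, out_dim, shape=(heads, out_dim)), requires_grad=True
            )
        self.bias = Tensor(
            np.zeros(heads * out_dim if concat_heads else out_dim), requires_grad=True
        )
        self.last_alpha: np.ndarray | None = None
        self.last_edge_index: np.ndarray | None = None

    def __call__(self, h: Tensor, edge_index: np.ndarray, edge_attr: np.ndarray | None = None) -> Tensor:
        n = h.shape[0]
        n_real = edge_index.shape[1]
        ei = _add_self_loops(edge_index, n)
        src, dst = ei[0], ei[1]

        z = (h @ self.weight).reshape(n, self.heads, self.out_dim)
        # per-node attention logits, shape (n, heads)
        a_src = (z * self.att_src).sum(axis=2)
        a_dst = (z * self.att_dst).sum(axis=2)
        e = gather_rows(a_src, src) + gather_rows(a_dst, dst)
        if self.edge_dim is not None:
            if edge_attr is None:
                raise ValueError("GATConv built with edge_dim requires edge_attr")
            ea = np.concatenate(
                [np.asarray(edge_attr, dtype=np.float64), np.zeros((n, self.edge_dim))]
            )
            ze = (Tensor(ea) @ self.weight_edge).reshape(len(ea), self.heads, self.out_dim)
            e = e + (ze * self.att_edge).sum(axis=2)
        e = e.leaky_relu(self.negative_slope)

        # softmax over the incoming edges of each destination node
        shift = np.full((n, self.heads), -np.inf)
        np.maximum.at(shift, dst, e.data)
        e_shifted = e - shift[dst]
        ex = e_shifted.exp()
        denom = segment_sum(ex, dst, n)
        alpha = ex / gather_rows(denom, dst)

        self.last_alpha = alpha.data[:n_real].copy()
        self.last_edge_index = ei[:, :n_real].copy()

        msg = alpha.reshape(len(src), self.heads, 1) * gather_rows(z, src)
        out = segment_sum(msg, dst, n)  # (n, heads, out_dim)
        if self.concat_heads:
            out = out.reshape(n, self.heads * self.out_dim)
        else:
            out = out.mean(axis=1)
        return out + self.bias


def sum_pool(h: Tensor, batch: np.ndarray, n_graphs: int) -> Tensor:
    """Sum node embeddings per graph (sum-aggregation readout)."""
    return segment_sum(h, batch, n_graphs)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable on logits."""
    y = np.asarray(targets, dtype=np.float64)
    absx = logits.relu() + (-logits).relu()
    return (logits.relu() - logits * y + ((-absx).exp() + 1.0).log()).mean()


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 0.005, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
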