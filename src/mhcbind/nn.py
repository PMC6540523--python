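"""Neural-network building blocks for the binding model.

Layers are thin parameter containers whose forward passes build an autodiff
graph (see ``mhcbind._tensor``). Sequences of different lengths are handled
by bucketing a minibatch by length, so no padding or masking is needed —
the recurrent layers genuinely consume variable-length input.

Dropout follows the variational convention for recurrent layers: one mask
per example, shared across timesteps, for both the input-to-gate and the
recurrent connections.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, concat, gather_rows

__all__ = ["Dense", "Embedding", "GRU", "BiGRU", "Adam", "Module"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Module:
    """Base class: recursive parameter collection and weight (de)serialization."""

    def weight_tensors(self) -> list[Tensor]:
        """All weight arrays, including currently frozen ones."""
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.weight_tensors())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.weight_tensors())
        return out

    def parameters(self) -> list[Tensor]:
        """Trainable weights only (frozen embeddings excluded)."""
        return [t for t in self.weight_tensors() if t.requires_grad]

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.weight_tensors()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.weight_tensors()
        if len(params) != len(weights):
            raise ValueError(f"expected {len(params)} arrays, got {len(weights)}")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {w.shape}")
            p.data[...] = w


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    """Token-index -> vector lookup table, optionally initialized from a
    pre-trained table and optionally frozen (pre-training adaptation off)."""

    def __init__(self, rng, n_tokens: int, dim: int,
                 pretrained: np.ndarray | None = None):
        if pretrained is not None:
            if pretrained.shape != (n_tokens, dim):
                raise ValueError(
                    f"pretrained table shape {pretrained.shape} does not match "
                    f"({n_tokens}, {dim})")
            data = pretrained.copy()
        else:
            data = rng.normal(0.0, 0.1, size=(n_tokens, dim))
        self.table = Tensor(data, requires_grad=True)

    @property
    def trainable(self) -> bool:
        return self.table.requires_grad

    @trainable.setter
    def trainable(self, flag: bool) -> None:
        self.table.requires_grad = bool(flag)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return gather_rows(self.table, np.asarray(indices))


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(a, -60, 60)))


def gru_cell(x: Tensor, h: Tensor, p: "GRU",
             im: np.ndarray | None, rm: np.ndarray | None) -> Tensor:
    """One GRU timestep as a single fused autodiff node.

        z  = sigmoid(x Wz + hd Uz + bz)      hd = h * recurrent_mask
        r  = sigmoid(x Wr + hd Ur + br)      xd = x * input_mask
        h~ = tanh(xd Wh' ... )  (see below)
        h' = (1 - z) * h + z * h~

    The backward pass is hand-derived and checked against finite
    differences in the test suite; fusing the cell keeps the graph small
    enough for pure-numpy training to be practical.
    """
    xd = x.data if im is None else x.data * im
    hd = h.data if rm is None else h.data * rm
    az = xd @ p.Wz.data + hd @ p.Uz.data + p.bz.data
    ar = xd @ p.Wr.data + hd @ p.Ur.data + p.br.data
    z = _sigmoid(az)
    r = _sigmoid(ar)
    rhd = r * hd
    c = np.tanh(xd @ p.Wh.data + rhd @ p.Uh.data + p.bh.data)
    hnew = (1.0 - z) * h.data + z * c

    parents = (x, h, p.Wz, p.Wr, p.Wh, p.Uz, p.Ur, p.Uh, p.bz, p.br, p.bh)

    def backward(g):
        dz = g * (c - h.data)
        dc = g * z
        dac = dc * (1.0 - c * c)
        daz = dz * z * (1.0 - z)
        drhd = dac @ p.Uh.data.T
        dr = drhd * hd
        dar = dr * r * (1.0 - r)
        dhd = drhd * r + daz @ p.Uz.data.T + dar @ p.Ur.data.T
        if x.requires_grad:
            dxd = daz @ p.Wz.data.T + dar @ p.Wr.data.T + dac @ p.Wh.data.T
            x._accum(dxd if im is None else dxd * im)
        if h.requires_grad:
            dh = g * (1.0 - z)
            dh = dh + (dhd if rm is None else dhd * rm)
            h._accum(dh)
        if p.Wz.requires_grad:
            p.Wz._accum(xd.T @ daz)
            p.Wr._accum(xd.T @ dar)
            p.Wh._accum(xd.T @ dac)
            p.Uz._accum(hd.T @ daz)
            p.Ur._accum(hd.T @ dar)
            p.Uh._accum(rhd.T @ dac)
            p.bz._accum(daz.sum(axis=0))
            p.br._accum(dar.sum(axis=0))
            p.bh._accum(dac.sum(axis=0))

    out = Tensor(hnew)
    if any(t.requires_grad for t in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


class GRU(Module):
    """Single-direction gated recurrent unit; returns the final hidden state.

    Update gate z, reset gate r, candidate h~:
        z = sigmoid(x Wz + h Uz + bz)
        r = sigmoid(x Wr + h Ur + br)
        h~ = tanh(x Wh + (r*h) Uh + bh)
        h' = (1 - z)*h + z*h~
    """

    def __init__(self, rng, n_in: int, units: int):
        self.units = units
        self.Wz = Tensor(glorot(rng, n_in, units), requires_grad=True)
        self.Wr = Tensor(glorot(rng, n_in, units), requires_grad=True)
        self.Wh = Tensor(glorot(rng, n_in, units), requires_grad=True)
        self.Uz = Tensor(glorot(rng, units, units), requires_grad=True)
        self.Ur = Tensor(glorot(rng, units, units), requires_grad=True)
        self.Uh = Tensor(glorot(rng, units, units), requires_grad=True)
        self.bz = Tensor(np.zeros(units), requires_grad=True)
        self.br = Tensor(np.zeros(units), requires_grad=True)
        self.bh = Tensor(np.zeros(units), requires_grad=True)

    def __call__(self, xs: list[Tensor],
                 input_mask: Tensor | None = None,
                 recurrent_mask: Tensor | None = None) -> Tensor:
        """xs: list of (batch, n_in) tensors, one per timestep."""
        batch = xs[0].shape[0]
        h = Tensor(np.zeros((batch, self.units)))
        im = None if input_mask is None else input_mask.data
        rm = None if recurrent_mask is None else recurrent_mask.data
        for x in xs:
            h = gru_cell(x, h, self, im, rm)
        return h


class BiGRU(Module):
    """Forward and reverse GRUs over the same sequence; final states concatenated."""

    def __init__(self, rng, n_in: int, units: int):
        self.fwd = GRU(rng, n_in, units)
        self.bwd = GRU(rng, n_in, units)

    def __call__(self, xs: list[Tensor], input_mask=None, recurrent_mask=None) -> Tensor:
        hf = self.fwd(xs, input_mask, recurrent_mask)
        hb = self.bwd(xs[::-1], input_mask, recurrent_mask)
        return concat([hf, hb], axis=1)


class Adam:
    """Adam optimizer (Kingma & Ba) over a fixed parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
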