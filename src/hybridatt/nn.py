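"""Parameterised layers built on the autodiff engine.

Initialisation is Glorot-uniform throughout, drawn from a caller-supplied
numpy Generator so whole models are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["glorot", "Linear", "BGRU", "dropout_mask", "apply_dropout"]


def glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear:
    """Affine map y = W x + b for 1-D inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.w = glorot(rng, (out_dim, in_dim), in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w @ x + self.b

    def parameters(self, prefix: str) -> dict:
        return {f"{prefix}.w": self.w, f"{prefix}.b": self.b}


class _GRUCellParams:
    """One direction of one GRU layer: gates ordered (reset, update, new)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.w_ih = glorot(rng, (3 * hidden, in_dim), in_dim, hidden)
        self.w_hh = glorot(rng, (3 * hidden, hidden), hidden, hidden)
        self.b_ih = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.b_hh = Tensor(np.zeros(3 * hidden), requires_grad=True)
        self.hidden = hidden

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        q = self.hidden
        gx = self.w_ih @ x + self.b_ih
        gh = self.w_hh @ h + self.b_hh
        r = ad.sigmoid(gx[0:q] + gh[0:q])
        z = ad.sigmoid(gx[q:2 * q] + gh[q:2 * q])
        n = ad.tanh(gx[2 * q:3 * q] + r * gh[2 * q:3 * q])
        return (1.0 - z) * n + z * h

    def run(self, xs: list, reverse: bool = False) -> list:
        h = Tensor(np.zeros(self.hidden))
        order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
        out: dict[int, Tensor] = {}
        for t in order:
            h = self.step(xs[t], h)
            out[t] = h
        return [out[t] for t in range(len(xs))]

    def parameters(self, prefix: str) -> dict:
        return {f"{prefix}.w_ih": self.w_ih, f"{prefix}.w_hh": self.w_hh,
                f"{prefix}.b_ih": self.b_ih, f"{prefix}.b_hh": self.b_hh}


class BGRU:
    """Stacked bidirectional GRU; each state concatenates forward and
    backward per-direction vectors, so states have length 2*hidden."""

    def __init__(self, in_dim: int, hidden: int, layers: int,
                 rng: np.random.Generator):
        self.cells = []
        for layer in range(layers):
            d = in_dim if layer == 0 else 2 * hidden
            fwd = _GRUCellParams(d, hidden, rng)
            bwd = _GRUCellParams(d, hidden, rng)
            self.cells.append((fwd, bwd))
        self.hidden = hidden

    def __call__(self, xs: list) -> list:
        if not xs:
            raise ValueError("BGRU requires a non-empty sequence")
        seq = xs
        for fwd, bwd in self.cells:
            hf = fwd.run(seq, reverse=False)
            hb = bwd.run(seq, reverse=True)
            seq = [ad.concat([f, b]) for f, b in zip(hf, hb)]
        return seq

    def parameters(self, prefix: str) -> dict:
        out: dict = {}
        for i, (fwd, bwd) in enumerate(self.cells):
            out.update(fwd.parameters(f"{prefix}.l{i}.fwd"))
            out.update(bwd.parameters(f"{prefix}.l{i}.bwd"))
        return out


def dropout_mask(rng: np.random.Generator, shape: tuple, rate: float) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability `rate`, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)


def apply_dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
                  train: bool) -> Tensor:
    if not train or rate <= 0.0 or rng is None:
        return x
    return x * Tensor(dropout_mask(rng, x.shape, rate))
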