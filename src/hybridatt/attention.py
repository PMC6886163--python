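"""Hybrid self-attention: channel-wise fusion and time-wise context.

Channel-wise attention gates each channel's view against the global
view through a learned fusional rate r = sigmoid(W_rg's + W_rc'd + b),
blends the two views at that rate, projects the blend to a scalar
energy, and softmax-normalises the energies into channel weights alpha.
The fused epoch vector concatenates the global view with the
alpha-weighted sum of channel views (length 2p).

Time-wise attention applies the same construction over the hidden
states of a 2-layer bidirectional GRU: for query timestamp t and every
key timestamp i, a rate r_{t,i} blends h_t with h_i before the energy
projection, and the softmax over i yields weights beta_t. The context
vector c_t is the beta-weighted sum of the sequence states h_i. (The
weighted-sum form as sometimes printed, sum_i beta_{t,i} * h_t, is
degenerate — it returns h_t for any normalised beta — and is kept here
only as `time_context_literal` for the negative test.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

SIMPLEX_TOL = 1e-6


@dataclass
class ChannelAttentionParams:
    """Weights of Eq-style channel attention: two rate vectors, an
    energy vector, and two scalar biases (all shared across channels)."""

    w_rg: Tensor
    w_rc: Tensor
    b_rc: Tensor
    w_ec: Tensor
    b_ec: Tensor

    @classmethod
    def init(cls, p: int, rng: np.random.Generator) -> "ChannelAttentionParams":
        return cls(
            w_rg=nn.glorot(rng, (p,), p, 1),
            w_rc=nn.glorot(rng, (p,), p, 1),
            b_rc=Tensor(np.zeros(()), requires_grad=True),
            w_ec=nn.glorot(rng, (p,), p, 1),
            b_ec=Tensor(np.zeros(()), requires_grad=True),
        )

    def parameters(self, prefix: str = "att_c") -> dict:
        return {f"{prefix}.w_rg": self.w_rg, f"{prefix}.w_rc": self.w_rc,
                f"{prefix}.b_rc": self.b_rc, f"{prefix}.w_ec": self.w_ec,
                f"{prefix}.b_ec": self.b_ec}


@dataclass
class TimeAttentionParams:
    """Time-wise analogue over BGRU states of length 2q."""

    w_rt: Tensor
    w_ri: Tensor
    b_rt: Tensor
    w_et: Tensor
    b_et: Tensor

    @classmethod
    def init(cls, two_q: int, rng: np.random.Generator) -> "TimeAttentionParams":
        return cls(
            w_rt=nn.glorot(rng, (two_q,), two_q, 1),
            w_ri=nn.glorot(rng, (two_q,), two_q, 1),
            b_rt=Tensor(np.zeros(()), requires_grad=True),
            w_et=nn.glorot(rng, (two_q,), two_q, 1),
            b_et=Tensor(np.zeros(()), requires_grad=True),
        )

    def parameters(self, prefix: str = "att_t") -> dict:
        return {f"{prefix}.w_rt": self.w_rt, f"{prefix}.w_ri": self.w_ri,
                f"{prefix}.b_rt": self.b_rt, f"{prefix}.w_et": self.w_et,
                f"{prefix}.b_et": self.b_et}


def _check_simplex(v: np.ndarray, tol: float = SIMPLEX_TOL) -> None:
    if np.any(v < -tol) or abs(v.sum() - 1.0) > tol:
        raise ValueError("weights must lie on the probability simplex")


# -- channel-wise ----------------------------------------------------


def fusional_rate(s, d, params: ChannelAttentionParams) -> Tensor:
    """r = sigmoid(W_rg's + W_rc'd + b_rc), the view-mixing gate in [0,1]."""
    s, d = ad.as_tensor(s), ad.as_tensor(d)
    if s.shape != d.shape or s.shape != params.w_rg.shape:
        raise ValueError("dimension mismatch in fusional_rate")
    return ad.sigmoid(params.w_rg @ s + params.w_rc @ d + params.b_rc)


def attention_energy(s, d, r, params: ChannelAttentionParams) -> Tensor:
    """e = W_ec'((1-r) * s + r * d) + b_ec (elementwise convex blend)."""
    s, d, r = ad.as_tensor(s), ad.as_tensor(d), ad.as_tensor(r)
    rv = float(r.data)
    if not -SIMPLEX_TOL <= rv <= 1.0 + SIMPLEX_TOL:
        raise ValueError(f"fusional rate {rv} outside [0, 1]")
    blend = (1.0 - r) * s + r * d
    return params.w_ec @ blend + params.b_ec


def channel_scores(energies) -> Tensor:
    """alpha = softmax(e_1..e_C), max-subtracted for stability."""
    if isinstance(energies, Tensor):
        e = energies
    else:
        e = ad.stack([ad.as_tensor(x) for x in energies])
    if e.data.size < 1 or not np.all(np.isfinite(e.data)):
        raise ValueError("energies must be finite and non-empty")
    return ad.softmax(e)


def channel_fuse(s, d_list, alpha) -> Tensor:
    """x_tilde = s (+) sum_c alpha_c * d_c, length 2p."""
    s = ad.as_tensor(s)
    alpha = ad.as_tensor(alpha) if not isinstance(alpha, Tensor) else alpha
    _check_simplex(alpha.data)
    D = ad.stack([ad.as_tensor(d) for d in d_list])   # (C, p)
    weighted = alpha @ D
    return ad.concat([s, weighted])


def channel_attention(s, d_list, params: ChannelAttentionParams):
    """Full channel-wise pass; returns (fused vector, alpha)."""
    energies = []
    for d in d_list:
        r = fusional_rate(s, d, params)
        energies.append(attention_energy(s, d, r, params))
    alpha = channel_scores(energies)
    return channel_fuse(s, d_list, alpha), alpha


# -- time-wise -------------------------------------------------------


def time_scores(h_seq, t: int, params: TimeAttentionParams) -> Tensor:
    """beta_t = softmax over i of the rate-blended energies between the
    query state h_t and every sequence state h_i (0-based t)."""
    T = len(h_seq)
    if not 0 <= t < T:
        raise IndexError(f"timestamp {t} out of range for T={T}")
    H = ad.stack([ad.as_tensor(h) for h in h_seq])    # (T, 2q)
    h_t = H[t]
    rate = ad.sigmoid(H @ params.w_ri + (params.w_rt @ h_t + params.b_rt))  # (T,)
    e = (1.0 - rate) * (params.w_et @ h_t) + rate * (H @ params.w_et) + params.b_et
    return ad.softmax(e)


def time_context(h_seq, beta) -> Tensor:
    """c_t = sum_i beta_{t,i} * h_i — the standard context vector."""
    beta = ad.as_tensor(beta) if not isinstance(beta, Tensor) else beta
    _check_simplex(beta.data)
    H = ad.stack([ad.as_tensor(h) for h in h_seq])
    return beta @ H


def time_context_literal(h_seq, t: int, beta) -> Tensor:
    """The degenerate printed form sum_i beta_{t,i} * h_t: because the
    weights sum to one this is identically h_t. Kept as a negative
    oracle; never used by the model."""
    beta = ad.as_tensor(beta) if not isinstance(beta, Tensor) else beta
    h_t = ad.as_tensor(h_seq[t])
    return beta.sum() * h_t
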