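"""Attentional representation, softmax classifier, and training cost.

The context vector c_t and hidden state h_t are concatenated and mapped
through a bounded nonlinearity to the attentional representation
h_hat_t = f(W_h [c_t (+) h_t] + b_h) with f = tanh by default; the
stage posterior is softmax(W_s h_hat_t + b_s). The cost is the two-term
(Bernoulli-style) cross-entropy applied to the softmax output,
J = -(1/M) sum_records (1/T) sum_t [y'log y_hat + (1-y)'log(1-y_hat)],
averaged per record and then across records, exactly in that order; a
standard categorical cross-entropy is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .stages import StageLabel

LOSS_EPS = 1e-7


@dataclass
class HeadParams:
    w_h: Tensor      # (r, 4q)
    b_h: Tensor      # (r,)
    w_s: Tensor      # (n_classes, r)
    b_s: Tensor      # (n_classes,)
    activation: str = "tanh"

    @classmethod
    def init(cls, q: int, r: int, n_classes: int, rng: np.random.Generator,
             activation: str = "tanh") -> "HeadParams":
        return cls(
            w_h=nn.glorot(rng, (r, 4 * q), 4 * q, r),
            b_h=Tensor(np.zeros(r), requires_grad=True),
            w_s=nn.glorot(rng, (n_classes, r), r, n_classes),
            b_s=Tensor(np.zeros(n_classes), requires_grad=True),
            activation=activation,
        )

    def parameters(self, prefix: str = "head") -> dict:
        return {f"{prefix}.W_h": self.w_h, f"{prefix}.b_h": self.b_h,
                f"{prefix}.W_s": self.w_s, f"{prefix}.b_s": self.b_s}


@dataclass
class Prediction:
    probs: np.ndarray
    label: StageLabel


def attentional_representation(c_t, h_t, params: HeadParams) -> Tensor:
    """h_hat = f(W_h [c (+) h] + b_h)."""
    c_t, h_t = ad.as_tensor(c_t), ad.as_tensor(h_t)
    z = ad.concat([c_t, h_t])
    if z.shape[0] != params.w_h.shape[1]:
        raise ValueError(f"head expects input {params.w_h.shape[1]}, got {z.shape[0]}")
    pre = params.w_h @ z + params.b_h
    if params.activation == "tanh":
        return ad.tanh(pre)
    if params.activation == "relu":
        return ad.relu(pre)
    raise ValueError(f"unknown activation {params.activation!r}")


def stage_logits(h_hat, params: HeadParams) -> Tensor:
    return params.w_s @ ad.as_tensor(h_hat) + params.b_s


def predict_stage(h_hat, params: HeadParams) -> Prediction:
    """Softmax posterior over the five stages; argmax label with
    lowest-index tie-break (numpy argmax convention)."""
    h_hat = ad.as_tensor(h_hat)
    if not np.all(np.isfinite(h_hat.data)):
        raise ValueError("non-finite input to predict_stage")
    probs = ad.softmax(stage_logits(h_hat, params)).data
    return Prediction(probs=probs, label=StageLabel(int(np.argmax(probs))))


def two_term_cross_entropy(probs: Tensor, y: np.ndarray) -> Tensor:
    """-[y'log p + (1-y)'log(1-p)] summed over classes, eps-clipped."""
    p = ad.clip(probs, LOSS_EPS, 1.0 - LOSS_EPS)
    y = np.asarray(y, dtype=float)
    return -(Tensor(y) * ad.log(p) + Tensor(1.0 - y) * ad.log(1.0 - p)).sum()


def categorical_cross_entropy(probs: Tensor, y: np.ndarray) -> Tensor:
    p = ad.clip(probs, LOSS_EPS, 1.0 - LOSS_EPS)
    return -(Tensor(np.asarray(y, dtype=float)) * ad.log(p)).sum()


def batch_loss(predictions, labels, grouping, mode: str = "two_term") -> Tensor:
    """J over a batch of records: mean over records of the per-record
    mean per-timestamp loss. `grouping` lists each record's length T_i
    (they must sum to the number of predictions); `labels` are one-hot
    rows. The default two-term form upper-bounds categorical CE."""
    n = len(predictions)
    labels = np.asarray(labels, dtype=float)
    if labels.shape[0] != n:
        raise ValueError("predictions and labels differ in length")
    if labels.ndim != 2 or not np.all(np.isin(labels, (0.0, 1.0))) \
            or not np.all(labels.sum(axis=1) == 1.0):
        raise ValueError("labels must be one-hot rows")
    if sum(grouping) != n:
        raise ValueError("grouping lengths must sum to the number of predictions")
    term = two_term_cross_entropy if mode == "two_term" else categorical_cross_entropy
    total = None
    idx = 0
    for t_len in grouping:
        if t_len <= 0:
            raise ValueError("record lengths must be positive")
        rec = None
        for _ in range(t_len):
            li = term(ad.as_tensor(predictions[idx]), labels[idx])
            rec = li if rec is None else rec + li
            idx += 1
        rec = rec / t_len
        total = rec if total is None else total + rec
    return total / len(grouping)
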