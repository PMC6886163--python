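"""End-to-end model: multi-view encoders, hybrid attention, classifier.

A window of T aligned epochs (T x C x L) flows through C channel
encoders and the global encoder (per epoch), channel-wise attention
fusing the views into x_tilde_t (length 2p), a 2-layer bidirectional
GRU producing h_t (length 2q), time-wise attention yielding beta_t and
the context c_t, and the tanh/softmax head predicting the stage
posterior at every timestamp. Dropout (training only) is applied to
the fused vectors before the recurrence and to the attentional
representation before the softmax layer.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import attention as att
from . import head as head_mod
from .autodiff import Tensor
from .encoder import EncoderParams, build_encoder, encode_channel, encode_global
from .nn import BGRU, apply_dropout
from .stages import N_STAGES


class HybridAttModel:
    """All learnable parameter sets (theta_c, theta_g, theta_r, both
    attention parameter sets, head weights) behind one object."""

    def __init__(self, montage_size: int, input_len: int, p: int = 128,
                 q: int = 128, r: int = 128, n_classes: int = N_STAGES,
                 channel_stages=None, global_stages=None, gru_layers: int = 2,
                 dropout: float = 0.5, seed: int = 0,
                 share_channels: bool = False, loss_mode: str = "two_term"):
        rng = np.random.default_rng(seed)
        self.encoder: EncoderParams = build_encoder(
            montage_size, input_len, p,
            channel_stages=channel_stages, global_stages=global_stages,
            rng=rng, share_channels=share_channels)
        self.att_c = att.ChannelAttentionParams.init(p, rng)
        self.bgru = BGRU(2 * p, q, gru_layers, rng)
        self.att_t = att.TimeAttentionParams.init(2 * q, rng)
        self.head = head_mod.HeadParams.init(q, r, n_classes, rng)
        self.p, self.q, self.r = p, q, r
        self.n_classes = n_classes
        self.dropout = dropout
        self.loss_mode = loss_mode
        self.montage_size = montage_size
        self.input_len = input_len

    # -- parameters --------------------------------------------------

    def parameters(self) -> dict:
        out = {}
        out.update(self.encoder.parameters())
        out.update(self.att_c.parameters())
        out.update(self.bgru.parameters("bgru"))
        out.update(self.att_t.parameters())
        out.update(self.head.parameters())
        return out

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k].data = np.array(v, dtype=np.float64)

    # -- forward -----------------------------------------------------

    def forward_window(self, X: np.ndarray, train: bool = False,
                       rng: np.random.Generator | None = None):
        """Run one window of epochs.

        Parameters
        ----------
        X : (T, C, L) array of aligned epoch matrices.

        Returns
        -------
        probs : (T, n_classes) Tensor of stage posteriors
        alpha : (T, C) channel weights (numpy)
        beta : (T, T) time weights, row t attending over the window (numpy)
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("expected a (T, C, L) window")
        T = X.shape[0]
        if T < 1:
            raise ValueError("empty window")
        fused, alphas = [], []
        for t in range(T):
            mat = X[t]
            d = [encode_channel(mat[c], enc)
                 for c, enc in enumerate(self.encoder.channel_encoders)]
            s = encode_global(mat, self.encoder.global_encoder)
            x_t, alpha_t = att.channel_attention(s, d, self.att_c)
            fused.append(apply_dropout(x_t, self.dropout, rng, train))
            alphas.append(alpha_t.data.copy())
        h_seq = self.bgru(fused)
        probs_rows, betas = [], []
        for t in range(T):
            beta_t = att.time_scores(h_seq, t, self.att_t)
            c_t = att.time_context(h_seq, beta_t)
            h_hat = head_mod.attentional_representation(c_t, h_seq[t], self.head)
            h_hat = apply_dropout(h_hat, self.dropout, rng, train)
            probs_rows.append(ad.softmax(head_mod.stage_logits(h_hat, self.head)))
            betas.append(beta_t.data.copy())
        return ad.stack(probs_rows), np.stack(alphas), np.stack(betas)

    def batch_forward_loss(self, windows, labels_list, train: bool = True,
                           rng: np.random.Generator | None = None):
        """Loss over a batch of windows, each treated as one record unit
        in the per-record-then-batch averaging of the cost."""
        preds, labels, grouping = [], [], []
        for X, y in zip(windows, labels_list):
            probs, _, _ = self.forward_window(X, train=train, rng=rng)
            for t in range(probs.shape[0]):
                preds.append(probs[t])
            labels.append(np.eye(self.n_classes)[np.asarray(y, dtype=int)])
            grouping.append(len(y))
        return head_mod.batch_loss(preds, np.concatenate(labels), grouping,
                                   mode=self.loss_mode)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior probabilities for one window, dropout disabled."""
        probs, _, _ = self.forward_window(X, train=False)
        return probs.data

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)
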