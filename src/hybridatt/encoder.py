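"""Multi-view convolutional representation module.

Each channel owns an independent 1-D encoder (parallel multi-scale
kernels, max pooling) producing a channel-view vector d_c of length p;
a single 2-D encoder over the aligned channel matrix (average pooling,
final pool collapsing the channel axis) produces the global-view vector
s of the same length. Multi-scale stage-1 kernels (8/16/32/64 samples)
capture waveform patterns at different frequency modes; max pooling
keeps the most salient per-channel features while average pooling keeps
the general picture across channels.

The printed configuration leaves stage-1 paddings for the 32- and
64-sample kernels that would make the parallel branches emit unequal
lengths; they are overridden to (K-2)/2 so all branches concatenate
(the only reading under which the stage composes). The stack ends at a
pooled 32-map tensor; a learned linear projection with ReLU maps the
flattened features to the target dimension p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor, conv_out_len
from .preprocessing import AlignedEpoch


@dataclass(frozen=True)
class ConvBranchSpec:
    """One parallel convolution branch; kernel/stride/padding are ints
    for 1-D stages and (height, width) pairs for 2-D stages."""

    kernel: object
    filters: int
    stride: object
    padding: object


@dataclass(frozen=True)
class PoolSpec:
    size: object
    stride: object
    padding: object
    mode: str  # "max" or "avg"


@dataclass(frozen=True)
class ConvStageSpec:
    branches: tuple
    pool: PoolSpec


def default_channel_stages() -> tuple:
    """1-D channel-encoder configuration (multi-scale stage 1)."""
    return (
        ConvStageSpec(
            branches=(
                ConvBranchSpec(8, 8, 2, 3),
                ConvBranchSpec(16, 8, 2, 7),
                ConvBranchSpec(32, 8, 2, 15),   # printed 3; equal-length override
                ConvBranchSpec(64, 8, 2, 31),   # printed 7; equal-length override
            ),
            pool=PoolSpec(6, 4, 1, "max"),
        ),
        ConvStageSpec(
            branches=(ConvBranchSpec(3, 16, 1, 1), ConvBranchSpec(5, 16, 1, 2)),
            pool=PoolSpec(3, 2, 1, "max"),
        ),
        ConvStageSpec(
            branches=(ConvBranchSpec(3, 16, 1, 1), ConvBranchSpec(5, 16, 1, 2)),
            pool=PoolSpec(3, 2, 1, "max"),
        ),
    )


def default_global_stages(montage_size: int = 14) -> tuple:
    """2-D global-encoder configuration; the last pool's height equals
    the montage size, collapsing the channel axis to 1."""
    return (
        ConvStageSpec(
            branches=(
                ConvBranchSpec((1, 8), 8, (1, 2), (0, 3)),
                ConvBranchSpec((1, 16), 8, (1, 2), (0, 7)),
                ConvBranchSpec((1, 32), 8, (1, 2), (0, 15)),
                ConvBranchSpec((1, 64), 8, (1, 2), (0, 31)),
            ),
            pool=PoolSpec((1, 6), (1, 4), (0, 1), "avg"),
        ),
        ConvStageSpec(
            branches=(ConvBranchSpec((3, 3), 16, (1, 1), (1, 1)),
                      ConvBranchSpec((5, 5), 16, (1, 1), (2, 2))),
            pool=PoolSpec((1, 3), (1, 2), (0, 1), "avg"),
        ),
        ConvStageSpec(
            branches=(ConvBranchSpec((3, 3), 16, (1, 1), (1, 1)),
                      ConvBranchSpec((5, 5), 16, (1, 1), (2, 2))),
            pool=PoolSpec((montage_size, 3), (montage_size, 2), (0, 1), "avg"),
        ),
    )


def toy_channel_stages() -> tuple:
    """Reduced two-stage configuration for fast CPU experiments."""
    return (
        ConvStageSpec(
            branches=(ConvBranchSpec(8, 4, 2, 3), ConvBranchSpec(16, 4, 2, 7)),
            pool=PoolSpec(4, 4, 0, "max"),
        ),
        ConvStageSpec(
            branches=(ConvBranchSpec(3, 8, 1, 1),),
            pool=PoolSpec(2, 2, 0, "max"),
        ),
    )


def toy_global_stages(montage_size: int = 2) -> tuple:
    return (
        ConvStageSpec(
            branches=(ConvBranchSpec((1, 8), 4, (1, 2), (0, 3)),
                      ConvBranchSpec((1, 16), 4, (1, 2), (0, 7))),
            pool=PoolSpec((1, 4), (1, 4), (0, 0), "avg"),
        ),
        ConvStageSpec(
            branches=(ConvBranchSpec((1, 3), 8, (1, 1), (0, 1)),),
            pool=PoolSpec((montage_size, 2), (montage_size, 2), (0, 0), "avg"),
        ),
    )


class ChannelEncoder:
    """1-D multi-branch CNN for one channel (max pooling between stages)."""

    def __init__(self, input_len: int, p: int, stages: tuple,
                 rng: np.random.Generator):
        self.stages = stages
        self.input_len = input_len
        self.weights = []   # per stage: list of (w, b)
        c_in, length = 1, input_len
        for si, stage in enumerate(stages):
            lens = set()
            ws = []
            for br in stage.branches:
                k, f, s, pad = br.kernel, br.filters, br.stride, br.padding
                w = nn.glorot(rng, (f, c_in, k), c_in * k, f * k)
                b = Tensor(np.zeros(f), requires_grad=True)
                ws.append((w, b, br))
                lens.add(conv_out_len(length, k, s, pad))
            if len(lens) != 1:
                raise ValueError(f"stage {si}: parallel branches emit unequal lengths {lens}")
            length = lens.pop()
            if length <= 0:
                raise ValueError(f"stage {si}: output length reached {length}")
            self.weights.append(ws)
            pl = stage.pool
            length = conv_out_len(length, pl.size, pl.stride, pl.padding)
            if length <= 0:
                raise ValueError(f"stage {si}: pooled length reached {length}")
            c_in = sum(br.filters for br in stage.branches)
        self.flat_dim = c_in * length
        self.proj = nn.Linear(self.flat_dim, p, rng)
        self.out_len = length

    def __call__(self, x: Tensor) -> Tensor:
        h = x.reshape(1, -1)
        for ws, stage in zip(self.weights, self.stages):
            outs = [ad.conv1d(h, w, b, br.stride, br.padding) for (w, b, br) in ws]
            h = ad.relu(ad.concat(outs, axis=0))
            pl = stage.pool
            pool = ad.maxpool1d if pl.mode == "max" else ad.avgpool1d
            h = pool(h, pl.size, pl.stride, pl.padding)
        return ad.relu(self.proj(h.reshape(-1)))

    def parameters(self, prefix: str) -> dict:
        out = {}
        for si, ws in enumerate(self.weights):
            for bi, (w, b, _) in enumerate(ws):
                out[f"{prefix}.s{si}.b{bi}.w"] = w
                out[f"{prefix}.s{si}.b{bi}.b"] = b
        out.update(self.proj.parameters(f"{prefix}.proj"))
        return out


class GlobalEncoder:
    """2-D CNN over the aligned channel matrix (average pooling)."""

    def __init__(self, montage_size: int, input_len: int, p: int, stages: tuple,
                 rng: np.random.Generator):
        self.stages = stages
        self.weights = []
        c_in, h, w_len = 1, montage_size, input_len
        for si, stage in enumerate(stages):
            shapes = set()
            ws = []
            for br in stage.branches:
                (kh, kw), f = br.kernel, br.filters
                (sh, sw), (ph, pw) = br.stride, br.padding
                wt = nn.glorot(rng, (f, c_in, kh, kw), c_in * kh * kw, f * kh * kw)
                bt = Tensor(np.zeros(f), requires_grad=True)
                ws.append((wt, bt, br))
                shapes.add((conv_out_len(h, kh, sh, ph), conv_out_len(w_len, kw, sw, pw)))
            if len(shapes) != 1:
                raise ValueError(f"stage {si}: parallel branches emit unequal shapes {shapes}")
            h, w_len = shapes.pop()
            if h <= 0 or w_len <= 0:
                raise ValueError(f"stage {si}: output shape reached {(h, w_len)}")
            self.weights.append(ws)
            pl = stage.pool
            h = conv_out_len(h, pl.size[0], pl.stride[0], pl.padding[0])
            w_len = conv_out_len(w_len, pl.size[1], pl.stride[1], pl.padding[1])
            if h <= 0 or w_len <= 0:
                raise ValueError(f"stage {si}: pooled shape reached {(h, w_len)}")
            c_in = sum(br.filters for br in stage.branches)
        self.flat_dim = c_in * h * w_len
        self.proj = nn.Linear(self.flat_dim, p, rng)
        self.out_shape = (h, w_len)

    def __call__(self, x: Tensor) -> Tensor:
        hmap = x.reshape(1, *x.shape)
        for ws, stage in zip(self.weights, self.stages):
            outs = [ad.conv2d(hmap, w, b, br.stride, br.padding) for (w, b, br) in ws]
            hmap = ad.relu(ad.concat(outs, axis=0))
            pl = stage.pool
            hmap = ad.avgpool2d(hmap, pl.size, pl.stride, pl.padding)
        return ad.relu(self.proj(hmap.reshape(-1)))

    def parameters(self, prefix: str) -> dict:
        out = {}
        for si, ws in enumerate(self.weights):
            for bi, (w, b, _) in enumerate(ws):
                out[f"{prefix}.s{si}.b{bi}.w"] = w
                out[f"{prefix}.s{si}.b{bi}.b"] = b
        out.update(self.proj.parameters(f"{prefix}.proj"))
        return out


@dataclass
class MultiViewFeatures:
    """C channel-view vectors d_c and one global-view vector s, length p each."""

    d: list
    s: Tensor
    t_index: int


@dataclass
class EncoderParams:
    channel_encoders: list
    global_encoder: GlobalEncoder
    p: int
    input_len: int
    montage_size: int
    shared: bool = False

    def parameters(self) -> dict:
        out = {}
        if self.shared:
            out.update(self.channel_encoders[0].parameters("cnn_c.shared"))
        else:
            for c, enc in enumerate(self.channel_encoders):
                out.update(enc.parameters(f"cnn_c.{c}"))
        out.update(self.global_encoder.parameters("cnn_g"))
        return out


def build_encoder(montage_size: int, input_len: int, p: int = 128,
                  channel_stages: tuple | None = None,
                  global_stages: tuple | None = None,
                  rng: np.random.Generator | None = None,
                  seed: int = 0,
                  share_channels: bool = False) -> EncoderParams:
    """Instantiate C independent channel encoders plus one global encoder,
    all projecting to dimension p; Glorot-initialised from a single seed.
    Stage output lengths are validated for input_len at build time."""
    rng = rng or np.random.default_rng(seed)
    channel_stages = channel_stages or default_channel_stages()
    global_stages = global_stages or default_global_stages(montage_size)
    if share_channels:
        shared = ChannelEncoder(input_len, p, channel_stages, rng)
        chans = [shared] * montage_size
    else:
        chans = [ChannelEncoder(input_len, p, channel_stages, rng)
                 for _ in range(montage_size)]
    glob = GlobalEncoder(montage_size, input_len, p, global_stages, rng)
    return EncoderParams(channel_encoders=chans, global_encoder=glob, p=p,
                         input_len=input_len, montage_size=montage_size,
                         shared=share_channels)


def encode_channel(x, params: ChannelEncoder) -> Tensor:
    """Channel-view feature d = CNN_c(x; theta_c), length p."""
    x = ad.as_tensor(x)
    if x.shape[-1] != params.input_len:
        raise ValueError(f"input length {x.shape[-1]} does not match encoder")
    return params(x)


def encode_global(X, params: GlobalEncoder) -> Tensor:
    """Global-view feature s = CNN_g(X; theta_g), length p."""
    X = ad.as_tensor(X)
    return params(X)


def encode_epoch(epoch: AlignedEpoch, params: EncoderParams) -> MultiViewFeatures:
    """Apply every channel encoder and the global encoder to one epoch."""
    mat = np.asarray(epoch.matrix, dtype=float)
    if mat.shape[0] != params.montage_size:
        raise ValueError(f"epoch has {mat.shape[0]} channels, encoder expects "
                         f"{params.montage_size}")
    if mat.shape[1] != params.input_len:
        raise ValueError(f"epoch length {mat.shape[1]} != encoder input_len "
                         f"{params.input_len}")
    d = [encode_channel(mat[c], enc)
         for c, enc in enumerate(params.channel_encoders)]
    s = encode_global(mat, params.global_encoder)
    return MultiViewFeatures(d=d, s=s, t_index=epoch.t_index)
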