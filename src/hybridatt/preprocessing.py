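"""Epoch segmentation, channel alignment, and STFT feature extraction.

A record is cut into labeled 30-s epochs; heterogeneous channels are
brought to a common length by linear interpolation (upsampling to the
fastest channel, so nothing is discarded); optionally each aligned
channel is mapped to a magnitude spectrogram by a non-overlapping
short-time Fourier transform. With the default montage (14 channels,
fastest rate 128 Hz) an epoch carries 14 x 3840 = 53,760 values in the
time domain and 14 x 65 x 30 = 27,300 in the frequency domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .stages import StageLabel
from .synthetic import EPOCH_SECONDS, PSGRecord

TIME_DOMAIN = "time"
FREQ_DOMAIN = "frequency"


@dataclass
class Epoch:
    """One 30-s slot at native per-channel rates."""

    channels: list           # per channel c, 1-D array of length rate_c * 30
    label: StageLabel
    t_index: int             # 0-based position within the record


@dataclass
class AlignedEpoch:
    """Common-length C x L matrix form of an epoch."""

    matrix: np.ndarray
    label: StageLabel
    t_index: int
    domain_tag: str = TIME_DOMAIN


@dataclass
class EpochSequence:
    """Ordered aligned epochs of one record."""

    epochs: list
    subject_id: str

    @property
    def labels(self) -> np.ndarray:
        return np.array([int(e.label) for e in self.epochs], dtype=np.int64)

    def matrices(self) -> np.ndarray:
        return np.stack([e.matrix for e in self.epochs])


@dataclass
class StftConfig:
    """Non-overlapping one-sided spectrogram; window/hop of 128 on a
    3840-sample epoch gives 65 bins x 30 frames per channel."""

    window: int = 128
    hop: int = 128
    onesided: bool = True
    log_magnitude: bool = False


def segment_epochs(record: PSGRecord) -> list:
    """One Epoch per hypnogram entry; trailing partial slots are dropped."""
    record.validate()
    epochs = []
    for t, stage in enumerate(record.hypnogram):
        chans = []
        for spec in record.montage:
            n = spec.samples_per_epoch
            sl = record.signals[spec.name][t * n:(t + 1) * n]
            if len(sl) < n:
                raise ValueError(f"channel {spec.name}: signal shorter than hypnogram implies")
            chans.append(np.asarray(sl, dtype=float))
        epochs.append(Epoch(channels=chans, label=StageLabel(int(stage)), t_index=t))
    return epochs


def align_epoch(epoch: Epoch, target_len: int) -> AlignedEpoch:
    """Linearly interpolate every channel onto target_len points over the
    same 30-s span. Sample k of an n-sample channel sits at time
    k/n * 30 s, so a channel at exactly half the target rate is
    reproduced verbatim at the even output indices, and a channel
    already at target_len passes through unchanged."""
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    rows = []
    for x in epoch.channels:
        x = np.asarray(x, dtype=float)
        n = len(x)
        if n == 0:
            raise ValueError("empty channel vector")
        if n == target_len:
            rows.append(x)
            continue
        old_t = np.arange(n) * (EPOCH_SECONDS / n)
        new_t = np.arange(target_len) * (EPOCH_SECONDS / target_len)
        rows.append(np.interp(new_t, old_t, x))
    return AlignedEpoch(matrix=np.stack(rows), label=epoch.label,
                        t_index=epoch.t_index, domain_tag=TIME_DOMAIN)


def common_length(montage) -> int:
    """Alignment target: the highest channel rate x 30 s."""
    return max(c.samples_per_epoch for c in montage)


def stft_features(aligned: AlignedEpoch, cfg: StftConfig | None = None) -> AlignedEpoch:
    """Magnitude spectrogram per aligned channel, flattened row-major
    (frequency bins x frames) into that channel's feature vector."""
    cfg = cfg or StftConfig()
    if aligned.domain_tag != TIME_DOMAIN:
        raise ValueError("stft_features expects a time-domain epoch")
    L = aligned.matrix.shape[1]
    if L < cfg.window:
        raise ValueError("epoch shorter than one STFT window")
    noverlap = cfg.window - cfg.hop
    rows = []
    for x in aligned.matrix:
        _, _, z = sps.stft(x, window="hann", nperseg=cfg.window,
                           noverlap=noverlap, boundary=None, padded=False,
                           return_onesided=cfg.onesided)
        mag = np.abs(z)
        if cfg.log_magnitude:
            mag = np.log1p(mag)
        rows.append(mag.ravel(order="C"))
    return AlignedEpoch(matrix=np.stack(rows), label=aligned.label,
                        t_index=aligned.t_index, domain_tag=FREQ_DOMAIN)


def stft_shape(length: int, cfg: StftConfig | None = None) -> tuple:
    """(bins, frames) the STFT pathway produces for an aligned length."""
    cfg = cfg or StftConfig()
    bins = cfg.window // 2 + 1 if cfg.onesided else cfg.window
    frames = (length - cfg.window) // cfg.hop + 1
    return bins, frames


def zscore_sequence(matrices: np.ndarray) -> np.ndarray:
    """Per-record, per-channel standardisation across all epochs."""
    mats = np.asarray(matrices, dtype=float)
    mean = mats.mean(axis=(0, 2), keepdims=True)
    sd = mats.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return (mats - mean) / sd


def prepare_sequence(record: PSGRecord, domain: str = TIME_DOMAIN,
                     stft_cfg: StftConfig | None = None,
                     normalize: bool = True,
                     target_len: int | None = None) -> EpochSequence:
    """Full preprocessing of one record: segment, align, optionally STFT,
    optionally per-channel z-score across the record."""
    if domain not in (TIME_DOMAIN, FREQ_DOMAIN):
        raise ValueError(f"unknown domain {domain!r}")
    L = target_len or common_length(record.montage)
    aligned = [align_epoch(e, L) for e in segment_epochs(record)]
    if domain == FREQ_DOMAIN:
        aligned = [stft_features(a, stft_cfg) for a in aligned]
    if normalize and aligned:
        mats = zscore_sequence(np.stack([a.matrix for a in aligned]))
        for a, m in zip(aligned, mats):
            a.matrix = m
    return EpochSequence(epochs=aligned, subject_id=record.subject_id)
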