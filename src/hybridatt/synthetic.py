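"""Synthetic multivariate polysomnography cohorts.

Generates pseudo-PSG records with the heterogeneity the classifier
assumes: a montage of channels at mixed sample rates, a Markov-chain
hypnogram of 30-s stage labels, and per-channel signals whose spectral
band powers depend on the current stage (delta-dominant slow-wave
sleep, alpha-dominant wake, and so on). Each 30-s slot of a channel is
a sum of band-limited sinusoids whose log-amplitudes are drawn around a
configurable per-(stage, channel-kind) mean, plus white Gaussian noise.

These records exercise every downstream component without any external
dataset; they make no claim of physiological fidelity (no apneas,
arousals, artifacts, or scorer noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stages import BANDS, STAGES, StageLabel

EPOCH_SECONDS = 30

CHANNEL_KINDS = ("eeg", "emg", "ecg", "eog", "other")


@dataclass(frozen=True)
class ChannelSpec:
    """One montage channel: a label, its sample rate (Hz), and a kind."""

    name: str
    rate: int
    kind: str = "other"

    def __post_init__(self):
        if self.rate <= 0 or int(self.rate) != self.rate:
            raise ValueError(f"channel {self.name!r}: rate must be a positive integer")
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"channel {self.name!r}: unknown kind {self.kind!r}")

    @property
    def samples_per_epoch(self) -> int:
        return self.rate * EPOCH_SECONDS


def default_montage() -> tuple:
    """14-channel mixed-rate montage: 6 EEG and 1 ECG at 128 Hz, 2 EOG at
    128 Hz, 1 EMG at 64 Hz, 4 auxiliary channels at 64 Hz.

    This is a stand-in with the stated rate heterogeneity (128 Hz EEG,
    64 Hz EMG, 14 channels total), not a claim about any real montage.
    """
    chans = [ChannelSpec(f"EEG{i+1}", 128, "eeg") for i in range(6)]
    chans += [ChannelSpec("EOGL", 128, "eog"), ChannelSpec("EOGR", 128, "eog")]
    chans += [ChannelSpec("EMG", 64, "emg"), ChannelSpec("ECG", 128, "ecg")]
    chans += [ChannelSpec(f"AUX{i+1}", 64, "other") for i in range(4)]
    return tuple(chans)


def default_transition() -> np.ndarray:
    """Row-stochastic stage-transition matrix (rows/cols in StageLabel order).

    Sticky diagonal with plausible moves: wake mostly persists or enters
    light sleep; S1 feeds S2; S2 deepens to S3 or surfaces to REM; REM
    returns to S2 or wakes.
    """
    #        WAKE   REM    S1     S2     S3
    p = np.array([
        [0.70, 0.02, 0.24, 0.03, 0.01],   # WAKE
        [0.08, 0.75, 0.05, 0.11, 0.01],   # REM
        [0.08, 0.05, 0.55, 0.30, 0.02],   # S1
        [0.03, 0.08, 0.05, 0.66, 0.18],   # S2
        [0.02, 0.02, 0.02, 0.24, 0.70],   # S3
    ])
    return p


def default_band_power_map() -> dict:
    """Mean log-amplitudes per (stage, channel kind) over the four bands
    (delta, theta, alpha, beta). Values follow textbook sleep physiology:
    alpha/beta-dominant wake, theta-dominant S1/REM, delta-dominant S3,
    EMG tone high in wake and suppressed in REM. Config defaults only."""
    lo, md, hi = -1.5, 0.0, 1.0
    eeg = {
        StageLabel.WAKE: [lo, lo, hi, md],
        StageLabel.REM: [lo, hi, lo, md],
        StageLabel.S1: [md, hi, md, lo],
        StageLabel.S2: [md, md, lo, hi],
        StageLabel.S3: [hi, md, lo, lo],
    }
    emg = {
        StageLabel.WAKE: [md, md, hi, hi],
        StageLabel.REM: [lo, lo, lo, lo],
        StageLabel.S1: [md, md, md, md],
        StageLabel.S2: [lo, md, md, lo],
        StageLabel.S3: [lo, lo, md, lo],
    }
    flat = {s: [md, md, md, md] for s in STAGES}
    table = {"eeg": eeg, "eog": eeg, "emg": emg, "ecg": flat, "other": flat}
    return {(stage, kind): np.asarray(table[kind][stage], dtype=float)
            for kind in CHANNEL_KINDS for stage in STAGES}


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 25
    montage: tuple = field(default_factory=default_montage)
    epochs_per_subject: int = 20
    stage_transition: np.ndarray = field(default_factory=default_transition)
    band_power_map: dict = field(default_factory=default_band_power_map)
    noise_sd: float = 0.5
    amp_jitter: float = 0.3
    components_per_band: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.montage:
            raise ValueError("montage must be non-empty")
        names = [c.name for c in self.montage]
        if len(set(names)) != len(names):
            raise ValueError("montage channel names must be unique")
        p = np.asarray(self.stage_transition, dtype=float)
        if p.shape != (len(STAGES), len(STAGES)):
            raise ValueError("stage_transition must be 5x5")
        if np.any(p < 0) or np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("stage_transition rows must be nonnegative and sum to 1")
        if self.epochs_per_subject < 1:
            raise ValueError("epochs_per_subject must be >= 1")


@dataclass
class PSGRecord:
    """One subject's multi-channel recording plus its hypnogram."""

    subject_id: str
    montage: tuple
    signals: dict            # channel name -> 1-D float array at native rate
    hypnogram: np.ndarray    # StageLabel value per 30-s slot

    def validate(self) -> None:
        if len(self.hypnogram) == 0:
            raise ValueError("hypnogram must be non-empty")
        for ch in self.montage:
            n = len(self.signals[ch.name])
            need = ch.samples_per_epoch * len(self.hypnogram)
            if n < need:
                raise ValueError(
                    f"channel {ch.name}: {n} samples < {need} implied by hypnogram")


def stationary_distribution(p: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(p.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    # SeedSequence hashing keeps per-subject streams order-independent
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def _simulate_hypnogram(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    pi = stationary_distribution(p)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(len(STAGES), p=pi)
    for t in range(1, n):
        states[t] = rng.choice(len(STAGES), p=p[states[t - 1]])
    return states


def _slot_signal(rng: np.random.Generator, spec: ChannelSpec, stage: StageLabel,
                 cfg: CohortConfig) -> np.ndarray:
    n = spec.samples_per_epoch
    t = np.arange(n) / spec.rate
    x = np.zeros(n)
    log_amps = cfg.band_power_map[(StageLabel(stage), spec.kind)]
    nyquist = spec.rate / 2.0
    for (name, lo, hi), mean_log in zip(BANDS, log_amps):
        if lo >= nyquist:
            continue  # band unrepresentable at this rate
        hi_eff = min(hi, 0.95 * nyquist)
        for _ in range(cfg.components_per_band):
            f = rng.uniform(lo, hi_eff)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amp = np.exp(mean_log + cfg.amp_jitter * rng.standard_normal())
            x += (amp / cfg.components_per_band) * np.sin(2.0 * np.pi * f * t + phase)
    if cfg.noise_sd > 0:
        x += cfg.noise_sd * rng.standard_normal(n)
    return x


def generate_record(config: CohortConfig, subject_index: int) -> PSGRecord:
    """Deterministically generate one subject's record.

    The stream depends only on (config.seed, subject_index), so cohorts
    are order-independent and records individually reproducible.
    """
    config.validate()
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")
    rng = _subject_rng(config.seed, subject_index)
    p = np.asarray(config.stage_transition, dtype=float)
    hyp = _simulate_hypnogram(rng, p, config.epochs_per_subject)
    signals = {}
    for spec in config.montage:
        slots = [_slot_signal(rng, spec, StageLabel(s), config) for s in hyp]
        signals[spec.name] = np.concatenate(slots)
    rec = PSGRecord(subject_id=f"S{subject_index:03d}", montage=config.montage,
                    signals=signals, hypnogram=hyp)
    rec.validate()
    return rec


def generate_cohort(config: CohortConfig) -> list:
    """All n_subjects records, with distinct subject ids."""
    config.validate()
    return [generate_record(config, i) for i in range(config.n_subjects)]


# -- toy study conditions --------------------------------------------


def toy_montage() -> tuple:
    return (ChannelSpec("EEG1", 32, "eeg"), ChannelSpec("EMG", 16, "emg"))


def toy_band_power_map() -> dict:
    """Well-separated two-channel map: each stage owns a distinct
    (EEG band, EMG tone) signature below both channels' Nyquist rates,
    so epochs are separable by band power alone and learning tests have
    an achievable target."""
    lo, hi = -2.0, 1.5
    eeg = {
        StageLabel.WAKE: [lo, lo, hi, lo],
        StageLabel.REM: [lo, hi, lo, lo],
        StageLabel.S1: [lo, hi, lo, lo],
        StageLabel.S2: [lo, lo, lo, hi],
        StageLabel.S3: [hi, lo, lo, lo],
    }
    emg = {
        StageLabel.WAKE: [lo, hi, lo, lo],
        StageLabel.REM: [lo, lo, lo, lo],
        StageLabel.S1: [hi, lo, lo, lo],
        StageLabel.S2: [lo, lo, lo, lo],
        StageLabel.S3: [lo, lo, lo, lo],
    }
    table = {"eeg": eeg, "eog": eeg, "emg": emg,
             "ecg": {s: [0.0] * 4 for s in STAGES},
             "other": {s: [0.0] * 4 for s in STAGES}}
    return {(stage, kind): np.asarray(table[kind][stage], dtype=float)
            for kind in CHANNEL_KINDS for stage in STAGES}


def toy_config(n_subjects: int = 2, epochs_per_subject: int = 40,
               seed: int = 0) -> CohortConfig:
    """Two-channel, well-separated cohort used by the learning tests."""
    trans = np.full((5, 5), 0.1) + np.eye(5) * 0.5
    return CohortConfig(
        n_subjects=n_subjects,
        montage=toy_montage(),
        epochs_per_subject=epochs_per_subject,
        stage_transition=trans,
        band_power_map=toy_band_power_map(),
        noise_sd=0.1,
        amp_jitter=0.2,
        seed=seed,
    )


# -- container I/O ---------------------------------------------------


def save_record(record: PSGRecord, path) -> None:
    """One NPZ archive per record: per-channel vectors, rates, kinds,
    and the hypnogram."""
    path = Path(path)
    arrays = {
        "subject_id": np.array(record.subject_id),
        "names": np.array([c.name for c in record.montage]),
        "rates": np.array([c.rate for c in record.montage]),
        "kinds": np.array([c.kind for c in record.montage]),
        "hypnogram": np.asarray(record.hypnogram, dtype=np.int64),
    }
    for i, ch in enumerate(record.montage):
        arrays[f"signal_{i}"] = record.signals[ch.name]
    np.savez(path, **arrays)


def load_record(path) -> PSGRecord:
    with np.load(Path(path), allow_pickle=False) as z:
        names = [str(n) for n in z["names"]]
        rates = [int(r) for r in z["rates"]]
        kinds = [str(k) for k in z["kinds"]]
        montage = tuple(ChannelSpec(n, r, k) for n, r, k in zip(names, rates, kinds))
        signals = {n: z[f"signal_{i}"] for i, n in enumerate(names)}
        rec = PSGRecord(subject_id=str(z["subject_id"]), montage=montage,
                        signals=signals, hypnogram=z["hypnogram"])
    rec.validate()
    return rec


def save_cohort(records: list, out_dir) -> list:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        p = out_dir / f"{rec.subject_id}.npz"
        save_record(rec, p)
        paths.append(p)
    return paths


def load_cohort(in_dir) -> list:
    return [load_record(p) for p in sorted(Path(in_dir).glob("*.npz"))]
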