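"""Run configuration: YAML schema, validation, and defaults.

A run is fully described by one mapping with sections `cohort`,
`preprocessing`, `model`, and `train` plus a master `seed`; every key
has a default reproducing the reference dimensions (p = q = r = 128,
five stages, 14 channels). Unknown keys and inconsistent dimensions
are rejected by name at load time. The master seed deterministically
fans out to simulation, initialisation, shuffling, and dropout streams
so stages can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .encoder import (default_channel_stages, default_global_stages,
                      toy_channel_stages, toy_global_stages)
from .preprocessing import FREQ_DOMAIN, TIME_DOMAIN, StftConfig
from .synthetic import CohortConfig, toy_config
from .training import TrainConfig

_COHORT_KEYS = {"preset", "n_subjects", "epochs_per_subject", "noise_sd",
                "amp_jitter", "seed"}
_PRE_KEYS = {"domain", "normalize", "stft_window", "stft_hop", "stft_onesided",
             "log_magnitude", "target_len"}
_MODEL_KEYS = {"preset", "p", "q", "r", "n_classes", "gru_layers",
               "share_channels", "loss_mode"}
_TRAIN_KEYS = {"rho", "eps", "l2_coeff", "dropout", "epochs", "batch",
               "window", "patience"}
_TOP_KEYS = {"cohort", "preprocessing", "model", "train", "seed"}


@dataclass
class RunConfig:
    cohort: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    seed: int = 0

    # -- resolved objects -------------------------------------------

    def cohort_config(self) -> CohortConfig:
        c = dict(self.cohort)
        preset = c.pop("preset", "default")
        seed = c.pop("seed", self.seed)
        if preset == "toy":
            cfg = toy_config(seed=seed)
        elif preset == "default":
            cfg = CohortConfig(seed=seed)
        else:
            raise ValueError(f"unknown cohort preset {preset!r}")
        for k, v in c.items():
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    @property
    def domain(self) -> str:
        return self.preprocessing.get("domain", TIME_DOMAIN)

    def stft_config(self) -> StftConfig:
        p = self.preprocessing
        return StftConfig(window=p.get("stft_window", 128),
                          hop=p.get("stft_hop", 128),
                          onesided=p.get("stft_onesided", True),
                          log_magnitude=p.get("log_magnitude", False))

    def model_kwargs(self, montage_size: int, input_len: int) -> dict:
        m = dict(self.model)
        preset = m.pop("preset", "default")
        if preset == "toy":
            chan, glob = toy_channel_stages(), toy_global_stages(montage_size)
            dims = {"p": 16, "q": 16, "r": 16}
        elif preset == "default":
            chan, glob = default_channel_stages(), default_global_stages(montage_size)
            dims = {"p": 128, "q": 128, "r": 128}
        else:
            raise ValueError(f"unknown model preset {preset!r}")
        dims.update(m)
        return dict(montage_size=montage_size, input_len=input_len,
                    channel_stages=chan, global_stages=glob,
                    dropout=self.train_config().dropout, seed=self.seed,
                    **dims)

    def train_config(self) -> TrainConfig:
        cfg = TrainConfig(seed=self.seed, **self.train)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, keys, got in (("cohort", _COHORT_KEYS, self.cohort),
                                ("preprocessing", _PRE_KEYS, self.preprocessing),
                                ("model", _MODEL_KEYS, self.model),
                                ("train", _TRAIN_KEYS, self.train)):
            unknown = set(got) - keys
            if unknown:
                raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
        if self.domain not in (TIME_DOMAIN, FREQ_DOMAIN):
            raise ValueError(f"preprocessing.domain must be "
                             f"'{TIME_DOMAIN}' or '{FREQ_DOMAIN}'")
        for dim in ("p", "q", "r"):
            if dim in self.model and self.model[dim] < 1:
                raise ValueError(f"model.{dim} must be >= 1")
        self.cohort_config()
        self.train_config()

    # -- serialisation ----------------------------------------------

    def resolved(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=True))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run config; an empty file yields the
    all-defaults configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    cfg = RunConfig(cohort=raw.get("cohort", {}) or {},
                    preprocessing=raw.get("preprocessing", {}) or {},
                    model=raw.get("model", {}) or {},
                    train=raw.get("train", {}) or {},
                    seed=int(raw.get("seed", 0)))
    cfg.validate()
    return cfg
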