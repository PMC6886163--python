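"""Sleep-stage vocabulary and spectral band definitions."""

from __future__ import annotations

from enum import IntEnum

import numpy as np


class StageLabel(IntEnum):
    """Five-class staging with slow-wave sleep (S3+S4) merged into S3."""

    WAKE = 0
    REM = 1
    S1 = 2
    S2 = 3
    S3 = 4


STAGES = tuple(StageLabel)
N_STAGES = len(STAGES)

# (name, low Hz, high Hz) — conventional EEG bands
BANDS = (
    ("delta", 0.5, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
)
N_BANDS = len(BANDS)


def one_hot(labels, n_classes: int = N_STAGES) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels] = 1.0
    return out.reshape(labels.shape + (n_classes,)) if labels.ndim else out[0]
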