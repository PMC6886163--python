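import numpy as np
import pytest

from hybridatt import generate_cohort, prepare_sequence, toy_config
from hybridatt.encoder import toy_channel_stages, toy_global_stages
from hybridatt.model import HybridAttModel

TOY_LEN = 960  # toy montage: 32 Hz EEG + 16 Hz EMG aligned to 32*30


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two subjects x 12 epochs of the well-separated toy conditions."""
    cfg = toy_config(n_subjects=2, epochs_per_subject=12, seed=7)
    recs = generate_cohort(cfg)
    return {r.subject_id: prepare_sequence(r) for r in recs}


@pytest.fixture()
def toy_model():
    def make(seed=0, dropout=0.5, **kw):
        return HybridAttModel(
            2, TOY_LEN, p=16, q=16, r=16,
            channel_stages=toy_channel_stages(),
            global_stages=toy_global_stages(2),
            dropout=dropout, seed=seed, **kw)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def numeric_grad(fn, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g
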