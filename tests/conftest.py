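import numpy as np
import pytest

import cropformer as cf
from cropformer.nn import tensor as nn_tensor


@pytest.fixture
def f64():
    """Run the engine in float64 for finite-difference and oracle-equality
    checks; restore the training default afterwards."""
    prev = nn_tensor.DTYPE
    nn_tensor.set_default_dtype(np.float64)
    yield
    nn_tensor.set_default_dtype(prev)


@pytest.fixture(scope="session")
def tiny_world():
    """A small simulated dataset shared by fast tests: 4 classes x 30
    labeled samples, 200 unlabeled, default season/revisit/noise."""
    sim = cf.SimConfig(n_per_class=(30, 30, 30, 30), n_unlabeled=200, seed=7)
    labeled, unlabeled = cf.simulate(sim)
    train, val, test = cf.train_val_test_split(labeled, seed=7)
    return {"sim": sim, "labeled": labeled, "unlabeled": unlabeled,
            "train": train, "val": val, "test": test}


def make_sequence(sample_id="s", doy=(10, 20, 30), values=None, n_bands=4,
                  label=None, seed=0):
    doy = np.asarray(doy)
    if values is None:
        values = np.random.default_rng(seed).uniform(0, 1, size=(len(doy), n_bands))
    return cf.SpectralSequence(sample_id=sample_id, doy=doy,
                               spectra=np.asarray(values), label=label)


@pytest.fixture
def make_seq():
    return make_sequence
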