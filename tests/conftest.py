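import warnings

import numpy as np
import pytest

from htsval.synth import SynthConfig, generate_screen

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def small_screen():
    """A small but learnable synthetic screen shared across tests."""
    return generate_screen(
        SynthConfig(n=400, active_rate=0.05, fp_rate=0.3, d=64, seed=11)
    )


@pytest.fixture
def screen_csv(tmp_path):
    """A tiny screen CSV with real SMILES on disk."""
    path = tmp_path / "screen.csv"
    path.write_text(
        "compound_id,smiles,score,primary,confirmatory\n"
        "a,CCO,95.0,1,1\n"
        "b,c1ccccc1,80.0,1,0\n"
        "c,CC(=O)O,40.0,0,\n"
        "d,CCN,30.0,0,\n"
        "e,CCCC,10.0,0,\n"
    )
    return path


def separable_xor_labels(seed, n=200, d=16, n_flip=20):
    """Linearly separable binary data with planted flipped labels."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    y = (X[:, 0] > 0).astype(np.int64)
    flip = rng.choice(n, size=n_flip, replace=False)
    y[flip] = 1 - y[flip]
    return X, y, flip
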