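import numpy as np
import pytest

from plvnet.montage import biosemi64
from plvnet.preprocess import BAND_BY_NAME
from plvnet.synth import default_coupling_plan, generate_subject, pair_plan


@pytest.fixture(scope="session")
def montage64():
    return biosemi64()


@pytest.fixture(scope="session")
def kappa_pairs_recording():
    """Six independent anchored channel pairs at kappa 0, 0.5, 1, 2, 5, lock."""
    kappas = [0.0, 0.5, 1.0, 2.0, 5.0, 1e6]
    plan, montage = pair_plan(kappas)
    rec = generate_subject(plan, montage, seed=7, snr_db=None)
    return kappas, rec


@pytest.fixture(scope="session")
def small_subject(montage64):
    """One full-montage subject, beta band only, default noise."""
    plan = default_coupling_plan(montage64)
    return generate_subject(
        plan, montage64, group="LS-like", seed=5, bands=[BAND_BY_NAME["beta"]]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
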