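import numpy as np
import pytest

from ramanpath.cnn import CNNConfig, build_model, prepare_dataset, train
from ramanpath.core import raman_axis
from ramanpath.synthgen import generate_training_set


@pytest.fixture(scope="session")
def axis():
    return raman_axis()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def trained_model():
    """One well-trained small CNN shared by the classifier tests.

    Trained on spectra spanning the full nucleus/cytoplasm mixing range with
    random baselines and the ambient water background, so map pixels
    (including pure-role ones) are in-domain.
    """
    cfg = CNNConfig(epochs=20, seed=7)
    spectra = generate_training_set(
        n_per_class=300,
        seed=7,
        mixture_range=(0.0, 1.0),
        baseline_sd=0.12,
        water_background=0.25,
    )
    dataset = prepare_dataset(spectra, cfg)
    model = build_model(cfg)
    history = train(model, dataset, cfg)
    return model, dataset, history
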