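"""Shared fixtures: small phantoms and a pooled healthy-trained mixture.

Everything is generated at test time; session scope keeps the heavier
phantom + EM fits to one evaluation.
"""

import logging

import numpy as np
import pytest

import placseg as ps
from placseg.clustering import build_feature_table, fit_mixture
from placseg.diffusion import DiffusionScheme, fit_tensor
from placseg.relaxometry import EchoTrain, fit_t2star

logging.getLogger("placseg").setLevel(logging.ERROR)

SMALL_SHAPE = (32, 32, 16)


@pytest.fixture(scope="session")
def acquisition():
    return ps.default_acquisition()


def phantom_features(seed, lesion_fraction=0.0, snr=25.0,
                     shape=SMALL_SHAPE, acq=None):
    """Generate a phantom and fit its feature table (the standard chain)."""
    acq = acq or ps.default_acquisition()
    mecho, dwi, truth = ps.generate_phantom(
        shape=shape, seed=seed, snr=snr, lesion_fraction=lesion_fraction,
        acquisition=acq)
    t2map = fit_t2star(EchoTrain(mecho, acq.echo_times), truth.placental_mask)
    tensors = fit_tensor(dwi, DiffusionScheme(acq.bvals, acq.bvecs),
                         truth.placental_mask)
    features = build_feature_table(t2map, tensors, truth.placental_mask)
    return features, truth, t2map, tensors


@pytest.fixture(scope="session")
def noiseless_phantom():
    return ps.generate_phantom(shape=SMALL_SHAPE, seed=7, snr=np.inf)


@pytest.fixture(scope="session")
def healthy_pooled_model(acquisition):
    """Mixture trained on pooled features of three healthy noisy phantoms."""
    tables = [phantom_features(seed, acq=acquisition)[0].values
              for seed in (1, 2, 3)]
    train = np.concatenate(tables)
    model = fit_mixture(train, K=3, seed=0)
    return model


@pytest.fixture(scope="session")
def separated_mixture_sample():
    """30k labelled draws from the well-separated healthy feature mixture."""
    specs = ps.default_compartment_specs()
    from placseg.phantom import sample_gaussian_mixture
    return sample_gaussian_mixture(specs, 30_000, 11)
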