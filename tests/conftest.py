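import logging

import numpy as np
import pytest

from mrmprep.chromatogram import gaussian
from mrmprep.io import Chromatogram, MetaboliteDef, ProcessingParams, TransitionKey
from mrmprep.pipeline import process_batch
from mrmprep.simulate import SimConfig, generate_batch

logging.getLogger("mrmprep").setLevel(logging.ERROR)


@pytest.fixture
def params():
    return ProcessingParams()


def make_chrom(times, intensities, prec=100.0, prod=58.0):
    return Chromatogram(TransitionKey(prec, prod), np.asarray(times, float),
                        np.asarray(intensities, float))


def gaussian_chrom(amplitude=1000.0, mu=5.0, sigma=0.05, baseline=0.0,
                   t0=4.0, t1=6.0, dt=0.005, prec=100.0, prod=58.0):
    t = np.arange(t0, t1 + dt / 2, dt)
    return make_chrom(t, baseline + gaussian(t, amplitude, mu, sigma), prec, prod)


def textbook_metabolite(expected_rt=5.0, expected_ratio=2.0):
    return MetaboliteDef(
        name="Met",
        quantifier=TransitionKey(100.0, 58.0),
        qualifiers=[TransitionKey(100.0, 40.0)],
        expected_rt=expected_rt,
        expected_ratio=expected_ratio,
    )


@pytest.fixture(scope="session")
def small_batch():
    """6 samples x 5 metabolites with defaults, moderate noise and decoys."""
    cfg = SimConfig(n_samples=6, n_metabolites=5, seed=3)
    return generate_batch(cfg)


@pytest.fixture(scope="session")
def small_result(small_batch):
    samples, metabolites, _ = small_batch
    return process_batch(samples, metabolites, ProcessingParams())
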