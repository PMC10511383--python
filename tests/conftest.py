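import os

# keep BLAS single-threaded: the batched element operations parallelize badly
# and oversubscription slows the FE assembly down massively
os.environ.setdefault("OMP_NUM_THREADS", "1")
os.environ.setdefault("OPENBLAS_NUM_THREADS", "1")

import numpy as np
import pytest

from ogdenfit import (
    OgdenParameters,
    SpecimenGeometry,
    SyntheticConfig,
    extract_hyperelastic_response,
    simulate_raw_recording,
)
from ogdenfit.preprocess import MODES


@pytest.fixture(scope="session")
def geom():
    """Mean specimen geometry: 8 mm diameter, 4.9 mm height."""
    return SpecimenGeometry()


@pytest.fixture(scope="session")
def brainlike_params():
    """A parameter set in the fitted range for human brain tissue."""
    return OgdenParameters(mu=300.0, alpha=-18.0, nu=0.45)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230907)


def make_curves(mu=300.0, alpha=-18.0, nu=0.45, cycle=1, seed=0, denoise=True, **kw):
    """Synthetic processed three-mode curve set with known ground truth."""
    cfg = SyntheticConfig(mu=mu, alpha=alpha, nu=nu, seed=seed, **kw)
    geom = cfg.geometry
    return {
        m: extract_hyperelastic_response(
            simulate_raw_recording(cfg, m), cycle, geom, denoise=denoise
        )
        for m in MODES
    }, cfg


@pytest.fixture(scope="session")
def clean_curveset():
    """Noiseless three-mode set at (mu=300, alpha=-18, nu=0.45), cycle 1."""
    curves, cfg = make_curves(noise_std_pa=0.0, seed=1)
    return curves, cfg
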