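import numpy as np
import pytest

from bprtool.model import NoiseModel, ar1_covariance
from bprtool.signal_io import PupilTrace
from bprtool.simulate import canonical_shape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def true_shape():
    """Canonical blink-response kernel: trough -0.2 mm at 0.9 s."""
    return canonical_shape()


@pytest.fixture
def recovery_noise():
    """Noise model of the segment-level recovery regime."""
    return NoiseModel(lambda_bc=1.0, shift_bc=0.0, sigma=0.05, rho=0.8)


def make_trace(pupil, rate=500.0, valid=None, unit="mm", run_id="test"):
    pupil = np.asarray(pupil, dtype=float)
    time = np.arange(len(pupil)) / rate
    return PupilTrace(time=time, pupil=pupil, rate=rate, unit=unit,
                      valid=valid, run_id=run_id)


def draw_segments(n, mu, sigma, rho, rng, baseline=0.0):
    """Draw n MVN segments with AR(1) covariance around mu + baseline."""
    cov = ar1_covariance(sigma, rho, len(mu))
    chol = np.linalg.cholesky(cov)
    return (chol @ rng.standard_normal((len(mu), n))).T + np.asarray(mu) + baseline


@pytest.fixture
def trace_factory():
    return make_trace
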