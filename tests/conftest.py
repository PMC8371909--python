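import numpy as np
import pytest

import gravjump as gj


@pytest.fixture(scope="session")
def config():
    return gj.AnalysisConfig()


@pytest.fixture(scope="session")
def subject():
    return gj.SubjectParams()


@pytest.fixture(scope="session")
def trial_1g():
    """A reference drop jump at steady 1 g with ground truth."""
    return gj.make_trial(1.0, seed=3, is_reference=True)


@pytest.fixture(scope="session")
def report_1g(trial_1g):
    return gj.analyze_trial(trial_1g)


@pytest.fixture(scope="session")
def noiseless_imaging():
    return gj.ImagingParams(speckle_sd=0.0)


def constant_trace(value, duration=1.0, rate=2000.0, t0=0.0, units=""):
    n = int(round(duration * rate)) + 1
    return gj.Trace(t0=t0, rate=rate, values=np.full(n, float(value)), units=units)
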