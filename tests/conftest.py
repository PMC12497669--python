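import numpy as np
import pytest

from renoperf import (
    AcquisitionSpec,
    Curve,
    FitConfig,
    GroundTruthCenters,
    make_aif,
    seven_comp_tissue,
)


@pytest.fixture(scope="session")
def spec():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def aif(spec):
    return make_aif(spec)


@pytest.fixture(scope="session")
def truth():
    return GroundTruthCenters().centers


@pytest.fixture(scope="session")
def tissue_curves(truth, aif):
    return seven_comp_tissue(truth, aif)


@pytest.fixture()
def fast_cfg():
    """Small multi-start budget for unit tests."""
    return FitConfig(n_starts=8, rng_seed=42)


@pytest.fixture()
def triangular_bolus():
    """Unit-area triangular bolus on a fine grid (dt = 0.1 s)."""
    t = np.arange(0, 60, 0.1)
    v = np.clip(1.0 - np.abs(t - 5.0) / 5.0, 0.0, None) / 5.0
    return Curve(t, v)
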