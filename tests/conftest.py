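import numpy as np
import pytest

import perftwin as pt
from perftwin.experiments import calibrate_signal_model, run_dose_series, ExperimentSpec


@pytest.fixture(scope="session")
def seq():
    return pt.SequenceParams()


@pytest.fixture(scope="session")
def calibrated_model():
    """Signal model calibrated against the hardware's printed peak table."""
    return calibrate_signal_model()


@pytest.fixture(scope="session")
def dose_table(calibrated_model):
    """Noiseless dose-series summary (peaks, expected peaks, saturation ratios)."""
    res = run_dose_series(ExperimentSpec(base_seed=0), calibrated_model, quantify=False)
    return res.table


@pytest.fixture
def ref_circuit():
    return pt.reference_circuit(3.0, 10.0, 10.0)


@pytest.fixture
def smooth_aif():
    """A smooth first-pass-like arterial curve on a 1 s grid (gamma-variate)."""
    t = np.arange(0.0, 120.0, 1.0)
    shape, scale_ = 4.0, 2.3
    v = np.where(t > 3, (t - 3) ** (shape - 1) * np.exp(-(t - 3) / scale_), 0.0)
    v = 10.0 * v / v.max()
    return pt.SignalCurve("aorta", t, v)
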