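import numpy as np
import pytest

from sfdcm import BurstTrain, default_kernel, simulate
from sfdcm.preproc import ConductanceSeries, Epoch, baseline_subtract


@pytest.fixture(scope="session")
def kernel():
    """Calibrated default response kernel (unit burst -> 1 μS peak)."""
    return default_kernel()


@pytest.fixture(scope="session")
def three_burst_epoch(kernel):
    """Noiseless epoch with three well-separated bursts (0.5/1.0/0.8 μS)."""
    train = BurstTrain(np.array([10.0, 30.0, 50.0]), np.array([0.5, 1.0, 0.8]))
    trace = simulate(kernel, train, duration=60.0, rate=10.0)
    return Epoch(series=baseline_subtract(trace)), train


def match_bursts(true_train, est_train):
    """Per-true-burst absolute amplitude and onset errors via nearest onset."""
    amp_err, onset_err = [], []
    for o, a in zip(true_train.onsets, true_train.amplitudes):
        if len(est_train) == 0:
            amp_err.append(a)
            onset_err.append(np.inf)
            continue
        j = int(np.argmin(np.abs(est_train.onsets - o)))
        amp_err.append(abs(est_train.amplitudes[j] - a))
        onset_err.append(abs(est_train.onsets[j] - o))
    return np.array(amp_err), np.array(onset_err)
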