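import numpy as np
import pytest

from cardioresp.breath import segment_breaths
from cardioresp.synth import SynthConfig, generate_breathing

EUPNEA_KW = dict(apnea_rate=0.0, hypopnea_rate=0.0, sigh_rate=0.0)


@pytest.fixture(scope="session")
def eupnea_cfg():
    return SynthConfig(duration=240.0, seed=7, **EUPNEA_KW)


@pytest.fixture(scope="session")
def eupnea(eupnea_cfg):
    flow, truth = generate_breathing(eupnea_cfg)
    series = segment_breaths(flow, eupnea_cfg.body_mass)
    return flow, truth, series


@pytest.fixture(scope="session")
def hour_recording():
    """One default-configuration 1-h recording with events (reused across tests)."""
    cfg = SynthConfig(duration=3600.0, seed=1)
    flow, truth = generate_breathing(cfg)
    series = segment_breaths(flow, cfg.body_mass)
    return cfg, flow, truth, series


def match_events(truth_onsets, det_onsets, tol):
    """Greedy one-to-one onset matching; returns (tp, fn, fp)."""
    truth_onsets = sorted(truth_onsets)
    det = sorted(det_onsets)
    used = [False] * len(det)
    tp = 0
    for t in truth_onsets:
        best, best_d = None, tol
        for j, d in enumerate(det):
            if not used[j] and abs(d - t) <= best_d:
                best, best_d = j, abs(d - t)
        if best is not None:
            used[best] = True
            tp += 1
    fn = len(truth_onsets) - tp
    fp = len(det) - tp
    return tp, fn, fp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
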