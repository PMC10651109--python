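import numpy as np
import pytest
from hypothesis import settings

import antennascan as ans

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_trial():
    """One fully featured synthetic trial (all odour effects on)."""
    trial, truth = ans.generate_trial(ans.TrialGeneratorParams(), seed=42)
    return trial, truth


@pytest.fixture(scope="session")
def null_trial():
    """A trial with every odour-induced effect switched off."""
    trial, truth = ans.generate_trial(ans.TrialGeneratorParams().null(), seed=43)
    return trial, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_trial_from_angles(az_L, el_L, az_R, el_R, frame_rate=100.0,
                           onset_s=None, offset_s=None, length_mm=50.0):
    """Build a Trial whose antennal tips realise the given angle series."""
    az_L, el_L = np.asarray(az_L, float), np.asarray(el_L, float)
    az_R, el_R = np.asarray(az_R, float), np.asarray(el_R, float)
    n = az_L.size
    head = np.zeros((n, 3))

    def tip(az, el):
        a, e = np.radians(az), np.radians(el)
        return length_mm * np.column_stack(
            [np.sin(a) * np.cos(e), np.cos(a) * np.cos(e), np.sin(e)])

    dur = n / frame_rate
    onset = dur / 3 if onset_s is None else onset_s
    offset = 2 * dur / 3 if offset_s is None else offset_s
    points = {
        "head": ans.PointSeries(head, np.ones(n, bool)),
        "ant_L": ans.PointSeries(tip(az_L, el_L), np.ones(n, bool)),
        "ant_R": ans.PointSeries(tip(az_R, el_R), np.ones(n, bool)),
    }
    proto = ans.StimulusProtocol(onset_s=onset, offset_s=offset)
    return ans.Trial(trial_id="t", animal_id="a", odour="colony",
                     frame_rate=frame_rate, points=points, protocol=proto)
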